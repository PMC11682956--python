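"""Model evaluation of the fitted score model.

Goodness-of-fit table/plots (PRED, IPRED, IWRES) and a prediction-
corrected visual predictive check over the four nominal visits, all
written as CSV tables plus static plots.

Run after 02_fit_model.py:  python analysis/03_diagnostics.py [seed]
"""

import json
import sys
from pathlib import Path

from serinepkpd import default_parameters, gof_table, pc_vpc
from serinepkpd.dataio import read_dataset
from serinepkpd.diagnostics import plot_gof, plot_vpc
from serinepkpd.estimation import FitResult

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240
OUT = Path("results")

ds = read_dataset(OUT / "phase2_synthetic.csv")
fitted = json.loads((OUT / "fit.json").read_text())
res = FitResult(
    estimates=fitted["estimates"], omegas=fitted["omegas"],
    corr_e0_kprog=fitted["corr_e0_kprog"], sigma_add=fitted["sigma_add"],
    ofv=fitted["ofv"], converged=fitted["converged"], method=fitted["method"],
    seed=fitted["seed"], n_subjects=fitted["n_subjects"], n_obs=fitted["n_obs"],
)
params = res.to_model_parameters(default_parameters().pk)

gof = gof_table(ds, params)
gof.to_csv(OUT / "gof.csv", index=False)
plot_gof(gof, OUT / "gof.png")
print(f"IWRES mean {gof['iwres'].mean():+.3f}, SD {gof['iwres'].std():.3f} "
      f"(well-specified target: 0 and <=1)")

vpc = pc_vpc(ds, params, n_sim=500, seed=SEED)
vpc.table.to_csv(OUT / "vpc_summary.csv", index=False)
plot_vpc(vpc, OUT / "vpc.png")
inside = sum(
    row[f"sim_p{p:g}_lo"] <= row[f"obs_p{p:g}"] <= row[f"sim_p{p:g}_hi"]
    for _, row in vpc.table.iterrows() for p in (5.0, 50.0, 95.0)
)
print(f"pcVPC: {inside}/{3 * len(vpc.table)} observed percentiles inside "
      f"their 95% simulation envelopes")
print(f"wrote {OUT / 'gof.csv'}, {OUT / 'vpc_summary.csv'} (+plots)")
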