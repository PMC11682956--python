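"""Fit the PD mixed-effects model to the simulated trial.

SAEM (300 burn-in + 100 smoothing iterations, 2 chains) followed by a
deterministic Laplace polish; the PK model is held fixed.  Prints the
estimates next to the generating values and writes the fit JSON.

Run after 01_simulate_trial.py:  python analysis/02_fit_model.py [seed]
"""

import sys
from pathlib import Path

from serinepkpd import default_parameters, fit
from serinepkpd.dataio import provenance, read_dataset, write_json

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240
OUT = Path("results")

ds = read_dataset(OUT / "phase2_synthetic.csv")
params = default_parameters()
res = fit(ds, pk=params.pk, method="saem", seed=SEED)

truth = {
    "ke0": params.pd.ke0, "e0": params.pd.e0, "beta_age": params.pd.beta_age,
    "deff": params.pd.deff, "kprog": params.pd.kprog,
    "omega_ke0": params.ranef.omega_ke0, "omega_e0": params.ranef.omega_e0,
    "omega_deff": params.ranef.omega_deff, "omega_kprog": params.ranef.omega_kprog,
    "corr_e0_kprog": params.ranef.corr_e0_kprog, "sigma_add": params.ranef.sigma_add,
}
est = {**{k: res.estimates[k] for k in ("ke0", "e0", "beta_age", "deff", "kprog")},
       **res.omegas, "corr_e0_kprog": res.corr_e0_kprog, "sigma_add": res.sigma_add}
print(f"{'parameter':<14}{'generating':>12}{'estimate':>12}")
for k, v in truth.items():
    print(f"{k:<14}{v:>12.4g}{est[k]:>12.4g}")
print(f"OFV: {res.ofv:.1f}  method: {res.method}  converged: {res.converged}")

write_json(res.to_dict(), OUT / "fit.json", meta=provenance(seed=SEED))
print(f"wrote {OUT / 'fit.json'}")
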