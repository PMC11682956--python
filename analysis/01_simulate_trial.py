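"""Simulate a phase-II-shaped virtual trial.

145 children aged 2-11 y (82.8% male), three arms (placebo / low / high)
with weight-tiered BID dosing, two-week titration in the high-dose arm
and placebo crossover to high dose at week 12; scores observed at weeks
0/12/24/36.  Writes the long-format dataset and a small cohort summary.

Run:  python analysis/01_simulate_trial.py [seed]
"""

import sys
from pathlib import Path

from serinepkpd import default_parameters, phase2_design, simulate_dataset
from serinepkpd.dataio import provenance, write_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240
OUT = Path("results")
OUT.mkdir(exist_ok=True)

params = default_parameters()
design = phase2_design()
ds = simulate_dataset(design, params, n=145, seed=SEED)

meta = provenance(seed=SEED, config=params.to_dict())
write_dataset(ds, OUT / "phase2_synthetic.csv", meta=meta)

demog = ds.demographics
print(f"subjects: {ds.n_subjects}, observations: {ds.n_observations}, "
      f"dose events: {len(ds.doses)}")
print("arms:", demog["arm"].value_counts().to_dict())
print(f"male fraction: {(demog['sex'] == 'male').mean():.3f}")
print(f"weight median (min-max): {demog['weight'].median():.1f} "
      f"({demog['weight'].min():.1f}-{demog['weight'].max():.1f}) kg")
print(f"age range: {demog['age'].min():.1f}-{demog['age'].max():.1f} y")
print(f"wrote {OUT / 'phase2_synthetic.csv'}")
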