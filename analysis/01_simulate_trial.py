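"""Simulate one virtual paediatric trial under the published final model
and summarise the censoring burden per analyte.

Writes results/trial_seed1.csv (NONMEM-style dataset) and
results/blq_summary.csv.
"""

from pathlib import Path

from svmetpk import dataio
from svmetpk.diagnostics import blq_summary
from svmetpk.simulate import TrialDesign, simulate_trial

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

ds = simulate_trial(TrialDesign(), seed=1)
dataio.write_dataset(ds, OUT / "trial_seed1.csv")

tab = blq_summary(ds)
tab.to_csv(OUT / "blq_summary.csv", index=False)

print(f"simulated {ds.n_subjects} subjects, "
      f"{len(ds.observations())} observation rows "
      f"-> {OUT / 'trial_seed1.csv'}")
print("\nbelow-quantification fractions (post-dose):")
print(tab.to_string(index=False))
print("\nThe active metabolite SVA and the hydroxymethyl metabolites are "
      "heavily censored at the 0.5 nM limit, which is why the likelihood "
      "treats those observations as censored (M3) instead of dropping "
      "them.")
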