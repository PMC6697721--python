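"""Covariate screening and stepwise selection on simulated study data.

Starting from a base model with no genotype effect, the script computes
empirical Bayes estimates, screens them against the demographic and
genotype covariates (linear regression / ANOVA, with the >40% shrinkage
rule), and runs forward-inclusion / backward-elimination on the SV-SVA
sub-model likelihood.

Writes results/screening.csv, results/shrinkage.csv and
results/selection_trace.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from svmetpk.covsearch import forward_backward_select, screen_covariates
from svmetpk.estimate import ModelSpec, empirical_bayes, shrinkage
from svmetpk.params import ThetaSet
from svmetpk.simulate import TrialDesign, simulate_trial

np.seterr(all="ignore")
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# 64 subjects for a better-behaved search than the 32-subject study
design = TrialDesign(n_subjects=64,
                     genotype_counts={"TT": 30, "TC": 30, "CC": 4})
ds = simulate_trial(design, seed=11, analytes=("SV", "SVA"))

base = ModelSpec(theta=ThetaSet(theta561=0.0, theta562=0.0),
                 analytes=("SV", "SVA"))
ebes = empirical_bayes(ds, base)
shr = shrinkage(ebes, base.omega)
shr.to_csv(OUT / "shrinkage.csv", index=False)

cands = screen_covariates(ebes, ds.subject_covariates(), shr)
pd.DataFrame([c.__dict__ for c in cands]).to_csv(OUT / "screening.csv",
                                                 index=False)
print(f"screening flagged {len(cands)} candidate relationship(s):")
for c in cands[:8]:
    print(f"  {c.param:16s} ~ {c.covariate:10s} p={c.p_value:.2e}"
          f"{'  (direct test: high shrinkage)' if c.direct_test else ''}")

# test the genotype candidates on the two SVA-sub-model parameters the
# screen associates with c.521T>C (formation and elimination ratios)
keep = [c for c in cands if c.covariate == "RS4149056"
        and c.param in ("CLLA_VSVA", "CLSVAe_VSVA")]
res = forward_backward_select(ds, keep, base, free_base=[])
res.trace.to_csv(OUT / "selection_trace.csv", index=False)
print(f"\nforward/backward selection: base OFV {res.base_ofv:.2f} -> "
      f"final OFV {res.final_ofv:.2f}")
if res.selected:
    for eff in res.selected:
        print(f"  retained: {eff.param} ~ {eff.covariate} ({eff.kind}, "
              f"{eff.df} df)")
    print("\nThe c.521T>C effect on the SVA sub-model survives the "
          "backward-elimination bar, mirroring its role in the final "
          "model.")
else:
    print("  no covariate survived the backward-elimination bar in this "
          "replicate")
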