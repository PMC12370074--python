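#!/usr/bin/env python
"""Parameter-recovery study at the field estimates.

Simulates many surveys at the published field values (809 cells, psi =
0.47 / 0.24, phi = 1.94, weak survey-specific detection) and refits the
models, summarizing bias and Monte-Carlo error of psi-hat and phi-hat.
The default 50 replicates give a quick look; the acceptance script runs
the full 200.
"""
import argparse
from pathlib import Path

import pandas as pd

from crocsurvey.recovery import recover_pair_phi, recover_single_psi

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--n-reps", type=int, default=50)
ap.add_argument("--out", type=Path, default=Path("results/recovery"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

rows = []
for name, res in (
    ("phi (two-species, p=r)", recover_pair_phi(args.n_reps, args.seed)),
    ("psi (gharial, p(survey))", recover_single_psi(args.n_reps, args.seed)),
):
    rows.append(
        {
            "parameter": name, "truth": res.truth, "mean": res.mean, "sd": res.sd,
            "mc_se": res.mc_se, "bias": res.bias, "within_2_mc_se": res.within(2.0),
            "n_reps": res.n_reps,
        }
    )
    print(f"{name}: truth {res.truth}, mean estimate {res.mean:.3f} "
          f"(SD {res.sd:.3f}, MC SE {res.mc_se:.4f}) -> bias {res.bias:+.3f}, "
          f"{'within' if res.within(2.0) else 'OUTSIDE'} 2 MC SEs")

print("note: at the weak printed gharial detection levels psi-hat is a "
      "boundary-prone, right-skewed MLE; its mean sits above truth even "
      "though its median recovers it. See docs/methods.md.")
pd.DataFrame(rows).to_csv(args.out / "recovery_summary.csv", index=False)
print(f"wrote {args.out / 'recovery_summary.csv'}")
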