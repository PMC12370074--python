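#!/usr/bin/env python
"""Generate the baseline synthetic drone survey.

Emulates the field campaign: 809 checkerboard cells of 0.04 km^2 along a
river ribbon, 1-5 flight-path replicates per cell, two crocodilian species
with habitat-use probabilities 0.47 / 0.24, interaction factor 1.94 and
weak survey-specific detection. Writes points, geometries, encounter
histories and the mission table under results/survey/.
"""
import argparse
from pathlib import Path

from crocsurvey.pipeline import PipelineConfig, stage_simulate
from crocsurvey.synthetic import SyntheticConfig

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/survey"))
args = ap.parse_args()

cfg = PipelineConfig(synthetic=SyntheticConfig(seed=args.seed))
args.out.mkdir(parents=True, exist_ok=True)
written = stage_simulate(cfg, args.out)

import pandas as pd  # noqa: E402

points = pd.read_csv(args.out / "points.csv")
print(f"simulated {cfg.synthetic.n_cells} cells (seed {args.seed})")
for sp, n in points.groupby("species").size().items():
    fl = points[points["species"] == sp]["floating"].mean()
    print(f"  {sp}: {n} individuals generated ({fl:.0%} floating)")
print(f"wrote {len(written)} files under {args.out}")
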