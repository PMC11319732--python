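"""Robustness of the trained models to training-set reduction.

Two stress grids on each preset: (a) removing training peptides similar
to the cognate (maximum aligned residues 6 -> 2) and (b) uniform
downsampling of the training set, retraining the full model each time
and re-ranking the cognate.

Run:  python analysis/07_robustness.py [--seed 1]
"""

import argparse
from pathlib import Path

from epibind import pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-models", type=int, default=2)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

for preset in pipeline.PRESETS.values():
    table = pipeline.prepare_table(preset, args.seed)
    sim, frac = pipeline.run_robustness_suite(
        table, preset, args.seed, n_models=args.n_models
    )
    sim.to_csv(args.outdir / f"{preset.name}.robustness_similarity.tsv", sep="\t", index=False)
    frac.to_csv(args.outdir / f"{preset.name}.robustness_fraction.tsv", sep="\t", index=False)
    print(f"\n{preset.name}: similarity-filtered training")
    print(sim.to_string(index=False))
    print(f"{preset.name}: downsampled training")
    print(frac.to_string(index=False))
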