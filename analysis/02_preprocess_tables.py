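"""Build the modeling tables: average replicates, correct saturation,
filter lengths, exclude cognates; fit the composition models and audit
the high-binder weighting.

Reads the raw tables written by 01_simulate_arrays.py.

Run:  python analysis/02_preprocess_tables.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from epibind import pipeline
from epibind.array_io import (
    average_replicates,
    correct_saturation,
    exclude_cognates,
    filter_by_length,
    read_array_table,
    write_binding_table,
)
from epibind.preprocess import WeightingConfig, fit_composition, weight_expand

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

for preset in pipeline.PRESETS.values():
    raw = args.outdir / f"{preset.name}.raw.tsv"
    if not raw.exists():
        raise SystemExit(f"{raw} missing - run analysis/01_simulate_arrays.py first")
    ds = read_array_table(raw)
    bt = correct_saturation(average_replicates(ds))
    n_sub = int(bt.saturation_substituted.sum())
    bt = filter_by_length(bt)
    bt, n_removed = exclude_cognates(bt, [preset.cognate])
    write_binding_table(bt, args.outdir / f"{preset.name}.binding.tsv", comment=f"seed={args.seed}")

    mult = weight_expand(bt.values[:, 3], WeightingConfig(seed=args.seed))
    pd.DataFrame({"sequence": bt.sequences, "multiplicity": mult}).query(
        "multiplicity > 1"
    ).to_csv(args.outdir / f"{preset.name}.weighting.tsv", sep="\t", index=False)

    comp = fit_composition(bt.sequences, bt.values)
    (args.outdir / f"{preset.name}.composition.json").write_text(comp.to_json())
    print(
        f"{preset.name}: {len(bt)} rows ({n_removed} cognate rows excluded), "
        f"{n_sub} saturated cells substituted, "
        f"{int((mult > 1).sum())} up-weighted pairs (total multiplicity {int(mult.sum())}), "
        f"composition R^2 by concentration {np.round(comp.r_squared, 3).tolist()}"
    )
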