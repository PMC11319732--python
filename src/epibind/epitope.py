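"""Downstream epitope analyses on trained binding models.

* Substitution scans: predicted linear-scale binding (2 nM) of every
  single-residue variant of a cognate, normalized to the unmutated value.
* Antigen tiling: overlapping 7-mers (6-residue overlap) across a protein
  sequence, scored at 2 nM, after mapping the four amino acids absent
  from the array alphabet by PAM250 similarity (I->V, T->S, M->L, C->S).
* Robustness utilities: cognate-similarity counting/filtering of the
  training set, and seeded downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_io import BindingTable
from .encoding import AMINO_ACIDS
from .model import Ensemble

#: Similarity substitution for the 4 amino acids not on the array (PAM250).
MISSING_AA_MAP = str.maketrans({"I": "V", "T": "S", "M": "L", "C": "S"})

TWO_NM = 2.0


def map_missing_aa(sequence: str) -> str:
    """Apply exactly the I->V, T->S, M->L, C->S substitutions."""
    return sequence.translate(MISSING_AA_MAP)


def _conc_index(concentrations, concentration=TWO_NM) -> int:
    return int(np.argmin(np.abs(np.asarray(concentrations) - concentration)))


@dataclass
class SubstitutionMatrix:
    """L x 16 linear-scale binding of single mutants relative to wild type."""

    cognate: str
    alphabet: str
    values: np.ndarray  # (len(cognate), 16), wild-type cells exactly 1.0

    def clipped(self, ceiling: float = 1.1) -> np.ndarray:
        """Presentation clip: values at/above ``ceiling`` shown as ceiling."""
        return np.minimum(self.values, ceiling)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=[f"{aa}{i + 1}" for i, aa in enumerate(self.cognate)],
            columns=list(self.alphabet),
        )
        df.index.name = "position"
        return df


def substitution_scan(
    ensemble: Ensemble, cognate: str, concentration: float = TWO_NM
) -> SubstitutionMatrix:
    """Predict every single-residue substitution of the cognate.

    Each cell is the 2 nM prediction of the mutant converted to linear
    scale and divided by the cognate's linear value; substituting a
    position by its own residue is exactly 1 by construction.
    """
    variants = [cognate]
    index: list[tuple[int, int]] = []
    for pos in range(len(cognate)):
        for a, aa in enumerate(AMINO_ACIDS):
            if aa != cognate[pos]:
                variants.append(cognate[:pos] + aa + cognate[pos + 1 :])
            index.append((pos, a))
    preds = ensemble.predict(variants)
    j = _conc_index(ensemble.models[0].concentrations, concentration)
    linear = 10.0 ** preds[:, j]
    values = np.ones((len(cognate), len(AMINO_ACIDS)))
    v = 1
    for pos in range(len(cognate)):
        for a, aa in enumerate(AMINO_ACIDS):
            if aa == cognate[pos]:
                values[pos, a] = 1.0
            else:
                values[pos, a] = linear[v] / linear[0]
                v += 1
    return SubstitutionMatrix(cognate=cognate, alphabet=AMINO_ACIDS, values=values)


@dataclass
class TilingProfile:
    """Predicted binding along an antigen, tile-wise and per residue."""

    antigen: str  # after missing-aa mapping
    tile_len: int
    tile_scores: np.ndarray  # (len - tile_len + 1,) log10 at 2 nM
    residue_scores: np.ndarray  # (len,), max over covering tiles

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.antigen) + 1),
                "residue": list(self.antigen),
                "residue_score": self.residue_scores,
            }
        )


def tile_antigen(
    ensemble: Ensemble,
    antigen: str,
    tile_len: int = 7,
    overlap: int = 6,
    concentration: float = TWO_NM,
    residue_aggregate: str = "max",
) -> TilingProfile:
    """Tile an antigen into overlapping windows and score each at 2 nM.

    The antigen is mapped through :func:`map_missing_aa` first; per-residue
    scores aggregate over the tiles covering each position (max by
    default, mean optionally).
    """
    step = tile_len - overlap
    if step != 1:
        raise ValueError("only offset-1 tiling (overlap = tile_len - 1) is supported")
    mapped = map_missing_aa(antigen)
    if len(mapped) < tile_len:
        raise ValueError(f"antigen shorter than tile length {tile_len}")
    tiles = [mapped[i : i + tile_len] for i in range(len(mapped) - tile_len + 1)]
    preds = ensemble.predict(tiles)
    j = _conc_index(ensemble.models[0].concentrations, concentration)
    tile_scores = preds[:, j]
    n = len(mapped)
    residue = np.full(n, -np.inf)
    counts = np.zeros(n)
    sums = np.zeros(n)
    for i, s in enumerate(tile_scores):
        lo, hi = i, i + tile_len
        residue[lo:hi] = np.maximum(residue[lo:hi], s)
        sums[lo:hi] += s
        counts[lo:hi] += 1
    if residue_aggregate == "mean":
        residue = sums / counts
    elif residue_aggregate != "max":
        raise ValueError("residue_aggregate must be 'max' or 'mean'")
    return TilingProfile(
        antigen=mapped, tile_len=tile_len, tile_scores=tile_scores, residue_scores=residue
    )


def similarity_count(peptide: str, cognate: str) -> int:
    """Best ungapped identity count against the cognate over all offsets,
    including partial overlaps (>=1 aligned position)."""
    m = len(cognate)
    n = len(peptide)
    best = 0
    for off in range(-(m - 1), n):
        s = 0
        for j in range(m):
            k = off + j
            if 0 <= k < n and peptide[k] == cognate[j]:
                s += 1
        best = max(best, s)
    return best


def filter_by_similarity(
    table: BindingTable, cognate: str, max_common: int
) -> tuple[BindingTable, int]:
    """Drop training rows sharing more than ``max_common`` aligned residues
    with the cognate; returns (table, number removed)."""
    counts = np.array([similarity_count(s, cognate) for s in table.sequences])
    keep = np.flatnonzero(counts <= max_common)
    return table.take(keep), len(table) - len(keep)


def downsample(table: BindingTable, fraction: float, seed: int = 0) -> BindingTable:
    """Seeded uniform subsample (without replacement) of the training rows."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return table.take(np.arange(len(table)))
    rng = np.random.default_rng(seed)
    n_keep = int(len(table) * fraction)
    keep = np.sort(rng.choice(len(table), size=n_keep, replace=False))
    return table.take(keep)
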