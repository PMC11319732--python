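"""Training-set transformations: high-binder up-weighting and
composition-model subtraction.

Antibody arrays are dominated by background binders, so the loss is
rebalanced by binning peptides on their 8 nM log10 binding (bin width
0.2) and expanding every bin below 300 members back toward 300 by
randomly duplicating members, with no single sequence-binding pair copied
more than 100 times.  Duplications are tracked as integer multiplicities
(used as per-example loss weights downstream) rather than materialized.

The composition model is an ordinary least-squares fit of log10 binding
on the 16-element amino-acid count vector (16 coefficients + intercept,
one independent fit per concentration).  Subtracting its prediction
leaves the purely order-dependent part of binding for the network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .array_io import BindingTable
from .encoding import AMINO_ACIDS


@dataclass(frozen=True)
class WeightingConfig:
    reference_concentration: float = 8.0
    bin_width: float = 0.2
    min_bin_count: int = 300
    max_copies_per_pair: int = 100
    bin_anchor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.min_bin_count < 1 or self.max_copies_per_pair < 1:
            raise ValueError("invalid weighting configuration")


def weight_expand(values_ref: np.ndarray, cfg: WeightingConfig) -> np.ndarray:
    """Integer multiplicity per row, from reference-concentration binning.

    Bins are half-open ``[anchor + m*w, anchor + (m+1)*w)``.  Bins with at
    least ``min_bin_count`` members are untouched (multiplicity 1).  A
    smaller bin is grown by seeded uniform draws with replacement until it
    reaches ``min_bin_count`` total or every member holds
    ``max_copies_per_pair`` copies, whichever comes first.
    """
    values_ref = np.asarray(values_ref, dtype=float)
    mult = np.ones(len(values_ref), dtype=np.int64)
    if len(values_ref) == 0:
        return mult
    rng = np.random.default_rng(cfg.seed)
    bins = np.floor((values_ref - cfg.bin_anchor) / cfg.bin_width).astype(np.int64)
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        n = len(members)
        if n >= cfg.min_bin_count:
            continue
        target = min(cfg.min_bin_count, cfg.max_copies_per_pair * n)
        total = n
        while total < target:
            pick = members[rng.integers(0, n)]
            if mult[pick] < cfg.max_copies_per_pair:
                mult[pick] += 1
                total += 1
    return mult


@dataclass
class CompositionModel:
    """Per-concentration linear model of log10 binding on amino-acid counts."""

    coefficients: np.ndarray  # (n_conc, 16), column order = AMINO_ACIDS
    intercepts: np.ndarray  # (n_conc,)
    r_squared: np.ndarray = field(default=None)  # (n_conc,)
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, float))
        self.intercepts = np.asarray(self.intercepts, float)

    def to_json(self) -> str:
        return json.dumps(
            {
                "alphabet": self.alphabet,
                "intercepts": self.intercepts.tolist(),
                "coefficients": {
                    aa: self.coefficients[:, i].tolist()
                    for i, aa in enumerate(self.alphabet)
                },
                "r_squared": None if self.r_squared is None else self.r_squared.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CompositionModel":
        d = json.loads(text)
        alphabet = d["alphabet"]
        coeffs = np.column_stack([d["coefficients"][aa] for aa in alphabet])
        return cls(
            coefficients=coeffs,
            intercepts=np.asarray(d["intercepts"]),
            r_squared=None if d["r_squared"] is None else np.asarray(d["r_squared"]),
            alphabet=alphabet,
        )


def composition_matrix(sequences: list[str], alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """Peptide x 16 matrix of residue counts."""
    idx = {aa: i for i, aa in enumerate(alphabet)}
    out = np.zeros((len(sequences), len(alphabet)), dtype=float)
    for r, seq in enumerate(sequences):
        for ch in seq:
            out[r, idx[ch]] += 1.0
    return out


def fit_composition(
    sequences: list[str], binding: np.ndarray, pooled: bool = False
) -> CompositionModel:
    """Independent OLS fit per concentration column; reports R^2.

    With ``pooled`` a single coefficient vector (and intercept) is fitted
    on all concentration columns stacked and replicated across columns.
    Rank-deficient designs fall back to the minimum-norm least-squares
    solution with a warning.
    """
    binding = np.asarray(binding, float)
    if binding.ndim == 1:
        binding = binding[:, None]
    if pooled:
        n_conc = binding.shape[1]
        stacked = fit_composition(
            sequences * n_conc, binding.T.reshape(-1, 1), pooled=False
        )
        model = CompositionModel(
            coefficients=np.tile(stacked.coefficients, (n_conc, 1)),
            intercepts=np.full(n_conc, stacked.intercepts[0]),
        )
        pred = predict_composition(model, sequences)
        ss_res = ((binding - pred) ** 2).sum(axis=0)
        ss_tot = ((binding - binding.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            model.r_squared = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        return model
    X = composition_matrix(sequences)
    design = np.column_stack([X, np.ones(len(sequences))])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("composition design is rank deficient; minimum-norm fit", stacklevel=2)
    beta, _, _, _ = np.linalg.lstsq(design, binding, rcond=None)
    pred = design @ beta
    ss_res = ((binding - pred) ** 2).sum(axis=0)
    ss_tot = ((binding - binding.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return CompositionModel(
        coefficients=beta[:-1].T, intercepts=beta[-1], r_squared=r2
    )


def predict_composition(model: CompositionModel, sequences: list[str]) -> np.ndarray:
    """Composition-only log10 binding, peptides x concentrations."""
    X = composition_matrix(sequences, model.alphabet)
    return X @ model.coefficients.T + model.intercepts[None, :]


def subtract_composition(model: CompositionModel, table: BindingTable) -> BindingTable:
    from dataclasses import replace

    return replace(table, values=table.values - predict_composition(model, table.sequences))


def add_composition(model: CompositionModel, table: BindingTable) -> BindingTable:
    from dataclasses import replace

    return replace(table, values=table.values + predict_composition(model, table.sequences))
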