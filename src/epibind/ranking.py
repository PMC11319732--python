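"""Ranking a candidate epitope among random sequence space.

The headline specificity statistic: predict binding of the cognate
epitope and N random sequences of the same length at all four
concentrations with a model ensemble, rank each concentration column
separately (descending value, rank 1 = strongest), take each sequence's
best (minimum) rank across concentrations, then stably re-rank those
best-rank values so every sequence holds a unique final rank.  Percent
rank is ``100 * rank / (N + 1)``.

Error statistics follow the repeat grid: ``n_models`` independently
seeded networks, ``n_random_sets`` independent random-sequence sets, and
``n_repeats`` full repeats with fresh seeds; the mean rank and its
standard error are reported over the per-set final ranks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import encoding
from .model import Ensemble


@dataclass(frozen=True)
class RankConfig:
    cognate: str
    n_random: int = 1_000_000
    n_models: int = 12
    n_random_sets: int = 2
    n_repeats: int = 5
    seed: int = 0
    add_composition_back: bool = True
    #: "predictions": average member predictions, then rank (default);
    #: "ranks": rank per member, then average the final ranks and re-rank
    average: str = "predictions"

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if set(self.cognate) - set(encoding.AMINO_ACIDS):
            raise ValueError(
                f"cognate {self.cognate!r} has letters outside the array alphabet; "
                "map them first (see epibind.epitope.map_missing_aa)"
            )


@dataclass
class RankResult:
    cognate: str
    rank: int  # final re-ranked position, 1-based
    n_random: int
    per_concentration_rank: np.ndarray  # (n_conc,)
    best_rank: int
    predictions: np.ndarray  # cognate's predicted values (n_conc,)
    ranks_over_repeats: list[int] = field(default_factory=list)

    @property
    def percent_rank(self) -> float:
        return 100.0 * self.rank / (self.n_random + 1)

    @property
    def mean_rank(self) -> float:
        reps = self.ranks_over_repeats or [self.rank]
        return float(np.mean(reps))

    @property
    def sem_rank(self) -> float:
        reps = self.ranks_over_repeats or [self.rank]
        if len(reps) < 2:
            return 0.0
        return float(np.std(reps, ddof=1) / np.sqrt(len(reps)))

    @property
    def mean_percent_rank(self) -> float:
        return 100.0 * self.mean_rank / (self.n_random + 1)

    def to_dict(self) -> dict:
        return {
            "cognate": self.cognate,
            "rank": self.rank,
            "n_random": self.n_random,
            "percent_rank": self.percent_rank,
            "per_concentration_rank": self.per_concentration_rank.tolist(),
            "best_rank": self.best_rank,
            "predictions": self.predictions.tolist(),
            "ranks_over_repeats": self.ranks_over_repeats,
            "mean_rank": self.mean_rank,
            "sem_rank": self.sem_rank,
            "mean_percent_rank": self.mean_percent_rank,
        }


def random_library(
    n: int, length: int, alphabet: str = encoding.AMINO_ACIDS, seed: int = 0
) -> list[str]:
    """n i.i.d.-uniform sequences of one length (duplicates permitted)."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    draws = rng.integers(0, len(letters), size=(n, length))
    return ["".join(row) for row in letters[draws]]


def _seq_hash(seq: str) -> int:
    """Deterministic tie-break hash (stable across runs and platforms)."""
    return int.from_bytes(hashlib.blake2b(seq.encode(), digest_size=8).digest(), "big")


def _final_ranks(values: np.ndarray, sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(final_ranks, per_concentration_ranks) for all sequences.

    Per-concentration ranks are descending-value ordinal ranks (ties kept
    in stable order).  The final re-rank orders sequences by their sorted
    per-concentration rank vector (best rank first), with remaining ties
    broken by a deterministic sequence hash — rank-based keys keep the
    final order invariant under any strictly monotone transform of the
    predictions, including per-concentration offsets.
    """
    n, n_conc = values.shape
    per_conc = np.empty((n, n_conc), dtype=np.int64)
    for j in range(n_conc):
        order = np.argsort(-values[:, j], kind="stable")
        per_conc[order, j] = np.arange(1, n + 1)
    rank_keys = np.sort(per_conc, axis=1)  # best rank first, then fallbacks
    hashes = np.array([_seq_hash(s) for s in sequences], dtype=np.uint64)
    order = np.lexsort((hashes,) + tuple(rank_keys[:, j] for j in range(n_conc - 1, -1, -1)))
    final = np.empty(n, dtype=np.int64)
    final[order] = np.arange(1, n + 1)
    return final, per_conc


def rank_cognate(
    ensemble: Ensemble, cognate: str, randoms: list[str], cfg: RankConfig
) -> RankResult:
    """Rank the cognate among ``randoms`` with ensemble-mean predictions.

    With ``cfg.average == "ranks"`` each member model produces its own
    final ranking and the member ranks are averaged, then re-ranked.
    """
    sequences = [cognate] + list(randoms)
    tokens, group = encoding.encode_batch(sequences, shifted=ensemble.config.shifting)
    if cfg.average == "ranks" and len(getattr(ensemble, "models", [])) > 1:
        member_finals = []
        per_conc = None
        values = None
        for member in ensemble.models:
            v = np.asarray(member.forward_tokens(tokens, group), dtype=float)
            if (
                ensemble.config.composition
                and cfg.add_composition_back
                and getattr(member, "composition_model", None) is not None
            ):
                from .preprocess import predict_composition

                v = v + predict_composition(member.composition_model, sequences)
            f, pc = _final_ranks(v, sequences)
            member_finals.append(f)
            per_conc, values = pc, v
        mean_rank = np.mean(member_finals, axis=0)
        hashes = np.array([_seq_hash(s) for s in sequences], dtype=np.uint64)
        order = np.lexsort((hashes, mean_rank))
        final = np.empty(len(sequences), dtype=np.int64)
        final[order] = np.arange(1, len(sequences) + 1)
    else:
        values = ensemble.predict_tokens(
            tokens,
            group,
            sequences=sequences,
            add_composition_back=cfg.add_composition_back,
        )
        final, per_conc = _final_ranks(values, sequences)
    return RankResult(
        cognate=cognate,
        rank=int(final[0]),
        n_random=len(randoms),
        per_concentration_rank=per_conc[0],
        best_rank=int(per_conc[0].min()),
        predictions=values[0],
    )


def repeat_rank(ensemble_factory, cfg: RankConfig) -> RankResult:
    """Run the full repeat grid and aggregate mean +/- SEM.

    ``ensemble_factory(seed, n_models)`` must return a trained
    :class:`Ensemble`; it is called once per repeat so network-seed
    variation is included alongside random-set variation.
    """
    ranks: list[int] = []
    last: RankResult | None = None
    for rep in range(cfg.n_repeats):
        rep_seed = cfg.seed + 7919 * rep
        ens = ensemble_factory(rep_seed, cfg.n_models)
        for s in range(cfg.n_random_sets):
            randoms = random_library(
                cfg.n_random, len(cfg.cognate), seed=rep_seed + 104729 * (s + 1)
            )
            last = rank_cognate(ens, cfg.cognate, randoms, cfg)
            ranks.append(last.rank)
    last.ranks_over_repeats = ranks
    return last


def top_k_table(
    ensemble: Ensemble, randoms: list[str], k: int = 20, add_composition_back: bool = True
) -> pd.DataFrame:
    """Top-k random sequences under the same best-rank/re-rank rule."""
    tokens, group = encoding.encode_batch(randoms, shifted=ensemble.config.shifting)
    values = ensemble.predict_tokens(
        tokens, group, sequences=randoms, add_composition_back=add_composition_back
    )
    final, per_conc = _final_ranks(values, randoms)
    order = np.argsort(final)[: min(k, len(randoms))]
    df = pd.DataFrame(
        {
            "rank": final[order],
            "sequence": [randoms[i] for i in order],
            "best_concentration_rank": per_conc.min(axis=1)[order],
        }
    )
    for j in range(values.shape[1]):
        df[f"pred_c{j}"] = values[order, j]
    return df
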