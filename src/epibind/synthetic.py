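"""Synthetic peptide libraries and antibody-like binding measurements.

The generator emulates a near-random peptide array assayed with a
monoclonal antibody: ~1e5 unique peptides of length 5-11 (median 9),
fluorescence background near 850 counts (log10 ~= 2.9), a scarce
high-binding tail driven by a planted linear motif, linear scaling over a
4x concentration ladder (0.125 / 0.5 / 2 / 8 nM), 4 replicates, and a
16-bit detector that saturates at 65,536 counts.

Ground truth is an explicit affinity function (motif match energy plus a
residue-composition term), so every downstream stage — replicate
averaging, saturation correction, weighting, register-shift training,
ranking, substitution scans — can be scored against a known landscape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .encoding import AMINO_ACIDS, MIN_LEN, MAX_LEN

DEFAULT_CONCENTRATIONS = (0.125, 0.5, 2.0, 8.0)
DEFAULT_BASELINE = 850.0
SATURATION_CAP = 65_536

#: Length weights peaked at 9, supported on 5..11 (median 9 by construction).
DEFAULT_LENGTH_DISTRIBUTION = {
    5: 0.03, 6: 0.05, 7: 0.09, 8: 0.15, 9: 0.36, 10: 0.20, 11: 0.12,
}


class ConfigurationError(ValueError):
    pass


class CapacityError(ValueError):
    pass


@dataclass(frozen=True)
class LibrarySpec:
    """Specification of a uniform random peptide library."""

    n_peptides: int
    alphabet: str = AMINO_ACIDS
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides <= 0:
            raise ConfigurationError("n_peptides must be positive")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ConfigurationError("alphabet letters must be unique")
        probs = np.array(list(self.length_distribution.values()), dtype=float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("length probabilities must be >=0 and sum to 1")
        capacity = sum(
            len(self.alphabet) ** length
            for length, p in self.length_distribution.items()
            if p > 0
        )
        if self.n_peptides > capacity:
            raise CapacityError(
                f"{self.n_peptides} unique peptides requested but only "
                f"{capacity} distinct sequences exist"
            )


@dataclass(frozen=True)
class SyntheticLandscape:
    """Planted-motif + composition generative model of mAb binding.

    Affinity (log10 units) of a peptide is the best ungapped identity
    alignment of ``motif`` against it (sum of ``match_energy`` over matched
    positions, partial overlaps allowed) plus a residue-composition term.
    Expected counts at concentration ``c`` are
    ``baseline_counts + gain * c * 10**affinity``, with log-normal replicate
    noise and clipping to ``[1, saturation_cap]``.
    """

    motif: str
    match_energy: tuple[float, ...]
    composition_coeffs: dict[str, float] = field(default_factory=dict)
    baseline_counts: float = DEFAULT_BASELINE
    gain: float = 1.0
    noise_sigma: float = 0.02
    saturation_cap: int = SATURATION_CAP
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (5 <= len(self.motif) <= 10):
            raise ConfigurationError("motif length must be in [5, 10]")
        if set(self.motif) - set(AMINO_ACIDS):
            raise ConfigurationError("motif letters must be in the 16-letter alphabet")
        if len(self.match_energy) != len(self.motif):
            raise ConfigurationError("one match energy per motif position")
        if any(e < 0 for e in self.match_energy):
            raise ConfigurationError("match energies must be nonnegative")
        if self.saturation_cap <= self.baseline_counts:
            raise ConfigurationError("saturation cap must exceed baseline")
        conc = np.asarray(self.concentrations)
        if not np.all(np.diff(conc) > 0):
            raise ConfigurationError("concentrations must be strictly increasing")
        ratios = conc[1:] / conc[:-1]
        if not np.allclose(ratios, ratios[0]):
            raise ConfigurationError("concentration ratio must be constant")

    def to_json(self) -> str:
        """Ground-truth sidecar (motif, energies, coefficients, seed)."""
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticLandscape":
        d = json.loads(text)
        d["match_energy"] = tuple(d["match_energy"])
        d["concentrations"] = tuple(d["concentrations"])
        return cls(**d)


def generate_library(spec: LibrarySpec, max_attempts: int = 10**6) -> list[str]:
    """Draw ``n_peptides`` unique i.i.d.-uniform sequences (resample collisions)."""
    rng = np.random.default_rng(spec.seed)
    lengths = np.array(sorted(spec.length_distribution))
    probs = np.array([spec.length_distribution[l] for l in lengths])
    letters = np.array(list(spec.alphabet))

    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < spec.n_peptides:
        n_draw = spec.n_peptides - len(out)
        attempts += n_draw
        if attempts > max_attempts + spec.n_peptides:
            raise CapacityError("too many collisions while sampling unique peptides")
        ls = rng.choice(lengths, size=n_draw, p=probs)
        for length in ls:
            seq = "".join(letters[rng.integers(0, len(letters), size=length)])
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
    return out


def affinity(landscape: SyntheticLandscape, peptide: str) -> float:
    """Ground-truth log10 affinity of one peptide (pure function)."""
    if set(peptide) - set(AMINO_ACIDS):
        raise ValueError(f"non-alphabet character in {peptide!r}")
    return float(
        _best_match_energy([peptide], landscape)[0]
        + _composition_term([peptide], landscape)[0]
    )


def affinity_batch(landscape: SyntheticLandscape, peptides: list[str]) -> np.ndarray:
    return _best_match_energy(peptides, landscape) + _composition_term(
        peptides, landscape
    )


def _best_match_energy(peptides: list[str], ls: SyntheticLandscape) -> np.ndarray:
    """Max over all ungapped offsets (partial overlaps included) of the
    summed match energy at identity positions."""
    motif = ls.motif
    m = len(motif)
    energy = np.asarray(ls.match_energy)
    best = np.zeros(len(peptides))
    for i, pep in enumerate(peptides):
        n = len(pep)
        top = 0.0
        # offset = index in peptide where motif position 0 lands
        for off in range(-(m - 1), n):
            s = 0.0
            for j in range(m):
                k = off + j
                if 0 <= k < n and pep[k] == motif[j]:
                    s += energy[j]
            if s > top:
                top = s
        best[i] = top
    return best


def _composition_term(peptides: list[str], ls: SyntheticLandscape) -> np.ndarray:
    if not ls.composition_coeffs:
        return np.zeros(len(peptides))
    out = np.zeros(len(peptides))
    for i, pep in enumerate(peptides):
        out[i] = sum(ls.composition_coeffs.get(aa, 0.0) * pep.count(aa) for aa in set(pep))
    return out


def expected_counts(landscape: SyntheticLandscape, peptides: list[str]) -> np.ndarray:
    """Noise-free expected counts, peptides x concentrations (unclipped)."""
    aff = affinity_batch(landscape, peptides)
    conc = np.asarray(landscape.concentrations)
    return landscape.baseline_counts + landscape.gain * conc[None, :] * 10.0 ** aff[:, None]


def simulate_binding(landscape: SyntheticLandscape, library: list[str]):
    """Simulate the full assay: counts (n x conc x replicate), seeded.

    Replicate counts are ``round(mu * 10**eps)`` with
    ``eps ~ Normal(0, noise_sigma)``, clipped to ``[1, saturation_cap]``.
    The returned :class:`~epibind.array_io.ArrayDataset` carries the
    landscape so recovery tests can consult the ground truth.
    """
    from .array_io import ArrayDataset

    if not library:
        raise ValueError("library must be nonempty")
    rng = np.random.default_rng(landscape.seed)
    mu = expected_counts(landscape, library)  # n x C
    n, c = mu.shape
    r = landscape.n_replicates
    eps = rng.normal(0.0, landscape.noise_sigma, size=(n, c, r)) if landscape.noise_sigma > 0 else np.zeros((n, c, r))
    counts = np.rint(mu[:, :, None] * 10.0**eps)
    counts = np.clip(counts, 1, landscape.saturation_cap).astype(np.int64)
    return ArrayDataset(
        sequences=list(library),
        concentrations=tuple(landscape.concentrations),
        counts=counts,
        saturation_cap=landscape.saturation_cap,
        landscape=landscape,
    )
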