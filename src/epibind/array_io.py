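"""Peptide-array table I/O and the raw-counts -> binding-table pipeline.

Raw assay data is a peptide x concentration x replicate grid of integer
fluorescence counts.  The modeling input is a *binding table*: one row per
unique peptide with the mean of the log10 replicate counts at each of the
four concentrations, optionally saturation-corrected (a cell pinned at the
16-bit detector ceiling is replaced by the next-lower-concentration value
plus log10 of the concentration ratio, assuming linear scaling with
concentration), length-filtered to 5-11 residues, and with the antibody's
cognate sequences excluded from training.

Table format (UTF-8 TSV, ``#``-prefixed metadata comment lines allowed):
column 1 ``sequence``; raw files have columns ``c{conc}_r{rep}`` with
integer counts; averaged files have columns ``c{conc}`` with 6-decimal
log10 values.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoding import AMINO_ACIDS
from .synthetic import SATURATION_CAP

#: A cell counts as saturated iff its averaged log10 value reaches the cap
#: within this tolerance (replicate averaging can land just below the cap).
SATURATION_TOL = 1e-9


class FormatError(ValueError):
    pass


@dataclass
class ArrayDataset:
    """Raw counts: peptide x concentration x replicate."""

    sequences: list[str]
    concentrations: tuple[float, ...]
    counts: np.ndarray  # (n, n_conc, n_rep) int
    saturation_cap: int = SATURATION_CAP
    control_flags: np.ndarray | None = None
    cognate_flags: np.ndarray | None = None
    landscape: object | None = None  # ground truth when simulated

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, c, r = self.counts.shape
        if n != len(self.sequences) or c != len(self.concentrations) or r < 1:
            raise FormatError("counts shape inconsistent with metadata")
        if self.counts.min() < 1:
            raise FormatError("counts must be >= 1")
        if self.counts.max() > self.saturation_cap:
            raise FormatError(
                f"count {self.counts.max()} exceeds saturation cap {self.saturation_cap}"
            )

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[2]


@dataclass
class BindingTable:
    """Averaged log10 binding: peptide x concentration, with provenance flags."""

    sequences: list[str]
    concentrations: tuple[float, ...]
    values: np.ndarray  # (n, n_conc) float, log10 scale
    saturation_substituted: np.ndarray = field(default=None)  # bool same shape
    landscape: object | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sequences), len(self.concentrations)):
            raise FormatError("values shape inconsistent with metadata")
        if self.saturation_substituted is None:
            self.saturation_substituted = np.zeros(self.values.shape, dtype=bool)

    def __len__(self) -> int:
        return len(self.sequences)

    def take(self, index: np.ndarray) -> "BindingTable":
        """Row subset in the given order; values untouched."""
        index = np.asarray(index)
        return replace(
            self,
            sequences=[self.sequences[i] for i in index],
            values=self.values[index],
            saturation_substituted=self.saturation_substituted[index],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[_conc_col(c) for c in self.concentrations])
        df.insert(0, "sequence", self.sequences)
        return df


def _conc_col(conc: float) -> str:
    return f"c{conc:g}"


def _raw_col(conc: float, rep: int) -> str:
    return f"c{conc:g}_r{rep + 1}"


# ---------------------------------------------------------------- I/O


def write_array_table(ds: ArrayDataset, path, comment: str = "") -> None:
    n, c, r = ds.counts.shape
    cols = {"sequence": ds.sequences}
    for j, conc in enumerate(ds.concentrations):
        for k in range(r):
            cols[_raw_col(conc, k)] = ds.counts[:, j, k]
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# epibind v0.1 array table{'; ' + comment if comment else ''}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_array_table(path, saturation_cap: int = SATURATION_CAP) -> ArrayDataset:
    """Parse a raw TSV count table; lossless round-trip with the writer.

    Unparseable rows are reported with their line numbers in one
    :class:`FormatError` listing every offender.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    while body_start < len(lines) and lines[body_start].startswith("#"):
        body_start += 1
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), sep="\t", dtype=str)
    if "sequence" not in df.columns:
        raise FormatError(f"{path}: missing 'sequence' column")
    raw_cols = [c for c in df.columns if c != "sequence"]
    concs: dict[float, list[str]] = {}
    for col in raw_cols:
        try:
            conc_part, rep_part = col.split("_")
            conc = float(conc_part[1:])
            int(rep_part[1:])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: unrecognized column {col!r}") from None
        concs.setdefault(conc, []).append(col)
    concentrations = tuple(sorted(concs))
    n_rep = {len(v) for v in concs.values()}
    if len(n_rep) != 1:
        raise FormatError(f"{path}: unequal replicate counts per concentration")

    errors: list[str] = []
    header_offset = body_start + 2  # comment lines + header, 1-based data rows
    seqs = df["sequence"].tolist()
    seen: dict[str, int] = {}
    for i, s in enumerate(seqs):
        if not isinstance(s, str) or set(s) - set(AMINO_ACIDS):
            errors.append(f"line {i + header_offset}: bad sequence {s!r}")
        elif s in seen:
            errors.append(f"line {i + header_offset}: duplicate sequence {s!r}")
        else:
            seen[s] = i
    counts = np.empty((len(df), len(concentrations), len(next(iter(concs.values())))), dtype=np.int64)
    for j, conc in enumerate(concentrations):
        for k, col in enumerate(sorted(concs[conc])):
            for i, v in enumerate(df[col]):
                try:
                    iv = int(v)
                except (TypeError, ValueError):
                    errors.append(f"line {i + header_offset}: non-integer count {v!r} in {col}")
                    iv = 1
                if iv > saturation_cap:
                    errors.append(
                        f"line {i + header_offset}: count {iv} exceeds cap {saturation_cap}"
                    )
                counts[i, j, k] = iv
    if errors:
        raise FormatError(f"{path}: " + "; ".join(errors))
    return ArrayDataset(
        sequences=seqs,
        concentrations=concentrations,
        counts=counts,
        saturation_cap=saturation_cap,
    )


def write_binding_table(bt: BindingTable, path, comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# epibind v0.1 binding table{'; ' + comment if comment else ''}\n")
        bt.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_binding_table(path) -> BindingTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    conc = tuple(float(c[1:]) for c in df.columns if c != "sequence")
    return BindingTable(
        sequences=df["sequence"].tolist(),
        concentrations=conc,
        values=df.drop(columns="sequence").to_numpy(float),
    )


# ---------------------------------------------------------------- pipeline


def average_replicates(ds: ArrayDataset) -> BindingTable:
    """Mean of the log10 replicate counts per cell; no outlier removal.

    Exact duplicate sequences are collapsed by averaging their log10
    values (the library nominally holds unique peptides, but control and
    cognate probes may appear in multiple copies).
    """
    logs = np.log10(ds.counts.astype(float))
    values = logs.mean(axis=2)
    seqs = ds.sequences
    if len(set(seqs)) != len(seqs):
        order: dict[str, list[int]] = {}
        for i, s in enumerate(seqs):
            order.setdefault(s, []).append(i)
        seqs = list(order)
        values = np.vstack([values[rows].mean(axis=0) for rows in order.values()])
    return BindingTable(
        sequences=list(seqs),
        concentrations=ds.concentrations,
        values=values,
        landscape=ds.landscape,
    )


def correct_saturation(
    bt: BindingTable,
    cap: int = SATURATION_CAP,
    concentration_ratio: float | None = None,
) -> BindingTable:
    """Substitute detector-saturated cells by linear concentration scaling.

    Scanning concentrations in ascending order, a cell at/above
    ``log10(cap)`` whose next-lower-concentration cell is unsaturated (or
    already corrected) becomes that lower value + log10(ratio); corrected
    values may exceed the cap.  A saturated cell at the lowest
    concentration cannot be corrected and is left as-is with a warning.
    """
    conc = np.asarray(bt.concentrations)
    ratios = conc[1:] / conc[:-1]
    if concentration_ratio is not None:
        ratios = np.full(len(conc) - 1, concentration_ratio)
    log_cap = math.log10(cap)
    values = bt.values.copy()
    flags = bt.saturation_substituted.copy()
    saturated = values >= log_cap - SATURATION_TOL
    if saturated[:, 0].any():
        warnings.warn(
            f"{int(saturated[:, 0].sum())} cell(s) saturated at the lowest "
            "concentration; left uncorrected",
            stacklevel=2,
        )
    for j in range(1, len(conc)):
        fixable = saturated[:, j] & (~saturated[:, j - 1] | flags[:, j - 1])
        values[fixable, j] = values[fixable, j - 1] + math.log10(ratios[j - 1])
        flags[fixable, j] = True
    return replace(bt, values=values, saturation_substituted=flags)


def filter_by_length(bt: BindingTable, min_len: int = 5, max_len: int = 11) -> BindingTable:
    keep = np.array([min_len <= len(s) <= max_len for s in bt.sequences])
    if not keep.any():
        warnings.warn("length filter removed every row", stacklevel=2)
    return bt.take(np.flatnonzero(keep))


def exclude_cognates(bt: BindingTable, cognates: list[str]) -> tuple[BindingTable, int]:
    """Drop exact-match cognate rows; returns (table, number removed)."""
    drop = set(cognates)
    keep = np.array([s not in drop for s in bt.sequences])
    return bt.take(np.flatnonzero(keep)), int((~keep).sum())


def kmer_coverage(sequences: list[str], k: int, alphabet: str = AMINO_ACIDS) -> float:
    """Fraction of all |alphabet|^k k-mers occurring as a substring."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if all(len(s) < k for s in sequences):
        warnings.warn(f"no sequence of length >= {k}", stacklevel=2)
        return 0.0
    seen: set[str] = set()
    for s in sequences:
        for i in range(len(s) - k + 1):
            seen.add(s[i : i + k])
    return len(seen) / len(alphabet) ** k


def replicate_correlation(ds: ArrayDataset, threshold: float = 0.95):
    """Replicate x replicate Pearson matrix on log10 counts, pooled over
    concentrations, plus the list of pairs below the QC threshold."""
    logs = np.log10(ds.counts.astype(float))
    flat = logs.reshape(-1, ds.n_replicates)  # (n*conc, rep)
    corr = np.corrcoef(flat, rowvar=False)
    corr = np.atleast_2d(corr)
    flagged = [
        (i, j, float(corr[i, j]))
        for i in range(ds.n_replicates)
        for j in range(i + 1, ds.n_replicates)
        if corr[i, j] < threshold
    ]
    return corr, flagged
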