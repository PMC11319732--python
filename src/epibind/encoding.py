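"""Sequence framing and one-hot encoding.

Peptides (5-11 residues over the 16-letter alphabet) are framed into
fixed-width token strings: the N-terminus is marked ``(``, the C-terminus
``)``, and the remainder is padded with the blank token ``X``::

    LPGVQG     ->  (LPGVQG)XXXXX        (base width 13)
    PWRGPWARV  ->  (PWRGPWARV)XXXXXXX   (extended width 18, shift 0)
                   ...
                   XXXXX(PWRGPWARV)XX   (extended width 18, shift 5)

Register-shifted copies place the same framed peptide at 6 different
offsets within an extended window, forcing position-independent learning.
Each framed string maps to a one-hot matrix over the 19-token alphabet
(16 amino acids + ``X`` + ``(`` + ``)``), flattened position-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The 16 amino acids available on the array, in frozen order.
AMINO_ACIDS = "ADEFGHKLNPQRSVWY"

#: Full token alphabet: amino acids, pad, N-terminal mark, C-terminal mark.
TOKENS = AMINO_ACIDS + "X()"

TOKEN_INDEX = {t: i for i, t in enumerate(TOKENS)}
N_TOKENS = len(TOKENS)  # 19

MIN_LEN = 5
MAX_LEN = 11
BASE_WIDTH = MAX_LEN + 2  # "(" + 11 + ")"
N_FRAMES = 6
EXTENDED_WIDTH = BASE_WIDTH + (N_FRAMES - 1)  # 18

PAD = "X"


class EncodingError(ValueError):
    """Raised for sequences that cannot be framed or encoded."""


@dataclass(frozen=True)
class FramedSequence:
    """A peptide placed in a fixed-width token window.

    ``shift`` is the number of leading pad tokens in the extended window;
    shift 0 at base width is the canonical (unshifted) frame.
    """

    text: str
    shift: int = 0

    def __post_init__(self) -> None:
        if self.text.count("(") != 1 or self.text.count(")") != 1:
            raise EncodingError(f"malformed frame {self.text!r}")

    @property
    def width(self) -> int:
        return len(self.text)

    @property
    def peptide(self) -> str:
        """The unframed peptide (strips marks and padding)."""
        return self.text[self.text.index("(") + 1 : self.text.index(")")]


def frame(peptide: str, max_len: int = MAX_LEN) -> FramedSequence:
    """Frame a peptide at shift 0: ``(`` + peptide + ``)`` + ``X`` padding."""
    if not (MIN_LEN <= len(peptide) <= max_len):
        raise EncodingError(
            f"peptide length {len(peptide)} outside [{MIN_LEN}, {max_len}]: {peptide!r}"
        )
    bad = set(peptide) - set(AMINO_ACIDS)
    if bad:
        raise EncodingError(
            f"letters {sorted(bad)} not in the 16-letter alphabet: {peptide!r}"
        )
    text = "(" + peptide + ")" + PAD * (max_len - len(peptide))
    return FramedSequence(text=text, shift=0)


def shift_frames(fs: FramedSequence, n_frames: int = N_FRAMES) -> list[FramedSequence]:
    """All register-shifted copies of a shift-0 frame, at extended width."""
    if fs.shift != 0:
        raise EncodingError("shift_frames expects a shift-0 frame")
    return [
        FramedSequence(text=PAD * k + fs.text + PAD * (n_frames - 1 - k), shift=k)
        for k in range(n_frames)
    ]


def one_hot(fs: FramedSequence) -> np.ndarray:
    """One-hot matrix (width x 19); each row has exactly one 1."""
    idx = token_indices(fs.text)
    out = np.zeros((len(idx), N_TOKENS), dtype=np.float32)
    out[np.arange(len(idx)), idx] = 1.0
    return out


def decode(matrix: np.ndarray) -> FramedSequence:
    """Inverse of :func:`one_hot`."""
    idx = np.asarray(matrix).argmax(axis=1)
    text = "".join(TOKENS[i] for i in idx)
    shift = len(text) - len(text.lstrip(PAD))
    return FramedSequence(text=text, shift=shift)


def token_indices(text: str) -> np.ndarray:
    try:
        return np.array([TOKEN_INDEX[t] for t in text], dtype=np.uint8)
    except KeyError as exc:
        raise EncodingError(f"unknown token {exc.args[0]!r} in {text!r}") from None


def encode_batch(
    peptides: list[str], *, shifted: bool, max_len: int = MAX_LEN
) -> tuple[np.ndarray, np.ndarray]:
    """Token-index matrix for a peptide batch.

    Returns ``(indices, group)`` where ``indices`` is (rows x width) uint8 and
    ``group[i]`` is the index into ``peptides`` that row ``i`` encodes.  With
    ``shifted`` each peptide contributes 6 rows (one per register); otherwise
    one row at base width.  One-hot expansion is deferred to the model so the
    batch stays small in memory.
    """
    rows: list[np.ndarray] = []
    group: list[int] = []
    for j, pep in enumerate(peptides):
        fs = frame(pep, max_len=max_len)
        if shifted:
            for sf in shift_frames(fs):
                rows.append(token_indices(sf.text))
                group.append(j)
        else:
            rows.append(token_indices(fs.text))
            group.append(j)
    return np.vstack(rows), np.asarray(group, dtype=np.int64)


def input_width(shifted: bool) -> int:
    """Flattened one-hot length: 342 for shifted (18x19), 247 unshifted (13x19)."""
    return (EXTENDED_WIDTH if shifted else BASE_WIDTH) * N_TOKENS
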