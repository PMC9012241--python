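"""Amino-acid tokenization, length regularization and input embedding.

Proteins are read as one-letter uppercase strings.  The vocabulary covers the
20 standard amino acids plus selenocysteine (U) and pyrrolysine (O) — 22
residue tokens — together with two sentinels, MASK and PAD.  Ambiguity codes
are resolved during normalization and never receive ids of their own:

* ``B`` (Asx) -> ``D`` or ``N``, drawn with equal probability on every call;
* ``Z`` (Glx) -> ``E`` or ``Q``, likewise;
* ``X`` (unknown) -> the MASK token, since both stand for "some residue,
  infer from context".

In canonical token strings the MASK token is written as :data:`MASK_CHAR`
(``"#"``) so a sequence stays an ordinary Python string.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, take_rows

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
NONSTANDARD_RESIDUES = "UO"
RESIDUES = "".join(sorted(STANDARD_RESIDUES + NONSTANDARD_RESIDUES))
AMBIGUITY_CODES = "BZX"
MASK_CHAR = "#"


class InvalidResidueError(ValueError):
    """Raised when a sequence contains a letter outside the amino-acid alphabet."""


@dataclass(frozen=True)
class Vocabulary:
    """Stable token-id assignment: residues in sorted order, then MASK, then PAD."""

    token_to_id: dict[str, int]
    mask_id: int
    pad_id: int

    @classmethod
    def default(cls) -> "Vocabulary":
        tokens = {tok: i for i, tok in enumerate(RESIDUES)}
        mask_id = len(tokens)
        pad_id = mask_id + 1
        tokens["MASK"] = mask_id
        tokens["PAD"] = pad_id
        return cls(token_to_id=tokens, mask_id=mask_id, pad_id=pad_id)

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    @property
    def n_residues(self) -> int:
        return len(RESIDUES)

    def residue_ids(self) -> np.ndarray:
        return np.arange(self.n_residues)

    def encode_char(self, c: str) -> int:
        if c == MASK_CHAR:
            return self.mask_id
        try:
            return self.token_to_id[c]
        except KeyError:
            raise InvalidResidueError(f"unknown token {c!r}") from None

    def decode_id(self, i: int) -> str:
        if i == self.mask_id:
            return MASK_CHAR
        if i == self.pad_id:
            return "-"
        return RESIDUES[i]


@dataclass
class TokenSequence:
    """Fixed-length token ids with a validity mask.

    ``mask`` is True at real residues (including MASK tokens) and False at PAD
    positions, which form a contiguous suffix.  ``raw_length`` is the residue
    count before chopping/padding.
    """

    ids: np.ndarray
    mask: np.ndarray
    raw_length: int

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.ids.shape != self.mask.shape:
            raise ValueError("ids and mask must have identical shape")

    def __len__(self) -> int:
        return self.ids.shape[0]


_RESOLUTION = {"B": "DN", "Z": "EQ"}


def normalize_sequence(raw: str, rng: np.random.Generator) -> str:
    """Resolve ambiguity codes; return a canonical token string.

    Every B is independently re-drawn as D or N (and Z as E or Q) with equal
    probability on each call, so repeated encodings of the same record differ.
    X becomes the MASK character.  Any other letter outside the amino-acid
    alphabet raises :class:`InvalidResidueError` naming the offender.
    """
    out = []
    for pos, c in enumerate(raw):
        if c in _RESOLUTION:
            choices = _RESOLUTION[c]
            out.append(choices[int(rng.integers(2))])
        elif c == "X":
            out.append(MASK_CHAR)
        elif c in RESIDUES:
            out.append(c)
        else:
            raise InvalidResidueError(
                f"invalid residue {c!r} at position {pos}")
    return "".join(out)


def regularize_length(tokens: str, l: int, mode: str = "eval",
                      rng: np.random.Generator | None = None,
                      vocab: Vocabulary | None = None) -> TokenSequence:
    """Chop or pad a canonical token string to exactly ``l`` positions.

    Longer sequences contribute a contiguous window: a uniformly random start
    in ``train`` mode, the leading window in ``eval`` mode (deterministic).
    Shorter sequences get PAD appended; the mask marks PAD positions False.
    """
    if l <= 0:
        raise ValueError(f"target length must be positive: {l}")
    if not tokens:
        raise ValueError("empty sequence")
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval': {mode!r}")
    vocab = vocab or Vocabulary.default()
    n = len(tokens)
    if n > l:
        if mode == "train":
            if rng is None:
                raise ValueError("train-mode chopping requires an rng")
            start = int(rng.integers(0, n - l + 1))
        else:
            start = 0
        window = tokens[start:start + l]
    else:
        window = tokens
    ids = np.full(l, vocab.pad_id, dtype=np.int64)
    mask = np.zeros(l, dtype=bool)
    for j, c in enumerate(window):
        ids[j] = vocab.encode_char(c)
        mask[j] = True
    return TokenSequence(ids=ids, mask=mask, raw_length=n)


def positional_encoding(l: int, f: int) -> np.ndarray:
    """Sinusoidal positional encoding: PE[pos, 2i] = sin(pos / 10000^(2i/f)),
    PE[pos, 2i+1] = cos of the same argument.  Deterministic, parameter-free."""
    if f % 2 != 0:
        raise ValueError(f"feature dimension must be even: {f}")
    if l < 1:
        raise ValueError(f"length must be >= 1: {l}")
    pos = np.arange(l, dtype=np.float64)[:, None]
    i = np.arange(f // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / f)
    pe = np.empty((l, f))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def embed(seq: TokenSequence, table: Tensor | np.ndarray, f: int,
          projection=None, pe: np.ndarray | None = None) -> Tensor:
    """Token embedding scaled by sqrt(f) plus positional encoding.

    ``table`` has one row per vocabulary id.  When the table's embedding width
    differs from the model dimension ``f``, a ``projection`` callable
    (a learned linear map) must bridge the two before the positional encoding
    is added.  PAD rows are exactly zero: no embedding, no positional term.
    """
    if not isinstance(table, Tensor):
        table = Tensor(table)
    ids = np.asarray(seq.ids)
    if ids.max() >= table.shape[0]:
        raise IndexError(f"token id {int(ids.max())} outside embedding table "
                         f"of size {table.shape[0]}")
    emb = take_rows(table, ids)
    if projection is not None:
        emb = projection(emb)
    if emb.shape[-1] != f:
        raise ValueError(f"embedding width {emb.shape[-1]} != model dimension {f} "
                         "(pass a projection)")
    l = ids.shape[-1]
    if pe is None:
        pe = positional_encoding(l, f)
    valid = seq.mask.astype(np.float64)[..., None]
    return (emb * np.sqrt(f) + Tensor(pe)) * Tensor(valid)
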