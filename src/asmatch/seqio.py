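"""Sequence I/O and numeric encoding.

Defines the alphabet contract used by every other module: DNA over
{A, C, G, T} plus IUPAC ambiguity codes, one-hot encoded as an L x 4
row-stochastic matrix with the fixed column order A, C, G, T.  Ambiguous
bases become uniform fractional rows over their compatible bases, which
keeps each per-position match reward p . s^T inside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Fixed column order of the one-hot encoding.  Recorded in saved model
#: files so that embeddings are portable across installations.
ALPHABET = "ACGT"

# IUPAC nucleotide codes -> compatible unambiguous bases.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COL = {b: i for i, b in enumerate(ALPHABET)}

# Precomputed fractional row per IUPAC code.
_ROWS = {}
for _code, _bases in IUPAC_CODES.items():
    _row = np.zeros(4)
    for _b in _bases:
        _row[_COL[_b]] = 1.0 / len(_bases)
    _ROWS[_code] = _row

#: Fixed numbering of the 15 IUPAC codes; index 15 is padding (all-zero
#: row, zero reward against any pattern).
CODE_ORDER = "ACGTRYSWKMBDHVN"
PAD_CODE = 15
CODE_ROWS = np.zeros((16, 4))
for _i, _c in enumerate(CODE_ORDER):
    CODE_ROWS[_i] = _ROWS[_c]
_CODE_INDEX = {c: i for i, c in enumerate(CODE_ORDER)}


def encode_codes(seq: Union["Sequence", str]) -> np.ndarray:
    """Encode residues as IUPAC code indices (rows of ``CODE_ROWS``).

    Equivalent information to :func:`one_hot_encode` in O(L) integers;
    the batched scoring kernels index small per-code tables with it.
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    try:
        return np.array([_CODE_INDEX[c] for c in residues], dtype=np.int64)
    except KeyError as e:
        raise EncodingError(f"invalid residue {e.args[0]!r}") from None


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed into valid sequences."""


class EncodingError(ValueError):
    """Raised when a residue falls outside the DNA + IUPAC alphabet."""


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide sequence (uppercase, DNA alphabet, U already
    mapped to T)."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"empty sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OneHotSeq:
    """L x 4 row-stochastic encoding of a sequence."""

    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] == 0:
            raise ValueError(f"expected L x 4 matrix, got shape {m.shape}")

    def __len__(self) -> int:
        return self.matrix.shape[0]


def _normalize(residues: str, *, origin: str) -> str:
    s = residues.upper().replace("U", "T")
    for pos, ch in enumerate(s, start=1):
        if ch not in IUPAC_CODES:
            raise EncodingError(
                f"invalid residue {ch!r} at position {pos} in {origin}"
            )
    return s


def read_fasta(path: Union[str, Path]) -> List[Sequence]:
    """Read a FASTA file into a list of :class:`Sequence`.

    Residues are uppercased and U is mapped to T.  Empty records and
    characters outside the DNA + IUPAC alphabet raise
    :class:`FastaParseError` naming the offending record.
    """
    path = Path(path)
    out: List[Sequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"empty record {rec.id!r} in {path}")
        try:
            residues = _normalize(str(rec.seq), origin=f"record {rec.id!r}")
        except EncodingError as e:
            raise FastaParseError(str(e)) from e
        out.append(Sequence(id=rec.id, residues=residues))
    return out


def write_fasta(seqs: Iterable[Sequence], path: Union[str, Path]) -> None:
    """Write sequences as single-line FASTA records.

    Round-trips with :func:`read_fasta`.
    """
    path = Path(path)
    records = []
    for s in seqs:
        if not s.id:
            raise ValueError("sequence id must be nonempty")
        records.append(SeqRecord(Seq(s.residues), id=s.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)


def one_hot_encode(seq: Union[Sequence, str]) -> OneHotSeq:
    """Encode a sequence as an L x 4 matrix (columns A, C, G, T).

    Unambiguous bases give indicator rows; IUPAC ambiguity codes give the
    uniform fractional vector over their compatible bases, e.g.
    N -> [1/4, 1/4, 1/4, 1/4] and R -> [1/2, 0, 1/2, 0].
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if not residues:
        raise ValueError("cannot encode an empty sequence")
    rows = np.empty((len(residues), 4))
    for i, ch in enumerate(residues):
        row = _ROWS.get(ch)
        if row is None:
            raise EncodingError(f"invalid residue {ch!r} at position {i + 1}")
        rows[i] = row
    return OneHotSeq(matrix=rows)
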