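"""Alignment ground truth: affine-gap Needleman-Wunsch and hard ASM.

This module supplies the supervision signal for training (the alignment
distance ``d_a``) and the exact, non-smoothed approximate-string-matching
dynamic program that the learnable layer relaxes.  The hard ASM recursion
doubles as the reference implementation that the smoothed layer is tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple, Union

import numpy as np
from Bio import Align

from .seqio import Sequence

GAP = "-"


@dataclass(frozen=True)
class NWScoring:
    """Affine-gap global alignment scores.

    A gap run of length k costs ``gap_open + (k - 1) * gap_extend``: the
    opening score covers the first gapped column.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    #: fraction of alignment columns that are not an identical pair of
    #: unambiguous bases; lies in [0, 1]
    distance: float


@dataclass(frozen=True)
class HardMatchResult:
    """Best approximate occurrence of a pattern inside a sequence."""

    min_edit_distance: int
    #: 1-based inclusive interval [start, end] into the sequence; empty
    #: (start > end) only when the optimal match deletes the whole pattern
    span: Tuple[int, int]


@lru_cache(maxsize=8)
def _aligner(scoring: NWScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def _residues(seq: Union[Sequence, str]) -> str:
    return seq.residues if isinstance(seq, Sequence) else seq


def _column_distance(a: str, b: str) -> float:
    unambiguous = set("ACGT")
    ident = sum(
        1 for x, y in zip(a, b) if x == y and x in unambiguous
    )
    return 1.0 - ident / len(a)


def nw_align(
    a: Union[Sequence, str],
    b: Union[Sequence, str],
    scoring: NWScoring = NWScoring(),
) -> AlignmentResult:
    """Optimal affine-gap global alignment (Gotoh three-state DP).

    The traceback is deterministic (first alignment in the aligner's fixed
    enumeration order).  A column counts toward identity only when both
    residues are the same unambiguous base.
    """
    ra, rb = _residues(a), _residues(b)
    if not ra or not rb:
        raise ValueError("both sequences must be nonempty")
    res = _aligner(scoring).align(ra, rb)
    aln = res[0]
    ga, gb = str(aln[0]), str(aln[1])
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        score=float(res.score),
        distance=_column_distance(ga, gb),
    )


def alignment_distance(
    a: Union[Sequence, str],
    b: Union[Sequence, str],
    scoring: NWScoring = NWScoring(),
) -> float:
    """Alignment distance d_a in [0, 1].

    d_a = 1 - (identical unambiguous columns / alignment length) computed
    on the optimal global alignment; 0 iff the sequences are identical,
    symmetric in its arguments.
    """
    return nw_align(a, b, scoring).distance


def hard_asm(
    pattern: Union[Sequence, str], seq: Union[Sequence, str]
) -> HardMatchResult:
    """Minimum edit distance between a pattern and any contiguous window
    of a sequence, with the matched window's coordinates.

    Builds the (M+1) x (L+1) scoring matrix with a free start (first row
    zero) and free end (answer read off the last row):
    F(0, l) = 0, F(m, 0) = -m, interior cell the max of
    {diag - c, up - 1, left - 1} with c = 0 on an exact base match else 1.
    The last-row argmax takes the smallest column on ties; traceback
    branch ties break diagonal > up > left.
    """
    p, s = _residues(pattern), _residues(seq)
    M, L = len(p), len(s)
    if M < 1 or L < 1:
        raise ValueError("pattern and sequence must be nonempty")

    F = np.zeros((M + 1, L + 1), dtype=np.int64)
    F[1:, 0] = -np.arange(1, M + 1)
    for m in range(1, M + 1):
        for l in range(1, L + 1):
            c = 0 if p[m - 1] == s[l - 1] else 1
            F[m, l] = max(F[m - 1, l - 1] - c, F[m - 1, l] - 1, F[m, l - 1] - 1)

    end = int(np.argmax(F[M]))  # ties -> smallest column
    best = int(F[M, end])

    # Backtrack to the first row; the consumed columns form the span.
    m, l = M, end
    while m > 0:
        if l == 0:
            m -= 1
            continue
        c = 0 if p[m - 1] == s[l - 1] else 1
        v = F[m, l]
        if F[m - 1, l - 1] - c == v:
            m, l = m - 1, l - 1
        elif F[m - 1, l] - 1 == v:
            m -= 1
        else:
            l -= 1
    return HardMatchResult(min_edit_distance=-best, span=(l + 1, end))


def brute_force_asm_oracle(
    pattern: Union[Sequence, str], seq: Union[Sequence, str]
) -> int:
    """Independent oracle for :func:`hard_asm` on small instances.

    Minimizes, over every contiguous window of the sequence (including the
    empty window), the textbook edit distance between the pattern and the
    window, each computed by a separate quadratic DP.  Exponentially many
    windows make this O(M L^3); keep M*L small.
    """
    p, s = _residues(pattern), _residues(seq)
    M, L = len(p), len(s)
    best = M  # empty window: delete the whole pattern
    for i in range(L):
        for j in range(i + 1, L + 1):
            best = min(best, _edit_distance(p, s[i:j]))
    return best


def _edit_distance(a: str, b: str) -> int:
    # textbook Wagner-Fischer, independent of the hard_asm recursion
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j - 1] + (a[i - 1] != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[lb]
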