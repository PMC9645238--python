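"""The smoothed approximate-string-matching layer.

A pattern is an M x 4 real matrix; scored against a one-hot sequence it
plays the role of a learnable motif.  The hard ASM recursion is relaxed by
(i) replacing the 0/1 substitution cost with the per-position reward
p_m . s_l^T, (ii) making the unit gap cost a learnable penalty g > 0, and
(iii) replacing max with the generalized operator

    max_gamma(a_1..a_J) = gamma * log sum_j exp(a_j / gamma),

a smooth upper bound on the hard max that converges to it as gamma -> 0.
The embedding of a sequence is u = ReLU(v + b), where v_n is the maximum
of the last row of pattern n's scoring matrix.

Two code paths compute the same recursion: a plain per-pattern reference
(`soft_asm_forward`) and a batch over all patterns and several sequences
at once (`soft_asm_batch` / `embed_batch`), which runs anti-diagonal by
anti-diagonal in the rescaled exponent domain (see `_kernels`) with a
log-domain fallback when gamma is too small for that representation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence as TSequence, Tuple, Union

import numpy as np

from .seqio import (
    ALPHABET,
    CODE_ROWS,
    PAD_CODE,
    OneHotSeq,
    Sequence,
    encode_codes,
    one_hot_encode,
)


@dataclass
class PatternSet:
    """Learnable parameters of the embedding map.

    Attributes
    ----------
    patterns : (N, M, 4) array
        N pattern matrices, one row per pattern position.
    gap_penalty : float
        Shared positive gap cost g.
    bias : (N,) array
        Bias b added to the score vector before the ReLU.
    gamma : float
        Smoothing temperature of the generalized max.
    alphabet_order : str
        Column order of the one-hot encoding the patterns were trained
        against.
    """

    patterns: np.ndarray
    gap_penalty: float
    bias: np.ndarray
    gamma: float = 0.1
    alphabet_order: str = ALPHABET

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.patterns.ndim != 3 or self.patterns.shape[2] != 4:
            raise ValueError("patterns must have shape (N, M, 4)")
        if self.bias.shape != (self.patterns.shape[0],):
            raise ValueError("bias must have shape (N,)")
        if self.gap_penalty <= 0:
            raise ValueError("gap penalty must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def pattern_len(self) -> int:
        return self.patterns.shape[1]

    def copy(self) -> "PatternSet":
        return replace(
            self, patterns=self.patterns.copy(), bias=self.bias.copy()
        )


@dataclass(frozen=True)
class SoftScoreMatrix:
    """Filled (M+1) x (L+1) soft scoring matrix for one pattern."""

    F: np.ndarray
    #: hard max of the last row
    v: float
    #: column index of that max (ties -> smallest column)
    argmax_col: int


def soft_max_gamma(values, gamma: float) -> float:
    """gamma * log sum_j exp(a_j / gamma), computed stably.

    Satisfies max(a) <= result <= max(a) + gamma * log J.
    """
    a = np.asarray(values, dtype=np.float64)
    if a.size == 0:
        raise ValueError("soft_max_gamma of an empty list")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    m = np.max(a)
    return float(m + gamma * np.log(np.sum(np.exp((a - m) / gamma))))


def _as_onehot(seq: Union[Sequence, OneHotSeq, str]) -> np.ndarray:
    if isinstance(seq, OneHotSeq):
        return seq.matrix
    return one_hot_encode(seq).matrix


def soft_asm_forward(
    P: np.ndarray,
    S: Union[Sequence, OneHotSeq, str],
    g: float,
    gamma: float,
) -> SoftScoreMatrix:
    """Fill the soft ASM scoring matrix for a single pattern.

    Boundary: F(0, l) = 0 (free start), F(m, 0) = -m g.  Interior cells
    combine the diagonal branch F(m-1, l-1) + p_m . s_l^T with the two gap
    branches F(m-1, l) - g and F(m, l-1) - g under the generalized max.
    v is the hard maximum of the last row.
    """
    P = np.asarray(P, dtype=np.float64)
    S = _as_onehot(S)
    M, L = P.shape[0], S.shape[0]
    reward = P @ S.T  # (M, L)

    F = np.zeros((M + 1, L + 1))
    F[1:, 0] = -g * np.arange(1, M + 1)
    for m in range(1, M + 1):
        for l in range(1, L + 1):
            F[m, l] = soft_max_gamma(
                (
                    F[m - 1, l - 1] + reward[m - 1, l - 1],
                    F[m - 1, l] - g,
                    F[m, l - 1] - g,
                ),
                gamma,
            )
    col = int(np.argmax(F[M]))
    return SoftScoreMatrix(F=F, v=float(F[M, col]), argmax_col=col)


def hard_max_asm_score(
    P: np.ndarray, S: Union[Sequence, OneHotSeq, str], g: float
) -> float:
    """gamma -> 0 limit of the soft recursion (exact max); test oracle."""
    P = np.asarray(P, dtype=np.float64)
    S = _as_onehot(S)
    M, L = P.shape[0], S.shape[0]
    if M == 0:
        return 0.0
    reward = P @ S.T
    F = np.zeros((M + 1, L + 1))
    F[1:, 0] = -g * np.arange(1, M + 1)
    for m in range(1, M + 1):
        for l in range(1, L + 1):
            F[m, l] = max(
                F[m - 1, l - 1] + reward[m - 1, l - 1],
                F[m - 1, l] - g,
                F[m, l - 1] - g,
            )
    return float(np.max(F[M]))


def best_match_span(
    F_or_result: Union[SoftScoreMatrix, np.ndarray],
    g: float,
    gamma: float,
    P: np.ndarray,
    S: Union[Sequence, OneHotSeq, str],
) -> Tuple[int, int]:
    """Backtrack the best-matched window of the sequence.

    Starting from (M, argmax_col), at each cell the branch whose argument
    (diagonal / up / left, as in the forward recursion) is largest is
    followed, ties broken diagonal > up > left, until the first row is
    reached.  Returns the consumed column interval as a 1-based inclusive
    (start, end); start > end denotes the empty window.
    """
    if isinstance(F_or_result, SoftScoreMatrix):
        F, end = F_or_result.F, F_or_result.argmax_col
    else:
        F = np.asarray(F_or_result)
        end = int(np.argmax(F[-1]))
    P = np.asarray(P, dtype=np.float64)
    S = _as_onehot(S)
    M = F.shape[0] - 1
    reward = P @ S.T

    m, l = M, end
    while m > 0:
        if l == 0:
            m -= 1
            continue
        diag = F[m - 1, l - 1] + reward[m - 1, l - 1]
        up = F[m - 1, l] - g
        left = F[m, l - 1] - g
        if diag >= up and diag >= left:
            m, l = m - 1, l - 1
        elif up >= left:
            m -= 1
        else:
            l -= 1
    return (l + 1, end)


# ---------------------------------------------------------------------------
# batched forward
# ---------------------------------------------------------------------------

def pad_codes(
    seqs: TSequence[Union[Sequence, str, np.ndarray]],
) -> Tuple[np.ndarray, np.ndarray]:
    """Encode and stack variable-length sequences into an (S, Lmax) code
    matrix plus true lengths.

    Entries are IUPAC code indices (see `seqio.CODE_ORDER`); padding uses
    the zero-reward code, which the batched forward never reads past each
    sequence's own length.
    """
    arrays = [
        s if isinstance(s, np.ndarray) else encode_codes(s) for s in seqs
    ]
    lengths = np.array([a.shape[0] for a in arrays], dtype=np.int64)
    Lmax = int(lengths.max())
    out = np.full((len(arrays), Lmax), PAD_CODE, dtype=np.int64)
    for i, a in enumerate(arrays):
        out[i, : a.shape[0]] = a
    return out, lengths


#: largest |value| / gamma the exponent-domain recursion can represent;
#: beyond it the batched forward switches to the log-domain path
_EXP_DOMAIN_BOUND = 600.0


def _reward_table(patterns: np.ndarray) -> np.ndarray:
    """(16, M, N) table of p_m . row(c)^T — every reward the DP can see."""
    return np.ascontiguousarray(
        np.einsum("ca,nma->cmn", CODE_ROWS, patterns)
    )


def _exp_domain_safe(reward_tab: np.ndarray, g: float, gamma: float) -> bool:
    return (
        max(float(np.abs(reward_tab).max(initial=0.0)), abs(g)) / gamma
        <= _EXP_DOMAIN_BOUND
    )


def _forward_core(
    patterns: np.ndarray,
    codes: np.ndarray,
    lengths: np.ndarray,
    g: float,
    gamma: float,
):
    """Batched forward pass in the scaled exponent domain.

    Returns (reward_tab, E, sc, v, argcol): reward_tab is the (16, M, N)
    per-IUPAC-code reward table and E/sc the scaled per-anti-diagonal
    buffers of `_kernels.forward_exp`.  When |reward|/gamma exceeds the
    representable exponent range (tiny gamma or huge patterns), E and sc
    are None and v/argcol come from the log-domain path instead.
    """
    from ._kernels import forward_exp

    patterns = np.asarray(patterns, dtype=np.float64)
    reward_tab = _reward_table(patterns)
    if not _exp_domain_safe(reward_tab, g, gamma):
        F, v, argcol = _forward_logspace(reward_tab, codes, lengths, g, gamma)
        return reward_tab, None, None, v, argcol
    exp_tab = np.exp(reward_tab / gamma)
    E, sc, v, argcol = forward_exp(
        exp_tab, codes, np.asarray(lengths, dtype=np.int64),
        patterns.shape[1], g, gamma,
    )
    return reward_tab, E, sc, v, argcol


def _forward_logspace(
    reward_tab: np.ndarray,
    codes: np.ndarray,
    lengths: np.ndarray,
    g: float,
    gamma: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-domain anti-diagonal forward (stable for any gamma); returns
    the full F plus last-row max and argmax."""
    _, M, N = reward_tab.shape
    S, Lmax = codes.shape
    # reward[s, n, m, l]
    reward = np.ascontiguousarray(
        reward_tab[codes].transpose(0, 3, 2, 1)
    )
    F = np.zeros((S, N, M + 1, Lmax + 1))
    F[:, :, 1:, 0] = -g * np.arange(1, M + 1)
    for d in range(2, M + Lmax + 1):
        m0, m1 = max(1, d - Lmax), min(M, d - 1)
        if m0 > m1:
            continue
        ms = np.arange(m0, m1 + 1)
        ls = d - ms
        b_diag = F[:, :, ms - 1, ls - 1] + reward[:, :, ms - 1, ls - 1]
        b_up = F[:, :, ms - 1, ls] - g
        b_left = F[:, :, ms, ls - 1] - g
        mx = np.maximum(b_diag, np.maximum(b_up, b_left))
        acc = np.exp((b_diag - mx) / gamma)
        acc += np.exp((b_up - mx) / gamma)
        acc += np.exp((b_left - mx) / gamma)
        F[:, :, ms, ls] = mx + gamma * np.log(acc)
    invalid = np.arange(Lmax + 1)[None, :] > lengths[:, None]
    last = np.where(invalid[:, None, :], -np.inf, F[:, :, M, :])
    argcol = np.argmax(last, axis=2)
    v = np.take_along_axis(last, argcol[:, :, None], axis=2)[:, :, 0]
    return F, v, argcol


def soft_asm_batch(
    patterns: np.ndarray,
    codes: np.ndarray,
    lengths: np.ndarray,
    g: float,
    gamma: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Soft ASM forward for every (sequence, pattern) combination.

    Parameters
    ----------
    patterns : (N, M, 4)
    codes : (S, Lmax) IUPAC code indices from :func:`pad_codes`
    lengths : (S,) true sequence lengths

    Returns
    -------
    F : (S, N, M+1, Lmax+1) filled scoring matrices
    v : (S, N) hard max of each last row (over valid columns only)
    argmax_col : (S, N) its column index (ties -> smallest)

    The recursion runs anti-diagonal by anti-diagonal in the rescaled
    exponent domain (see `_kernels.forward_exp`); the full log-domain F is
    reconstructed afterwards, so entries agree with `soft_asm_forward` up
    to floating-point rounding.
    """
    patterns = np.asarray(patterns, dtype=np.float64)
    N, M, _ = patterns.shape
    S, Lmax = codes.shape
    reward_tab = _reward_table(patterns)
    if not _exp_domain_safe(reward_tab, g, gamma):
        return _forward_logspace(reward_tab, codes, lengths, g, gamma)
    _, E, sc, v, argcol = _forward_core(patterns, codes, lengths, g, gamma)

    F = np.empty((S, N, M + 1, Lmax + 1))
    with np.errstate(divide="ignore"):
        for d in range(M + Lmax + 1):
            for m in range(max(0, d - Lmax), min(M, d) + 1):
                # (S, N) slab of cells (m, d - m)
                F[:, :, m, d - m] = gamma * (
                    np.log(E[d, :, m, :]) + sc[:, d, None]
                )
    return F, v, argcol


def embed_batch(
    seqs: TSequence[Union[Sequence, str, np.ndarray]],
    params: PatternSet,
    chunk: int = 64,
) -> np.ndarray:
    """Embed several sequences; returns an (S, N) nonnegative matrix.

    Sequences are processed in chunks to bound the memory of the batched
    DP.  Embeddings are deterministic for fixed parameters.
    """
    code_arrays = [
        s if isinstance(s, np.ndarray) else encode_codes(s) for s in seqs
    ]
    out = np.empty((len(code_arrays), params.n_patterns))
    for lo in range(0, len(code_arrays), chunk):
        codes, lengths = pad_codes(code_arrays[lo : lo + chunk])
        _, _, _, v, _ = _forward_core(
            params.patterns, codes, lengths, params.gap_penalty, params.gamma
        )
        out[lo : lo + codes.shape[0]] = np.maximum(v + params.bias, 0.0)
    return out


def embed(seq: Union[Sequence, str], params: PatternSet) -> np.ndarray:
    """Embedding u = ReLU(v + b) of one sequence; (N,) nonnegative."""
    return embed_batch([seq], params)[0]
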