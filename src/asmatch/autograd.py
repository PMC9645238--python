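"""Analytic gradients of the smoothed ASM score.

The score v of a pattern against a sequence is, by construction, the
global-alignment score between the pattern and its best-matched window
S-tilde of the sequence.  Gradients are therefore computed on a small
differentiable Needleman-Wunsch matrix F-tilde built over that window
only (both boundaries gap-penalized), which keeps the backward pass
O(M * L-tilde) per pattern instead of O(M * L):

* dF/dp_m at cell (m, l) is exp((F(m-1,l-1) + p_m.s_l - F(m,l)) / gamma) * s_l,
  i.e. the diagonal-branch softmax weight times the one-hot column;
* dF(M, Lt)/dF(m, l) is accumulated backward through each cell's three
  downstream neighbours;
* dF/dg is accumulated forward, seeding the boundaries with -m and -l and
  weighting the two gap branches by (child - 1) and the diagonal branch
  by (child).

Gradients do not flow through the choice of the window itself, nor
through the last-row argmax: both are treated as fixed once the forward
pass has selected them (a subgradient of the hard max).

The module also carries the full loss chain rule for one training pair
(`loss_backward`); the mini-batch trainer uses the compiled kernels in
`_kernels` which implement the identical recursions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .seqio import OneHotSeq, one_hot_encode
from .asmnet import PatternSet, best_match_span, soft_asm_forward

EPS_NORM = 1e-8  # epsilon guard of the cosine distance


@dataclass
class Gradients:
    """Gradient of a scalar loss with respect to every parameter."""

    patterns: np.ndarray  # (N, M, 4)
    gap: float
    bias: np.ndarray  # (N,)


def _as_matrix(S) -> np.ndarray:
    if isinstance(S, OneHotSeq):
        return S.matrix
    if isinstance(S, np.ndarray):
        return S
    return one_hot_encode(S).matrix


def diff_nw_forward(
    P: np.ndarray, S_tilde, g: float, gamma: float
) -> np.ndarray:
    """Differentiable NW matrix over the best-matched window.

    Same three branches as the soft ASM recursion but with global
    boundary conditions F(m, 0) = -m g and F(0, l) = -l g.  Returns the
    full (M+1) x (Lt+1) matrix; its bottom-right entry approximates v.
    """
    P = np.asarray(P, dtype=np.float64)
    St = _as_matrix(S_tilde)
    M, Lt = P.shape[0], St.shape[0]
    reward = P @ St.T if Lt else np.zeros((M, 0))

    F = np.zeros((M + 1, Lt + 1))
    F[1:, 0] = -g * np.arange(1, M + 1)
    F[0, 1:] = -g * np.arange(1, Lt + 1)
    for m in range(1, M + 1):
        for l in range(1, Lt + 1):
            b = np.array(
                [
                    F[m - 1, l - 1] + reward[m - 1, l - 1],
                    F[m - 1, l] - g,
                    F[m, l - 1] - g,
                ]
            )
            mx = b.max()
            F[m, l] = mx + gamma * np.log(np.exp((b - mx) / gamma).sum())
    return F


def branch_weights(
    F: np.ndarray, P: np.ndarray, S_tilde, g: float, gamma: float,
    m: int, l: int,
) -> Tuple[float, float, float]:
    """Softmax weights (diag, up, left) of cell (m, l) of F-tilde.

    These are the local derivatives of the generalized max with respect
    to its three arguments; they are nonnegative and sum to one.
    """
    P = np.asarray(P, dtype=np.float64)
    St = _as_matrix(S_tilde)
    r = float(P[m - 1] @ St[l - 1])
    w_diag = np.exp((F[m - 1, l - 1] + r - F[m, l]) / gamma)
    w_up = np.exp((F[m - 1, l] - g - F[m, l]) / gamma)
    w_left = np.exp((F[m, l - 1] - g - F[m, l]) / gamma)
    return float(w_diag), float(w_up), float(w_left)


def _all_branch_weights(
    F: np.ndarray, reward: np.ndarray, g: float, gamma: float
) -> np.ndarray:
    """(M+1, Lt+1, 3) weights for every interior cell (zeros elsewhere)."""
    M, Lt = F.shape[0] - 1, F.shape[1] - 1
    w = np.zeros((M + 1, Lt + 1, 3))
    if M == 0 or Lt == 0:
        return w
    core = F[1:, 1:]
    w[1:, 1:, 0] = np.exp((F[:-1, :-1] + reward - core) / gamma)
    w[1:, 1:, 1] = np.exp((F[:-1, 1:] - g - core) / gamma)
    w[1:, 1:, 2] = np.exp((F[1:, :-1] - g - core) / gamma)
    return w


def _terminal_sensitivities(w: np.ndarray) -> np.ndarray:
    """E(m, l) = dF(M, Lt)/dF(m, l) by the backward recursion."""
    M, Lt = w.shape[0] - 1, w.shape[1] - 1
    E = np.zeros((M + 1, Lt + 1))
    E[M, Lt] = 1.0
    for m in range(M, -1, -1):
        for l in range(Lt, -1, -1):
            if m == M and l == Lt:
                continue
            acc = 0.0
            if m + 1 <= M:
                acc += E[m + 1, l] * w[m + 1, l, 1]
            if l + 1 <= Lt:
                acc += E[m, l + 1] * w[m, l + 1, 2]
            if m + 1 <= M and l + 1 <= Lt:
                acc += E[m + 1, l + 1] * w[m + 1, l + 1, 0]
            E[m, l] = acc
    return E


def grad_pattern(
    P: np.ndarray, S_tilde, g: float, gamma: float
) -> np.ndarray:
    """(M, 4) matrix of dv/dp_m over the window S-tilde."""
    P = np.asarray(P, dtype=np.float64)
    St = _as_matrix(S_tilde)
    M, Lt = P.shape[0], St.shape[0]
    if Lt == 0:
        return np.zeros((M, 4))
    reward = P @ St.T
    F = diff_nw_forward(P, St, g, gamma)
    w = _all_branch_weights(F, reward, g, gamma)
    E = _terminal_sensitivities(w)
    # dF(m,l)/dp_m = w_diag(m,l) * s_l ; sum over l with weight E(m,l)
    coef = E[1:, 1:] * w[1:, 1:, 0]  # (M, Lt)
    return coef @ St


def grad_gap(P: np.ndarray, S_tilde, g: float, gamma: float) -> float:
    """dv/dg over the window S-tilde (forward accumulation)."""
    P = np.asarray(P, dtype=np.float64)
    St = _as_matrix(S_tilde)
    M, Lt = P.shape[0], St.shape[0]
    if Lt == 0:
        return -float(M)
    reward = P @ St.T
    F = diff_nw_forward(P, St, g, gamma)
    w = _all_branch_weights(F, reward, g, gamma)
    D = np.zeros((M + 1, Lt + 1))
    D[:, 0] = -np.arange(M + 1)
    D[0, :] = -np.arange(Lt + 1)
    for m in range(1, M + 1):
        for l in range(1, Lt + 1):
            D[m, l] = (
                w[m, l, 0] * D[m - 1, l - 1]
                + w[m, l, 1] * (D[m - 1, l] - 1.0)
                + w[m, l, 2] * (D[m, l - 1] - 1.0)
            )
    return float(D[M, Lt])


# ---------------------------------------------------------------------------
# loss chain rule for one pair
# ---------------------------------------------------------------------------

def _embed_with_spans(seq, params: PatternSet):
    """Forward one sequence through every pattern, recording spans."""
    S = _as_matrix(seq)
    N = params.n_patterns
    v = np.empty(N)
    spans = []
    for n in range(N):
        res = soft_asm_forward(
            params.patterns[n], OneHotSeq(S), params.gap_penalty, params.gamma
        )
        v[n] = res.v
        spans.append(
            best_match_span(
                res, params.gap_penalty, params.gamma,
                params.patterns[n], OneHotSeq(S),
            )
        )
    u = np.maximum(v + params.bias, 0.0)
    return S, v, u, spans


def cosine_distance_grad(
    u1: np.ndarray, u2: np.ndarray
) -> Tuple[float, np.ndarray, np.ndarray]:
    """(de, d de/d u1, d de/d u2) with the epsilon-guarded cosine."""
    n1 = float(np.linalg.norm(u1))
    n2 = float(np.linalg.norm(u2))
    denom = (n1 + EPS_NORM) * (n2 + EPS_NORM)
    dot = float(u1 @ u2)
    de = 1.0 - dot / denom
    u1_hat = u1 / n1 if n1 > 0 else np.zeros_like(u1)
    u2_hat = u2 / n2 if n2 > 0 else np.zeros_like(u2)
    d1 = -u2 / denom + dot * u1_hat / ((n1 + EPS_NORM) ** 2 * (n2 + EPS_NORM))
    d2 = -u1 / denom + dot * u2_hat / ((n2 + EPS_NORM) ** 2 * (n1 + EPS_NORM))
    return de, d1, d2


def loss_backward(pair, params: PatternSet) -> Gradients:
    """Gradient of the squared error of one training pair w.r.t. Theta.

    Chains (de - d_a)^2 through the cosine distance, the ReLU (whose mask
    also gives the bias gradient), and the per-pattern window gradients.
    Both twin branches share one parameter set, so their contributions
    are summed.
    """
    S1, v1, u1, spans1 = _embed_with_spans(pair.seq_a, params)
    S2, v2, u2, spans2 = _embed_with_spans(pair.seq_b, params)
    de, dde_du1, dde_du2 = cosine_distance_grad(u1, u2)
    dC_dde = 2.0 * (de - pair.d_a)

    dP = np.zeros_like(params.patterns)
    dg = 0.0
    db = np.zeros_like(params.bias)
    for S, v, u, spans, dde_du in (
        (S1, v1, u1, spans1, dde_du1),
        (S2, v2, u2, spans2, dde_du2),
    ):
        mask = (v + params.bias > 0).astype(float)
        coeff = dC_dde * dde_du * mask  # dC/dv_n == dC/db_n per sequence
        db += coeff
        for n in range(params.n_patterns):
            if coeff[n] == 0.0:
                continue
            lo, hi = spans[n]
            St = S[lo - 1 : hi]  # empty when lo > hi
            if St.shape[0] == 0:
                dg += coeff[n] * (-params.pattern_len)
                continue
            dP[n] += coeff[n] * grad_pattern(
                params.patterns[n], St, params.gap_penalty, params.gamma
            )
            dg += coeff[n] * grad_gap(
                params.patterns[n], St, params.gap_penalty, params.gamma
            )
    return Gradients(patterns=dP, gap=float(dg), bias=db)
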