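"""Compiled batch kernels for training and bulk embedding.

The smoothed-max recursion

    F(m,l) = max_gamma(diag + r, up - g, left - g)

becomes, in the exponent domain E = exp(F / gamma), a pure multiply-add

    E(m,l) = E(m-1,l-1) * exp(r / gamma) + exp(-g / gamma) * (E(m-1,l) + E(m,l-1)),

so `forward_exp` fills the whole (sequence, pattern) batch anti-diagonal
by anti-diagonal without per-cell transcendentals.  Each anti-diagonal is
rescaled by its maximum and the log-scale tracked per sequence (exact up
to floating-point rounding, as in scaled HMM forward passes), which keeps
the recursion inside float64 range for any parameter magnitude.

`span_grads_exp` backtracks the best-matched window per (sequence,
pattern) slot by comparing branch values in the scaled domain, then runs
the differentiable-NW forward / backward recursions over the window —
exactly what `autograd` does one window at a time.  Agreement between the
two paths is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e300  # stand-in for log(0)


@njit(cache=True)
def forward_exp(exp_tab, codes, lengths, M, g, gamma):
    """Scaled exponent-domain soft ASM forward for a whole batch.

    The per-position reward p_m . s_l takes one of at most 16 values per
    pattern row (one per IUPAC code, plus padding), so instead of a dense
    (S, L, M, N) reward tensor the kernel gathers from a cache-resident
    table.

    Parameters
    ----------
    exp_tab : (16, M, N) exp(reward / gamma) per IUPAC code index
    codes : (S, Lmax) IUPAC code indices, padded with the zero-reward code
    lengths : (S,) true lengths
    M : pattern length
    g, gamma : gap penalty and smoothing temperature

    Returns
    -------
    E : (D+1, S, M+1, N) scaled exp(F / gamma) per anti-diagonal d = m + l
    sc : (S, D+1) log-scale of each anti-diagonal
    v : (S, N) hard max of the last row of F (valid columns only)
    argcol : (S, N) its column (ties -> smallest)
    """
    S, Lmax = codes.shape
    N = exp_tab.shape[2]
    D = M + Lmax
    G = np.exp(-g / gamma)

    E = np.zeros((D + 1, S, M + 1, N))
    sc = np.zeros((S, D + 1))
    v = np.full((S, N), -g * M)  # F(M, 0) = -M g
    argcol = np.zeros((S, N), dtype=np.int64)

    for s in range(S):
        for n in range(N):
            E[0, s, 0, n] = 1.0

    for d in range(1, D + 1):
        for s in range(S):
            prev = sc[s, d - 1]
            alpha = np.exp(sc[s, d - 2] - prev) if d >= 2 else 1.0
            # boundary cells
            if d <= Lmax:
                b0 = np.exp(-prev)  # F(0, d) = 0
                for n in range(N):
                    E[d, s, 0, n] = b0
            if d <= M:
                bm = np.exp(-d * g / gamma - prev)  # F(d, 0) = -d g
                for n in range(N):
                    E[d, s, d, n] = bm
            mlo = d - Lmax if d - Lmax > 1 else 1
            mhi = M if M < d - 1 else d - 1
            for m in range(mlo, mhi + 1):
                l = d - m
                c = codes[s, l - 1]
                for n in range(N):
                    E[d, s, m, n] = (
                        E[d - 2, s, m - 1, n] * exp_tab[c, m - 1, n] * alpha
                        + G * (E[d - 1, s, m, n] + E[d - 1, s, m - 1, n])
                    )
            # rescale the diagonal by its maximum
            mx = 0.0
            for m in range(M + 1):
                for n in range(N):
                    if E[d, s, m, n] > mx:
                        mx = E[d, s, m, n]
            if mx <= 0.0:
                mx = 1.0
            inv = 1.0 / mx
            for m in range(M + 1):
                for n in range(N):
                    E[d, s, m, n] *= inv
            sc[s, d] = prev + np.log(mx)

            # last-row readout
            l = d - M
            if d >= M and 1 <= l <= lengths[s]:
                base = sc[s, d]
                for n in range(N):
                    e = E[d, s, M, n]
                    if e > 0.0:
                        f = gamma * (np.log(e) + base)
                        if f > v[s, n]:
                            v[s, n] = f
                            argcol[s, n] = l
    return E, sc, v, argcol


@njit(cache=True)
def _logE(E, sc, s, n, m, l):
    """log-domain F(m, l) / gamma from the scaled buffers."""
    e = E[m + l, s, m, n]
    if e <= 0.0:
        return NEG
    return np.log(e) + sc[s, m + l]


@njit(cache=True)
def span_grads_exp(E, sc, reward_tab, codes, code_rows, argcol, M, g, gamma):
    """Window backtrack + analytic gradients for a whole batch.

    Parameters
    ----------
    E, sc : scaled forward buffers from :func:`forward_exp`
    reward_tab : (16, M, N) raw rewards p_m . s^T per IUPAC code index
    codes : (S, Lmax) IUPAC code indices
    code_rows : (16, 4) fractional one-hot row per code
    argcol : (S, N) last-row argmax columns

    Returns
    -------
    dvdP : (S, N, M, 4) gradient of each v w.r.t. its pattern
    dvdg : (S, N) gradient of each v w.r.t. the shared gap penalty
    spans : (S, N, 2) 1-based inclusive windows (start > end = empty)
    """
    S, N = argcol.shape
    Lmax = codes.shape[1]

    dvdP = np.zeros((S, N, M, 4))
    dvdg = np.zeros((S, N))
    spans = np.zeros((S, N, 2), dtype=np.int64)

    ginv = g / gamma
    Ft = np.zeros((M + 1, Lmax + 1))
    w = np.zeros((M + 1, Lmax + 1, 3))
    Eb = np.zeros((M + 1, Lmax + 1))
    Dg = np.zeros((M + 1, Lmax + 1))

    for s in range(S):
        for n in range(N):
            # --- backtrack the best-matched window ---
            end = argcol[s, n]
            m = M
            l = end
            while m > 0:
                if l == 0:
                    m -= 1
                    continue
                diag = (_logE(E, sc, s, n, m - 1, l - 1)
                        + reward_tab[codes[s, l - 1], m - 1, n] / gamma)
                up = _logE(E, sc, s, n, m - 1, l) - ginv
                left = _logE(E, sc, s, n, m, l - 1) - ginv
                if diag >= up and diag >= left:
                    m -= 1
                    l -= 1
                elif up >= left:
                    m -= 1
                else:
                    l -= 1
            lo = l + 1
            spans[s, n, 0] = lo
            spans[s, n, 1] = end
            Lt = end - lo + 1
            if Lt <= 0:
                # all-gap limit: v-tilde = -M g
                dvdg[s, n] = -float(M)
                continue

            # --- differentiable NW forward over the window ---
            for j in range(Lt + 1):
                Ft[0, j] = -g * j
            for i in range(1, M + 1):
                Ft[i, 0] = -g * i
            for i in range(1, M + 1):
                for j in range(1, Lt + 1):
                    r = reward_tab[codes[s, lo - 1 + j - 1], i - 1, n]
                    b1 = Ft[i - 1, j - 1] + r
                    b2 = Ft[i - 1, j] - g
                    b3 = Ft[i, j - 1] - g
                    mx = b1
                    if b2 > mx:
                        mx = b2
                    if b3 > mx:
                        mx = b3
                    e1 = np.exp((b1 - mx) / gamma)
                    e2 = np.exp((b2 - mx) / gamma)
                    e3 = np.exp((b3 - mx) / gamma)
                    tot = e1 + e2 + e3
                    Ft[i, j] = mx + gamma * np.log(tot)
                    w[i, j, 0] = e1 / tot
                    w[i, j, 1] = e2 / tot
                    w[i, j, 2] = e3 / tot

            # --- backward: Eb(i, j) = dFt(M, Lt)/dFt(i, j) ---
            for i in range(M + 1):
                for j in range(Lt + 1):
                    Eb[i, j] = 0.0
            Eb[M, Lt] = 1.0
            for i in range(M, -1, -1):
                for j in range(Lt, -1, -1):
                    if i == M and j == Lt:
                        continue
                    acc = 0.0
                    if i + 1 <= M:
                        acc += Eb[i + 1, j] * w[i + 1, j, 1]
                    if j + 1 <= Lt:
                        acc += Eb[i, j + 1] * w[i, j + 1, 2]
                    if i + 1 <= M and j + 1 <= Lt:
                        acc += Eb[i + 1, j + 1] * w[i + 1, j + 1, 0]
                    Eb[i, j] = acc

            # --- accumulate dv/dP rows ---
            for i in range(1, M + 1):
                for j in range(1, Lt + 1):
                    c = Eb[i, j] * w[i, j, 0]
                    if c != 0.0:
                        code = codes[s, lo - 1 + j - 1]
                        for a in range(4):
                            dvdP[s, n, i - 1, a] += c * code_rows[code, a]

            # --- forward: Dg(i, j) = dFt(i, j)/dg ---
            for i in range(M + 1):
                Dg[i, 0] = -float(i)
            for j in range(Lt + 1):
                Dg[0, j] = -float(j)
            for i in range(1, M + 1):
                for j in range(1, Lt + 1):
                    Dg[i, j] = (
                        w[i, j, 0] * Dg[i - 1, j - 1]
                        + w[i, j, 1] * (Dg[i - 1, j] - 1.0)
                        + w[i, j, 2] * (Dg[i, j - 1] - 1.0)
                    )
            dvdg[s, n] = Dg[M, Lt]

    return dvdP, dvdg, spans
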