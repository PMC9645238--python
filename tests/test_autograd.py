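import numpy as np
import pytest

from asmatch.asmnet import (
    PatternSet,
    best_match_span,
    pad_codes,
    soft_asm_forward,
    _forward_core,
)
from asmatch.autograd import (
    Gradients,
    branch_weights,
    cosine_distance_grad,
    diff_nw_forward,
    grad_gap,
    grad_pattern,
    loss_backward,
)
from asmatch.model import TrainingPair, mse_loss
from asmatch.seqio import CODE_ROWS, Sequence, one_hot_encode
from asmatch._kernels import span_grads_exp


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def random_onehot(rng, length):
    return np.eye(4)[rng.integers(0, 4, size=length)]


class TestDiffNWForward:
    def test_global_boundaries(self, rng):
        P = rng.random((3, 4))
        St = random_onehot(rng, 5)
        F = diff_nw_forward(P, St, g=0.8, gamma=0.5)
        assert np.allclose(F[0], -0.8 * np.arange(6))
        assert np.allclose(F[:, 0], -0.8 * np.arange(4))

    def test_identical_strings_score_length(self):
        St = one_hot_encode("ACGT").matrix
        F = diff_nw_forward(St, St, g=1.0, gamma=1e-3)
        assert F[-1, -1] == pytest.approx(4.0, abs=1e-2)

    def test_consistent_with_soft_asm_on_extracted_span(self, rng):
        """F-tilde at the corner approximates v when the window is the
        extracted span."""
        for _ in range(20):
            M, L = int(rng.integers(2, 6)), int(rng.integers(6, 15))
            P = rng.random((M, 4))
            S = random_dna(rng, L)
            g, gamma = 1.0, 0.05
            res = soft_asm_forward(P, S, g, gamma)
            lo, hi = best_match_span(res, g, gamma, P, S)
            if lo > hi:
                continue
            St = one_hot_encode(S).matrix[lo - 1 : hi]
            F = diff_nw_forward(P, St, g, gamma)
            Lt = St.shape[0]
            assert F[-1, -1] == pytest.approx(
                res.v, abs=10 * gamma * (M + Lt)
            )


class TestBranchWeights:
    def test_sum_to_one_everywhere(self, rng):
        P = rng.normal(0, 1, (4, 4))
        St = random_onehot(rng, 6)
        F = diff_nw_forward(P, St, 1.0, 0.7)
        for m in range(1, 5):
            for l in range(1, 7):
                w = branch_weights(F, P, St, 1.0, 0.7, m, l)
                assert sum(w) == pytest.approx(1.0)
                assert all(x >= 0 for x in w)

    def test_hard_max_limit(self):
        # a strict best branch takes all the weight as gamma -> 0
        P = one_hot_encode("AC").matrix * 5
        St = one_hot_encode("AC").matrix
        F = diff_nw_forward(P, St, 1.0, 1e-3)
        w = branch_weights(F, P, St, 1.0, 1e-3, 1, 1)
        assert w[0] == pytest.approx(1.0, abs=1e-6)

    def test_equal_branches_split_evenly(self):
        # zero rewards and zero-cost gaps make all three branches equal
        P = np.zeros((2, 4))
        St = np.zeros((2, 4))
        g = 1e-9
        F = diff_nw_forward(P, St, g, 1.0)
        w = branch_weights(F, P, St, g, 1.0, 1, 1)
        assert np.allclose(w, 1 / 3, atol=1e-6)


class TestWindowGradients:
    @pytest.mark.parametrize("gamma,tol", [(1.0, 1e-4), (0.5, 1e-4), (0.1, 1e-3)])
    def test_pattern_gradient_matches_finite_differences(self, rng, gamma, tol):
        eps = 1e-5
        worst = 0.0
        for _ in range(100 if gamma == 1.0 else 30):
            M, Lt = int(rng.integers(2, 6)), int(rng.integers(2, 9))
            P = rng.random((M, 4))
            St = random_onehot(rng, Lt)
            g = float(rng.uniform(0.5, 2.0))
            dP = grad_pattern(P, St, g, gamma)
            for m in range(M):
                for a in range(4):
                    Pp, Pm = P.copy(), P.copy()
                    Pp[m, a] += eps
                    Pm[m, a] -= eps
                    fd = (diff_nw_forward(Pp, St, g, gamma)[-1, -1]
                          - diff_nw_forward(Pm, St, g, gamma)[-1, -1]) / (2 * eps)
                    worst = max(worst, abs(dP[m, a] - fd) / max(abs(fd), 1.0))
        assert worst < tol

    @pytest.mark.parametrize("gamma,tol", [(1.0, 1e-4), (0.1, 1e-3)])
    def test_gap_gradient_matches_finite_differences(self, rng, gamma, tol):
        eps = 1e-6
        worst = 0.0
        for _ in range(100 if gamma == 1.0 else 30):
            M, Lt = int(rng.integers(2, 6)), int(rng.integers(2, 9))
            P = rng.random((M, 4))
            St = random_onehot(rng, Lt)
            g = float(rng.uniform(0.5, 2.0))
            dg = grad_gap(P, St, g, gamma)
            fd = (diff_nw_forward(P, St, g + eps, gamma)[-1, -1]
                  - diff_nw_forward(P, St, g - eps, gamma)[-1, -1]) / (2 * eps)
            worst = max(worst, abs(dg - fd) / max(abs(fd), 1.0))
        assert worst < tol

    def test_uniform_rows_give_symmetric_gradient(self, rng):
        # an all-N window cannot distinguish the four bases
        P = rng.random((3, 4))
        St = np.full((5, 4), 0.25)
        dP = grad_pattern(P, St, 1.0, 0.5)
        for row in dP:
            assert np.allclose(row, row[0])

    def test_identical_match_has_no_gap_sensitivity(self):
        St = one_hot_encode("ACGTA").matrix
        dg = grad_gap(St * 3, St, 1.0, 1e-2)
        assert dg == pytest.approx(0.0, abs=1e-6)

    def test_zero_reward_window_gap_gradient_nonpositive(self, rng):
        P = rng.random((3, 4))
        St = np.zeros((4, 4))  # no reward anywhere
        assert grad_gap(P, St, 1.0, 0.5) <= 0.0

    def test_gradients_finite_under_extreme_inputs(self, rng):
        P = rng.choice([-50.0, 50.0], size=(4, 4))
        St = random_onehot(rng, 6)
        dP = grad_pattern(P, St, 1.0, 0.5)
        dg = grad_gap(P, St, 1.0, 0.5)
        assert np.all(np.isfinite(dP)) and np.isfinite(dg)


class TestLossBackward:
    def _tiny_setup(self, rng, gamma=0.1):
        a = Sequence("a", random_dna(rng, 18))
        b = Sequence("b", random_dna(rng, 22))
        pair = TrainingPair(a, b, 0.35)
        params = PatternSet(
            rng.random((2, 3, 4)), 1.0, rng.normal(0, 0.1, 2), gamma=gamma
        )
        return pair, params

    def test_perfect_prediction_gives_zero_gradient(self, rng):
        pair, params = self._tiny_setup(rng)
        de = 1.0 - 0.0  # compute actual predicted distance, then retarget
        from asmatch.model import cosine_distance
        from asmatch.asmnet import embed

        de = cosine_distance(embed(pair.seq_a, params), embed(pair.seq_b, params))
        exact = TrainingPair(pair.seq_a, pair.seq_b, de)
        g = loss_backward(exact, params)
        assert np.allclose(g.patterns, 0) and g.gap == 0 and np.allclose(g.bias, 0)

    def test_end_to_end_finite_differences(self, rng):
        """The windowed analytic gradient matches finite differences of
        the full loss at the default smoothing."""
        pair, params = self._tiny_setup(rng, gamma=0.1)
        g = loss_backward(pair, params)
        eps = 1e-5
        fdP = np.zeros_like(params.patterns)
        for idx in np.ndindex(params.patterns.shape):
            pp = params.copy()
            pp.patterns[idx] += eps
            pm = params.copy()
            pm.patterns[idx] -= eps
            fdP[idx] = (mse_loss([pair], pp) - mse_loss([pair], pm)) / (2 * eps)
        ref = np.linalg.norm(fdP)
        assert np.linalg.norm(g.patterns - fdP) / ref < 1e-3

    def test_bias_gradient_masked_by_relu(self, rng):
        pair, params = self._tiny_setup(rng)
        params.bias[:] = -1e6  # every ReLU output clamped at 0
        g = loss_backward(pair, params)
        assert np.allclose(g.bias, 0.0)


class TestKernelAgreement:
    def test_batched_kernel_equals_reference_path(self, rng):
        """The compiled exp-domain kernel reproduces the numpy reference
        recursions bit-for-bit up to rounding."""
        seqs = [random_dna(rng, int(rng.integers(10, 30))) for _ in range(6)]
        N, M = 3, 5
        P = rng.normal(0, 0.6, (N, M, 4))
        g, gamma = 1.0, 0.3
        codes, lengths = pad_codes(seqs)
        reward_tab, E, sc, v, argcol = _forward_core(P, codes, lengths, g, gamma)
        dvdP, dvdg, spans = span_grads_exp(
            E, sc, reward_tab, codes, CODE_ROWS, argcol, M, g, gamma
        )
        for s, seq in enumerate(seqs):
            oh = one_hot_encode(seq).matrix
            for n in range(N):
                res = soft_asm_forward(P[n], seq, g, gamma)
                assert v[s, n] == pytest.approx(res.v, abs=1e-9)
                lo, hi = best_match_span(res, g, gamma, P[n], seq)
                assert (lo, hi) == tuple(spans[s, n])
                St = oh[lo - 1 : hi]
                if St.shape[0] == 0:
                    assert dvdg[s, n] == -M
                    continue
                assert np.allclose(
                    grad_pattern(P[n], St, g, gamma), dvdP[s, n], atol=1e-9
                )
                assert dvdg[s, n] == pytest.approx(
                    grad_gap(P[n], St, g, gamma), abs=1e-9
                )


class TestCosineDistanceGrad:
    def test_matches_finite_differences(self, rng):
        u1 = rng.random(6) + 0.1
        u2 = rng.random(6) + 0.1
        de, d1, d2 = cosine_distance_grad(u1, u2)
        eps = 1e-7
        for k in range(6):
            up = u1.copy()
            up[k] += eps
            de2, _, _ = cosine_distance_grad(up, u2)
            assert (de2 - de) / eps == pytest.approx(d1[k], rel=1e-4, abs=1e-8)

    def test_zero_vector_guard(self):
        de, d1, d2 = cosine_distance_grad(np.zeros(3), np.ones(3))
        assert de == pytest.approx(1.0)
        assert np.all(np.isfinite(d1)) and np.all(np.isfinite(d2))
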