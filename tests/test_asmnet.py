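import numpy as np
import pytest

from asmatch.align import hard_asm
from asmatch.asmnet import (
    PatternSet,
    best_match_span,
    embed,
    embed_batch,
    hard_max_asm_score,
    pad_codes,
    soft_asm_batch,
    soft_asm_forward,
    soft_max_gamma,
)
from asmatch.seqio import one_hot_encode


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def one_hot_pattern(residues):
    return one_hot_encode(residues).matrix


class TestSoftMaxGamma:
    def test_equal_arguments(self):
        assert soft_max_gamma([0, 0, 0], 1.0) == pytest.approx(np.log(3))

    def test_dominant_argument(self):
        assert soft_max_gamma([5, -1000, -1000], 0.1) == pytest.approx(
            5.0, abs=1e-12
        )

    def test_closed_form(self):
        expected = 1 + np.log(1 + np.exp(-1) + np.exp(-2))
        assert soft_max_gamma([1, 0, -1], 1.0) == pytest.approx(expected)

    def test_stable_for_huge_magnitudes(self):
        assert np.isfinite(soft_max_gamma([1e6, 1e6 - 1], 0.01))

    def test_upper_and_lower_bounds(self, rng):
        for _ in range(50):
            a = rng.normal(0, 10, size=rng.integers(1, 8))
            gamma = float(rng.uniform(0.01, 2.0))
            r = soft_max_gamma(a, gamma)
            assert a.max() <= r <= a.max() + gamma * np.log(a.size) + 1e-12


class TestSoftForward:
    def test_boundary_conditions(self, rng):
        P = rng.random((3, 4))
        res = soft_asm_forward(P, "ACGTTT", g=0.7, gamma=0.5)
        assert np.allclose(res.F[0], 0.0)
        assert np.allclose(res.F[:, 0], -0.7 * np.arange(4))

    def test_exact_substring_scores_pattern_length(self):
        P = one_hot_pattern("ACGT")
        res = soft_asm_forward(P, "TTACGTTT", g=1.0, gamma=1e-3)
        assert res.v == pytest.approx(4.0, abs=1e-2)

    def test_converges_to_hard_max_and_monotone_in_gamma(self, rng):
        P = rng.random((4, 4))
        S = random_dna(rng, 12)
        hard = hard_max_asm_score(P, S, g=1.0)
        prev = np.inf
        for gamma in (1.0, 0.3, 0.1, 1e-2, 1e-4):
            v = soft_asm_forward(P, S, 1.0, gamma).v
            assert v <= prev + 1e-12
            prev = v
        assert prev == pytest.approx(hard, abs=5e-3)

    def test_sandwich_bound_per_cell(self, rng):
        for _ in range(20):
            M, L = int(rng.integers(1, 6)), int(rng.integers(1, 12))
            P = rng.normal(0, 1, (M, 4))
            S = random_dna(rng, L)
            gamma = float(rng.uniform(0.05, 1.0))
            soft = soft_asm_forward(P, S, 1.0, gamma).F
            hard = _hard_F(P, S, 1.0)
            slack = gamma * np.log(3)
            assert np.all(soft >= hard - 1e-12)
            # each interior cell adds at most gamma*log(3) of slack
            cell_count = (np.arange(M + 1)[:, None]
                          + np.arange(L + 1)[None, :])
            assert np.all(soft <= hard + slack * cell_count + 1e-9)

    def test_column_prefix_property(self, rng):
        P = rng.random((3, 4))
        S = random_dna(rng, 10)
        full = soft_asm_forward(P, S + "ACGT", 1.0, 0.2).F
        part = soft_asm_forward(P, S, 1.0, 0.2).F
        assert np.allclose(full[:, : part.shape[1]], part)


class TestHardMaxScore:
    def test_agrees_with_window_brute_force(self, rng):
        for _ in range(100):
            M, L = int(rng.integers(1, 6)), int(rng.integers(1, 11))
            P = rng.normal(0, 1, (M, 4))
            S = random_dna(rng, L)
            g = float(rng.uniform(0.3, 2.0))
            expected = _window_brute_force(P, one_hot_encode(S).matrix, g)
            assert hard_max_asm_score(P, S, g) == pytest.approx(expected)

    def test_empty_pattern_scores_zero(self):
        assert hard_max_asm_score(np.zeros((0, 4)), "ACGT", 1.0) == 0.0


class TestSpans:
    def test_exact_substring_span(self):
        P = one_hot_pattern("ACGT")
        res = soft_asm_forward(P, "TTACGTTT", 1.0, 1e-3)
        assert best_match_span(res, 1.0, 1e-3, P, "TTACGTTT") == (3, 6)

    def test_pattern_at_sequence_start(self):
        P = one_hot_pattern("ACG")
        res = soft_asm_forward(P, "ACGTTT", 1.0, 1e-3)
        assert best_match_span(res, 1.0, 1e-3, P, "ACGTTT")[0] == 1

    def test_exact_substring_span_agrees_with_edit_distance_dp(self, rng):
        # for a clean exact occurrence both formulations pick the window
        for _ in range(20):
            core = random_dna(rng, 4)
            s_res = random_dna(rng, 5) + core + random_dna(rng, 5)
            P = one_hot_pattern(core)
            res = soft_asm_forward(P, s_res, 1.0, 1e-3)
            span = best_match_span(res, 1.0, 1e-3, P, s_res)
            assert s_res[span[0] - 1 : span[1]] == core
            assert span == hard_asm(core, s_res).span

    def test_soft_and_hard_spans_mostly_agree(self, rng):
        """At small gamma the soft backtrack recovers the window of the
        hard-max recursion except at near-ties."""
        agree = total = 0
        for _ in range(200):
            M = int(rng.integers(2, 7))
            s_res = random_dna(rng, int(rng.integers(4, 16)))
            P = rng.normal(0, 0.7, (M, 4))
            soft = soft_asm_forward(P, s_res, 1.0, 1e-3)
            soft_span = best_match_span(soft, 1.0, 1e-3, P, s_res)
            hard_span = best_match_span(
                _hard_F(P, s_res, 1.0), 1.0, 1e-3, P, s_res
            )
            total += 1
            agree += soft_span == hard_span
        assert agree / total >= 0.95


class TestBatchForward:
    def test_matches_reference_per_cell(self, rng):
        seqs = [random_dna(rng, int(rng.integers(5, 25))) for _ in range(5)]
        seqs.append("ACGNRYTTWACGT")  # ambiguity codes batch path
        P = rng.normal(0, 0.7, (3, 4, 4))
        codes, lengths = pad_codes(seqs)
        F, v, argcol = soft_asm_batch(P, codes, lengths, 1.0, 0.3)
        for s, seq in enumerate(seqs):
            L = len(seq)
            for n in range(P.shape[0]):
                ref = soft_asm_forward(P[n], seq, 1.0, 0.3)
                assert np.allclose(F[s, n, :, : L + 1], ref.F, atol=1e-9)
                assert v[s, n] == pytest.approx(ref.v, abs=1e-9)
                assert argcol[s, n] == ref.argmax_col


class TestEmbedding:
    def test_large_negative_bias_clips_to_zero(self, rng):
        params = PatternSet(rng.random((3, 4, 4)), 1.0, -1e6 * np.ones(3))
        assert np.array_equal(embed("ACGTACGT", params), np.zeros(3))

    def test_exact_match_single_pattern(self):
        params = PatternSet(
            one_hot_pattern("ACGT")[None], 1.0, np.zeros(1), gamma=1e-3
        )
        u = embed("TTACGTTT", params)
        assert u[0] == pytest.approx(4.0, abs=1e-2)

    def test_deterministic_and_nonnegative(self, rng, small_families):
        params = PatternSet(rng.normal(0, 1, (6, 5, 4)), 1.0, rng.normal(0, 1, 6))
        seqs = [r.seq for r in small_families[:8]]
        U1 = embed_batch(seqs, params)
        U2 = embed_batch(seqs, params)
        assert np.array_equal(U1, U2)
        assert np.all(U1 >= 0)
        assert U1.shape == (8, 6)

    def test_dimension_independent_of_length(self, rng):
        params = PatternSet(rng.random((5, 4, 4)), 1.0, np.zeros(5))
        assert embed("ACG", params).shape == embed("ACGT" * 50, params).shape


class TestPatternSet:
    def test_validation(self, rng):
        with pytest.raises(ValueError):
            PatternSet(rng.random((2, 3, 4)), -1.0, np.zeros(2))
        with pytest.raises(ValueError):
            PatternSet(rng.random((2, 3, 4)), 1.0, np.zeros(3))
        with pytest.raises(ValueError):
            PatternSet(rng.random((2, 3, 4)), 1.0, np.zeros(2), gamma=0.0)


def _hard_F(P, S, g):
    oh = one_hot_encode(S).matrix
    M, L = P.shape[0], oh.shape[0]
    reward = P @ oh.T
    F = np.zeros((M + 1, L + 1))
    F[1:, 0] = -g * np.arange(1, M + 1)
    for m in range(1, M + 1):
        for l in range(1, L + 1):
            F[m, l] = max(F[m - 1, l - 1] + reward[m - 1, l - 1],
                          F[m - 1, l] - g, F[m, l - 1] - g)
    return F


def _window_brute_force(P, oh, g):
    """Max over all windows of the global alignment score (reward/gap)."""
    M, L = P.shape[0], oh.shape[0]
    reward = P @ oh.T
    best = -g * M  # empty window: delete the whole pattern
    for i in range(L):
        for j in range(i + 1, L + 1):
            best = max(best, _global_score(reward[:, i:j], g))
    return best


def _global_score(r, g):
    M, W = r.shape
    F = np.zeros((M + 1, W + 1))
    F[1:, 0] = -g * np.arange(1, M + 1)
    F[0, 1:] = -g * np.arange(1, W + 1)
    for m in range(1, M + 1):
        for l in range(1, W + 1):
            F[m, l] = max(F[m - 1, l - 1] + r[m - 1, l - 1],
                          F[m - 1, l] - g, F[m, l - 1] - g)
    return F[M, W]
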