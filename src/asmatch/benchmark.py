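"""Desk-scale validation protocol.

Self-contained, seeded experiments that exercise the whole pipeline at a
scale that runs on one CPU in minutes: oracle equivalence of the hard ASM
DP, convergence of the smoothed recursion to its hard limit, analytic-vs-
numeric gradient agreement, training on the synthetic family fixture with
held-out distance evaluation, and taxonomy assignment against the NW
ground truth.  Both the test suite and ``scripts/acceptance.py`` run
these functions; every quantity they report is computed at call time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence as TSequence, Tuple

import numpy as np
from scipy.stats import spearmanr

from .seqio import Sequence, one_hot_encode
from .align import alignment_distance, brute_force_asm_oracle, hard_asm
from .asmnet import embed_batch, hard_max_asm_score, soft_asm_forward
from .autograd import diff_nw_forward, grad_gap, grad_pattern
from .model import AsMacModel, TrainConfig, TrainingPair, cosine_distance
from .evaluate import TaxonomyRecord, assign_taxonomy, mre
from .synth import (
    default_between_model,
    default_within_model,
    make_families,
    mutate,
)

#: Desk-scale study conditions: 10 genus-like families of 20 members,
#: V4-amplicon-like length 150, 2000 training and 1000 held-out pairs,
#: 50 patterns of length 12 trained for 60 epochs at the published
#: learning rate.
DESK_FAMILIES = 10
DESK_MEMBERS = 20
DESK_LENGTH = 150
DESK_TRAIN_PAIRS = 2000
DESK_HELDOUT_PAIRS = 1000
DESK_CONFIG = dict(
    n_patterns=50, pattern_len=12, gamma=0.1, learning_rate=1e-4,
    epochs=60, batch_size=32,
)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# hard ASM vs brute force
# ---------------------------------------------------------------------------

def hard_asm_oracle_agreement(seed: int, trials: int = 500) -> float:
    """Fraction of random instances (M <= 8, L <= 20) on which the ASM DP
    equals the window-wise brute-force edit distance."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(trials):
        p = random_dna(rng, int(rng.integers(1, 9)))
        s = random_dna(rng, int(rng.integers(1, 21)))
        agree += hard_asm(p, s).min_edit_distance == \
            brute_force_asm_oracle(p, s)
    return agree / trials


# ---------------------------------------------------------------------------
# smoothed recursion vs hard limit
# ---------------------------------------------------------------------------

def soft_hard_convergence(
    seed: int, trials: int = 200, gamma: float = 1e-4
) -> Dict[str, float]:
    """Max |soft - hard| of the optimal score at small gamma, plus the
    worst per-cell sandwich-bound violation (negative slack)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    worst_sandwich = 0.0
    for _ in range(trials):
        M, L = int(rng.integers(1, 7)), int(rng.integers(1, 16))
        P = rng.normal(0, 1, (M, 4))
        S = random_dna(rng, L)
        g = float(rng.uniform(0.3, 2.0))
        soft = soft_asm_forward(P, S, g, gamma)
        hard = hard_max_asm_score(P, S, g)
        worst = max(worst, abs(soft.v - hard))
        # hard <= soft per cell (sandwich lower bound)
        hard_F = _hard_matrix(P, S, g)
        worst_sandwich = max(worst_sandwich, float((hard_F - soft.F).max()))
    return {"max_abs_deviation": worst, "max_sandwich_violation": worst_sandwich}


def _hard_matrix(P, S, g):
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


# ---------------------------------------------------------------------------
# analytic gradients vs finite differences
# ---------------------------------------------------------------------------

def gradient_check(
    seed: int, trials: int = 100, gamma: float = 1.0
) -> Dict[str, float]:
    """Max relative error of the analytic window gradients against
    central finite differences (guarded denominator max(|fd|, 1))."""
    rng = np.random.default_rng(seed)
    eps = 1e-5
    worst_p = worst_g = 0.0
    for _ in range(trials):
        M, Lt = int(rng.integers(2, 6)), int(rng.integers(2, 9))
        P = rng.random((M, 4))
        St = np.eye(4)[rng.integers(0, 4, size=Lt)]
        g = float(rng.uniform(0.5, 2.0))

        def corner(P_, g_):
            return diff_nw_forward(P_, St, g_, gamma)[-1, -1]

        dP = grad_pattern(P, St, g, gamma)
        for m in range(M):
            for a in range(4):
                Pp, Pm = P.copy(), P.copy()
                Pp[m, a] += eps
                Pm[m, a] -= eps
                fd = (corner(Pp, g) - corner(Pm, g)) / (2 * eps)
                worst_p = max(worst_p, abs(dP[m, a] - fd) / max(abs(fd), 1.0))
        dg = grad_gap(P, St, g, gamma)
        fd = (corner(P, g + eps) - corner(P, g - eps)) / (2 * eps)
        worst_g = max(worst_g, abs(dg - fd) / max(abs(fd), 1.0))
    return {"max_rel_err_pattern": worst_p, "max_rel_err_gap": worst_g}


# ---------------------------------------------------------------------------
# desk-scale training and evaluation
# ---------------------------------------------------------------------------

@dataclass
class DeskRun:
    """Everything the desk-scale experiment measures."""

    records: List[TaxonomyRecord]
    results: "object"  # AsMacResults
    loss_history: List[float]
    spearman: float
    mre_percent: float
    baseline_mre_percent: float
    taxonomy_accuracy: float


def desk_fixture(seed: int) -> List[TaxonomyRecord]:
    """The synthetic family fixture under the study conditions."""
    records, _ = make_families(
        DESK_FAMILIES, DESK_MEMBERS, DESK_LENGTH,
        default_within_model(), default_between_model(), seed,
    )
    return records


def sample_index_pairs(
    rng: np.random.Generator, n_seqs: int, k: int,
    exclude: frozenset = frozenset(),
) -> List[Tuple[int, int]]:
    """k distinct-member index pairs, skipping any in ``exclude``."""
    out: List[Tuple[int, int]] = []
    while len(out) < k:
        ia, ib = sorted(rng.choice(n_seqs, size=2, replace=False))
        if ia == ib or (ia, ib) in exclude:
            continue
        out.append((int(ia), int(ib)))
    return out


def desk_training_run(seed: int, n_queries: int = 50) -> DeskRun:
    """Train on the fixture and evaluate on held-out pairs and taxonomy.

    Training pairs and held-out pairs are disjoint; held-out embedding
    distances are compared to NW distances by Spearman correlation and
    MRE, with the constant-mean predictor as the MRE baseline.  Taxonomy
    queries are fresh strain-level mutants of fixture members, labelled
    by nearest embedding and scored against the NW best hit.
    """
    records = desk_fixture(seed)
    seqs = [r.seq for r in records]
    rng = np.random.default_rng(seed)
    train_idx = sample_index_pairs(rng, len(seqs), DESK_TRAIN_PAIRS)
    held_idx = sample_index_pairs(
        rng, len(seqs), DESK_HELDOUT_PAIRS, exclude=frozenset(train_idx)
    )
    pairs = [
        TrainingPair(seqs[i], seqs[j], alignment_distance(seqs[i], seqs[j]))
        for i, j in train_idx
    ]
    da_held = np.array(
        [alignment_distance(seqs[i], seqs[j]) for i, j in held_idx]
    )

    config = TrainConfig(seed=seed, **DESK_CONFIG)
    results = AsMacModel(pairs, config).fit()

    U = embed_batch(seqs, results.params)
    de = np.array([cosine_distance(U[i], U[j]) for i, j in held_idx])
    rho = float(spearmanr(de, da_held).statistic)
    est_mre = mre(de, da_held).value
    baseline = mre(np.full_like(da_held, da_held.mean()), da_held).value

    qrng = np.random.default_rng(seed + 1_000_000)
    within = default_within_model()
    queries = [
        mutate(
            records[int(qrng.integers(len(records)))].seq,
            within, rng=qrng, id=f"q{k}",
        )
        for k in range(n_queries)
    ]
    tax = assign_taxonomy(queries, records, results.params)

    return DeskRun(
        records=records,
        results=results,
        loss_history=results.loss_history,
        spearman=rho,
        mre_percent=est_mre,
        baseline_mre_percent=baseline,
        taxonomy_accuracy=tax.accuracy,
    )


def windowed_means(values: TSequence[float], window: int = 10) -> List[float]:
    """Non-overlapping window averages (for monotone-trend checks)."""
    return [
        float(np.mean(values[i : i + window]))
        for i in range(0, len(values) - window + 1, window)
    ]
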