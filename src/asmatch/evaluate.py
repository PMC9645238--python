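"""Evaluation protocol: pair sampling, mean relative error, taxonomy.

The accuracy of an alignment-free estimator is scored by the mean
relative error (MRE) of its estimated distances against NW alignment
distances over all unordered pairs of a random sample of sequences, and
by how often nearest-neighbour search in embedding space annotates a
query with the same genus-like label as an exhaustive NW database search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence as TSequence, Tuple

import numpy as np

from .seqio import Sequence
from .align import NWScoring, alignment_distance, nw_align
from .asmnet import PatternSet, embed_batch
from .model import cosine_distance


@dataclass(frozen=True)
class TaxonomyRecord:
    """A reference sequence with its genus-like label."""

    seq: Sequence
    label: str

    def __post_init__(self):
        if not self.label:
            raise ValueError("label must be nonempty")


@dataclass
class PairSample:
    """n sequences drawn without replacement plus all n(n-1)/2 pairs."""

    sequences: List[Sequence]
    pairs: List[Tuple[int, int]]
    d_a: Optional[np.ndarray]  # None when distances were skipped


def sample_pairs(
    seqs: TSequence[Sequence],
    n: int,
    seed: int,
    scoring: NWScoring = NWScoring(),
    with_distances: bool = True,
) -> PairSample:
    """Draw n sequences without replacement and enumerate all unordered
    pairs; optionally compute d_a per pair."""
    if n > len(seqs):
        raise ValueError(f"cannot draw {n} from {len(seqs)} sequences")
    rng = np.random.default_rng(seed)
    chosen = [seqs[i] for i in rng.choice(len(seqs), size=n, replace=False)]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d_a = None
    if with_distances:
        d_a = np.array(
            [alignment_distance(chosen[i], chosen[j], scoring)
             for i, j in pairs]
        )
    return PairSample(sequences=chosen, pairs=pairs, d_a=d_a)


class MREResult(NamedTuple):
    """MRE in percent, plus how many zero-distance pairs were excluded."""

    value: float
    n_excluded: int


def mre(estimated, truth) -> MREResult:
    """Mean relative error, in percent.

    mean over pairs with truth > 0 of |est - truth| / truth, times 100.
    Zero-truth pairs (identical sequences) have no defined relative error;
    they are excluded and counted in ``n_excluded``.
    """
    est = np.asarray(estimated, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("estimated and truth must be equal-length, nonempty")
    keep = tru > 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all truth distances are zero; MRE is undefined")
    value = float(np.mean(np.abs(est[keep] - tru[keep]) / tru[keep]) * 100.0)
    return MREResult(value=value, n_excluded=n_excluded)


@dataclass
class TaxonomyAssignment:
    """Embedding-based labels, NW ground-truth labels, and agreement."""

    labels: List[str]
    truth_labels: List[str]
    accuracy: float


def assign_taxonomy(
    queries: TSequence[Sequence],
    refs: TSequence[TaxonomyRecord],
    params: PatternSet,
    scoring: NWScoring = NWScoring(),
) -> TaxonomyAssignment:
    """Annotate queries by their nearest reference in embedding space and
    score against an exhaustive NW database search.

    Reference embeddings are computed exactly once.  The embedding label
    is that of the reference at minimum cosine distance (ties -> smallest
    reference index); the ground truth is the label of the reference with
    the maximum NW alignment score (same tie rule).
    """
    if not refs:
        raise ValueError("reference database must be nonempty")
    ref_emb = embed_batch([r.seq for r in refs], params)
    qry_emb = embed_batch(list(queries), params)

    labels: List[str] = []
    truth: List[str] = []
    for qi, q in enumerate(queries):
        dists = [cosine_distance(qry_emb[qi], ref_emb[ri])
                 for ri in range(len(refs))]
        labels.append(refs[int(np.argmin(dists))].label)
        scores = [nw_align(q, r.seq, scoring).score for r in refs]
        truth.append(refs[int(np.argmax(scores))].label)
    agree = sum(a == b for a, b in zip(labels, truth))
    return TaxonomyAssignment(
        labels=labels,
        truth_labels=truth,
        accuracy=agree / len(labels) if labels else float("nan"),
    )
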