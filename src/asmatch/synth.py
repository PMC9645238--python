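"""Synthetic amplicon-like sequence families.

Emulates the divergence structure the estimator is trained on: an
ancestral random sequence diversified by point substitutions and short
insertions/deletions into nested genus-like families (serial radiation of
family ancestors, then within-family divergence).  One master seed drives
an explicit stream-splitting scheme (one child stream per family), so
adding a family does not perturb earlier families.

The generator captures substitution/indel divergence only; it does not
emulate sequencing-error profiles, chimeras or primer artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .seqio import Sequence
from .align import NWScoring, alignment_distance
from .evaluate import TaxonomyRecord

_BASES = np.array(list("ACGT"))


def default_within_model() -> "MutationModel":
    """Within-family divergence: ~3% substitutions plus rare short
    indels, the scale of strain-level 16S variation."""
    return MutationModel(sub_rate=0.03, ins_rate=0.005, del_rate=0.005)


def default_between_model() -> "MutationModel":
    """Per-radiation-step divergence between family ancestors: ~5%
    substitutions plus short indels, so adjacent families differ at the
    genus scale (~10-15%) and distant ones saturate gradually."""
    return MutationModel(sub_rate=0.05, ins_rate=0.01, del_rate=0.01)


@dataclass(frozen=True)
class MutationModel:
    """Per-position mutation process.

    At each position of the input, one categorical event is drawn:
    deletion of a short run (prob ``del_rate``), insertion of a short
    random run before the position (prob ``ins_rate``), substitution to a
    uniformly chosen different base (prob ``sub_rate``), or an exact copy.
    Indel run lengths are geometric with success 1/2, capped at
    ``max_indel_len``.
    """

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    max_indel_len: int = 5
    seed: int = 0

    def __post_init__(self):
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 or r >= 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("rates must be in [0, 1) and sum below 1")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")


def random_sequence(
    length: int, seed: int, id: str = "random",
    rng: Optional[np.random.Generator] = None,
) -> Sequence:
    """i.i.d. uniform sequence over {A, C, G, T}; reproducible by seed."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    return Sequence(id=id, residues="".join(rng.choice(_BASES, size=length)))


def _run_length(rng: np.random.Generator, cap: int) -> int:
    return min(int(rng.geometric(0.5)), cap)


def mutate(
    seq: Sequence,
    model: MutationModel,
    rng: Optional[np.random.Generator] = None,
    id: Optional[str] = None,
) -> Sequence:
    """Apply the mutation process once; seeded via ``model.seed`` unless
    an explicit generator is passed."""
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    out: List[str] = []
    residues = seq.residues
    i = 0
    while i < len(residues):
        u = rng.random()
        if u < model.del_rate:
            i += _run_length(rng, model.max_indel_len)
            continue
        u -= model.del_rate
        if u < model.ins_rate:
            k = _run_length(rng, model.max_indel_len)
            out.extend(rng.choice(_BASES, size=k))
            out.append(residues[i])
        elif u - model.ins_rate < model.sub_rate:
            others = [b for b in "ACGT" if b != residues[i]]
            out.append(others[rng.integers(3)])
        else:
            out.append(residues[i])
        i += 1
    if not out:
        raise ValueError("mutation rates too aggressive: sequence vanished")
    return Sequence(id=id if id is not None else seq.id, residues="".join(out))


def make_families(
    n_families: int,
    members_per_family: int,
    length: int,
    within_model: MutationModel,
    between_model: MutationModel,
    seed: int,
    with_distances: bool = False,
    scoring: NWScoring = NWScoring(),
) -> Tuple[List[TaxonomyRecord], Optional[Dict[Tuple[int, int], float]]]:
    """Generate labelled sequence families by serial radiation.

    Family ancestors form a mutation chain (root -> anc_1 -> ... ->
    anc_F, one ``between_model`` step each), so clades are nested and
    pairwise distances span a graded spectrum rather than a single
    between-family level — mimicking the continuous distance spread of
    real amplicon data.  Each ancestor spawns ``members_per_family``
    members with ``within_model``.  Labels are the family ids.  When
    ``with_distances`` is set, d_a for every unordered member pair is
    returned as a dict keyed by member index pairs.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_families + 1)
    ancestor = random_sequence(
        length, 0, id="root", rng=np.random.default_rng(children[0])
    )
    records: List[TaxonomyRecord] = []
    for f in range(n_families):
        rng = np.random.default_rng(children[f + 1])
        label = f"family_{f:02d}"
        ancestor = mutate(ancestor, between_model, rng=rng, id=f"{label}_anc")
        for k in range(members_per_family):
            member = mutate(
                ancestor, within_model, rng=rng, id=f"{label}_m{k:02d}"
            )
            records.append(TaxonomyRecord(seq=member, label=label))
    dists = None
    if with_distances:
        dists = {}
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                dists[(i, j)] = alignment_distance(
                    records[i].seq, records[j].seq, scoring
                )
    return records, dists
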