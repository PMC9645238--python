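"""Siamese assembly: model object, training loop, persistence.

`AsMacModel` holds a set of training pairs (two sequences plus their NW
alignment distance) and a `TrainConfig`; `fit()` minimizes the mean
squared error between cosine embedding distances and alignment distances
with Adam, updating one shared `PatternSet` (the two twin branches use
identical parameters, so their gradient contributions are summed), and
returns an `AsMacResults` carrying the trained parameters, the per-epoch
loss history, prediction/embedding methods and a `summary()` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence as TSequence, Tuple, Union

import numpy as np

from .seqio import (
    CODE_ROWS,
    OneHotSeq,
    Sequence,
    encode_codes,
)
from .align import NWScoring, alignment_distance
from .asmnet import PatternSet, _forward_core, embed_batch, pad_codes
from .autograd import EPS_NORM, cosine_distance_grad
from ._kernels import span_grads_exp

MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a model file cannot be loaded as the current format."""


@dataclass(frozen=True)
class TrainingPair:
    """Two sequences and their alignment distance (the regression target)."""

    seq_a: Sequence
    seq_b: Sequence
    d_a: float

    def __post_init__(self):
        if not 0.0 <= self.d_a <= 1.0:
            raise ValueError(f"d_a must lie in [0, 1], got {self.d_a}")


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Pattern count and length default to the published operating point
    (300 patterns of length 20); learning rate 1e-4 and 200 epochs match
    the published Adam setup.  Batch size, initialization and the
    per-batch mean (rather than sum) of the squared errors are this
    package's choices.
    """

    n_patterns: int = 300
    pattern_len: int = 20
    gamma: float = 0.1
    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if min(self.n_patterns, self.pattern_len, self.epochs,
               self.batch_size) < 1:
            raise ValueError("n_patterns, pattern_len, epochs and "
                             "batch_size must be positive")


def cosine_distance(u1: np.ndarray, u2: np.ndarray) -> float:
    """1 - (u1.u2) / ((||u1|| + eps)(||u2|| + eps)), eps = 1e-8.

    Symmetric; for nonnegative embeddings the value lies in [0, 1] up to
    the epsilon slack.  Two zero vectors are at distance 1.
    """
    u1 = np.asarray(u1, dtype=np.float64)
    u2 = np.asarray(u2, dtype=np.float64)
    if u1.shape != u2.shape:
        raise ValueError("embeddings must have the same dimension")
    denom = (np.linalg.norm(u1) + EPS_NORM) * (np.linalg.norm(u2) + EPS_NORM)
    return float(1.0 - (u1 @ u2) / denom)


def mse_loss(pairs: TSequence[TrainingPair], params: PatternSet) -> float:
    """Mean squared error between embedding distances and targets."""
    if not pairs:
        raise ValueError("pairs must be nonempty")
    seqs, index = _unique_sequences(pairs)
    U = embed_batch(seqs, params)
    err = 0.0
    for k, p in enumerate(pairs):
        ia, ib = index[2 * k], index[2 * k + 1]
        de = cosine_distance(U[ia], U[ib])
        err += (de - p.d_a) ** 2
    return err / len(pairs)


def _unique_sequences(pairs) -> Tuple[List[Sequence], List[int]]:
    """Deduplicate the sequences of a pair list, preserving first-seen order."""
    seqs: List[Sequence] = []
    where = {}
    index: List[int] = []
    for p in pairs:
        for s in (p.seq_a, p.seq_b):
            key = (s.id, s.residues)
            if key not in where:
                where[key] = len(seqs)
                seqs.append(s)
            index.append(where[key])
    return seqs, index


class _Adam:
    """Adam over a list of parameter arrays (beta1=0.9, beta2=0.999)."""

    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, grads):
        self.t += 1
        out = []
        for i, grad in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad * grad
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(-self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


class AsMacModel:
    """Siamese regression of cosine embedding distance onto d_a.

    Parameters
    ----------
    pairs : list of TrainingPair
        Supervision: sequence pairs with their NW alignment distance.
    config : TrainConfig
        Hyperparameters; all randomness (initialization, shuffling) flows
        from ``config.seed``.
    """

    #: g is floor-clamped here after every optimizer step to stay positive
    MIN_GAP = 1e-3

    def __init__(self, pairs: TSequence[TrainingPair], config: TrainConfig):
        if len(pairs) < config.batch_size:
            raise ValueError("need at least one full batch of pairs")
        self.pairs = list(pairs)
        self.config = config

    @classmethod
    def from_sequences(
        cls,
        seqs: TSequence[Sequence],
        n_pairs: int,
        config: TrainConfig,
        scoring: NWScoring = NWScoring(),
        rng: Optional[np.random.Generator] = None,
    ) -> "AsMacModel":
        """Sample training pairs (with replacement, self-pairs excluded)
        and compute their alignment distances."""
        if len(seqs) < 2:
            raise ValueError("need at least two sequences")
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        pairs = []
        for _ in range(n_pairs):
            ia, ib = rng.choice(len(seqs), size=2, replace=False)
            pairs.append(
                TrainingPair(
                    seqs[ia], seqs[ib],
                    alignment_distance(seqs[ia], seqs[ib], scoring),
                )
            )
        return cls(pairs, config)

    def initial_parameters(self, rng: np.random.Generator) -> PatternSet:
        """Patterns i.i.d. uniform(-1/2, 1/2), g = 1, b = 0.

        The zero-mean init keeps initial per-position rewards centred, so
        pattern scores (and hence cosine distances) start spread out
        instead of collapsed onto a common large positive value; an
        all-positive init leaves the embedding distances orders of
        magnitude below the alignment distances they must regress onto.
        """
        cfg = self.config
        return PatternSet(
            patterns=rng.random((cfg.n_patterns, cfg.pattern_len, 4)) - 0.5,
            gap_penalty=1.0,
            bias=np.zeros(cfg.n_patterns),
            gamma=cfg.gamma,
        )

    def fit(
        self,
        callback: Optional[Callable[[int, float], None]] = None,
    ) -> "AsMacResults":
        """Run Adam for the configured number of epochs.

        Returns an :class:`AsMacResults`; reproducible bit-for-bit given
        the seed.  ``callback(epoch, loss)`` is invoked after each epoch.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        params = self.initial_parameters(rng)

        seqs, index = _unique_sequences(self.pairs)
        code_arrays = [encode_codes(s) for s in seqs]
        pair_idx = np.array(index, dtype=np.int64).reshape(-1, 2)
        targets = np.array([p.d_a for p in self.pairs])
        n_pairs = len(self.pairs)

        opt = _Adam(
            [params.patterns.shape, (), params.bias.shape], cfg.learning_rate
        )
        history: List[float] = []
        for epoch in range(cfg.epochs):
            perm = rng.permutation(n_pairs)
            sq_err_sum = 0.0
            for lo in range(0, n_pairs, cfg.batch_size):
                batch = perm[lo : lo + cfg.batch_size]
                loss, grads = self._batch_grads(
                    params, code_arrays, pair_idx[batch], targets[batch]
                )
                if not math.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss in epoch {epoch}, batch "
                        f"starting at shuffled index {lo}"
                    )
                sq_err_sum += loss * len(batch)
                dp, dg, db = opt.step(grads)
                params.patterns += dp
                params.gap_penalty = max(
                    params.gap_penalty + float(dg), self.MIN_GAP
                )
                params.bias += db
            epoch_loss = sq_err_sum / n_pairs
            history.append(epoch_loss)
            if callback is not None:
                callback(epoch, epoch_loss)
        return AsMacResults(model=self, params=params, loss_history=history)

    @staticmethod
    def _batch_grads(params, code_arrays, pair_idx, targets):
        """Loss and parameter gradients of one mini-batch (mean squared
        error over the batch)."""
        uniq, inv = np.unique(pair_idx.ravel(), return_inverse=True)
        inv = inv.reshape(pair_idx.shape)
        codes, lengths = pad_codes([code_arrays[i] for i in uniq])
        g, gamma = params.gap_penalty, params.gamma
        reward_tab, E, sc, v, argcol = _forward_core(
            params.patterns, codes, lengths, g, gamma
        )
        if E is not None:
            dvdP, dvdg, _ = span_grads_exp(
                E, sc, reward_tab, codes, CODE_ROWS, argcol,
                params.pattern_len, g, gamma,
            )
        else:
            # extreme gamma/pattern scale: reference log-domain path
            dvdP, dvdg = _span_grads_reference(
                params, codes, lengths, argcol
            )

        U = np.maximum(v + params.bias, 0.0)
        mask = (v + params.bias > 0).astype(float)
        B = pair_idx.shape[0]
        coeff = np.zeros_like(v)  # dC/dv_n per batch sequence
        loss = 0.0
        for k in range(B):
            ia, ib = inv[k]
            de, d1, d2 = cosine_distance_grad(U[ia], U[ib])
            resid = de - targets[k]
            loss += resid * resid
            scale = 2.0 * resid / B
            coeff[ia] += scale * d1 * mask[ia]
            coeff[ib] += scale * d2 * mask[ib]
        loss /= B

        d_patterns = np.einsum("sn,snma->nma", coeff, dvdP)
        d_gap = float(np.sum(coeff * dvdg))
        d_bias = coeff.sum(axis=0)
        return loss, (d_patterns, d_gap, d_bias)


def _span_grads_reference(params, codes, lengths, argcol):
    """Per-(sequence, pattern) window gradients via the reference numpy
    path; used only when the exponent-domain kernel is out of range."""
    from .asmnet import _forward_logspace, _reward_table, best_match_span
    from .autograd import grad_gap, grad_pattern

    g, gamma = params.gap_penalty, params.gamma
    M = params.pattern_len
    S, N = argcol.shape
    reward_tab = _reward_table(params.patterns)
    F, _, _ = _forward_logspace(reward_tab, codes, lengths, g, gamma)
    dvdP = np.zeros((S, N, M, 4))
    dvdg = np.zeros((S, N))
    for s in range(S):
        oh = CODE_ROWS[codes[s, : lengths[s]]]
        for n in range(N):
            L = lengths[s]
            lo, hi = best_match_span(
                F[s, n, :, : L + 1], g, gamma, params.patterns[n],
                OneHotSeq(oh),
            )
            window = oh[lo - 1 : hi]
            if window.shape[0] == 0:
                dvdg[s, n] = -float(M)
                continue
            dvdP[s, n] = grad_pattern(params.patterns[n], window, g, gamma)
            dvdg[s, n] = grad_gap(params.patterns[n], window, g, gamma)
    return dvdP, dvdg


@dataclass
class AsMacResults:
    """Fitted parameters plus diagnostics returned by `AsMacModel.fit`."""

    model: Optional[AsMacModel]
    params: PatternSet
    loss_history: List[float] = field(default_factory=list)

    def embed(self, seqs) -> np.ndarray:
        """Embed one or several sequences with the fitted parameters."""
        single = isinstance(seqs, (Sequence, OneHotSeq, str))
        out = embed_batch([seqs] if single else list(seqs), self.params)
        return out[0] if single else out

    def predict(self, pairs) -> np.ndarray:
        """Estimated alignment distance per (seq_a, seq_b) pair."""
        flat = []
        for a, b in pairs:
            flat.extend((a, b))
        U = embed_batch(flat, self.params)
        return np.array(
            [cosine_distance(U[2 * k], U[2 * k + 1])
             for k in range(len(U) // 2)]
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "AsMac Siamese embedding fit",
            "=" * 42,
            f"{'patterns (N)':<28}{p.n_patterns:>14d}",
            f"{'pattern length (M)':<28}{p.pattern_len:>14d}",
            f"{'smoothing gamma':<28}{p.gamma:>14.4g}",
            f"{'fitted gap penalty g':<28}{p.gap_penalty:>14.6g}",
            f"{'bias mean':<28}{float(np.mean(p.bias)):>14.6g}",
            f"{'epochs run':<28}{len(self.loss_history):>14d}",
        ]
        if self.loss_history:
            lines += [
                f"{'initial loss (MSE)':<28}{self.loss_history[0]:>14.6g}",
                f"{'final loss (MSE)':<28}{self.loss_history[-1]:>14.6g}",
            ]
        if self.model is not None:
            lines.append(
                f"{'training pairs':<28}{len(self.model.pairs):>14d}"
            )
        lines.append("=" * 42)
        return "\n".join(lines)

    def save(self, path: Union[str, Path]) -> None:
        save_model(self.params, path)


def save_model(params: PatternSet, path: Union[str, Path]) -> None:
    """Write a versioned structured-text (JSON) model container.

    Floats are serialized by Python's shortest round-trip repr, so
    load(save(p)) is bit-exact.
    """
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "alphabet_order": params.alphabet_order,
        "n_patterns": params.n_patterns,
        "pattern_len": params.pattern_len,
        "gamma": params.gamma,
        "gap_penalty": params.gap_penalty,
        "bias": params.bias.tolist(),
        "patterns": params.patterns.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: Union[str, Path]) -> PatternSet:
    """Load a model container written by :func:`save_model`."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as e:
        raise ModelFormatError(f"cannot parse model file {path}: {e}") from e
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {version!r} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    params = PatternSet(
        patterns=np.array(doc["patterns"], dtype=np.float64),
        gap_penalty=float(doc["gap_penalty"]),
        bias=np.array(doc["bias"], dtype=np.float64),
        gamma=float(doc["gamma"]),
        alphabet_order=doc["alphabet_order"],
    )
    if (params.n_patterns != doc["n_patterns"]
            or params.pattern_len != doc["pattern_len"]):
        raise ModelFormatError("model file dimensions are inconsistent")
    return params
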