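"""Held-out edge prediction.

A fraction of one network's edges is held out (marked unobserved, so they
are *discarded from the likelihood*, not set to zero), the model is
refitted, and each held-out pair is scored with the posterior edge
probability

    p(A_ij = 1) = (mc - md) * sum_k Q^(t)_ik Q^(t)_jk + md,

where ``mc`` and ``md`` are the posterior means of the within- and
between-module edge probabilities.  Ranking quality over held-out positives
and sampled (or all) non-edge negatives is summarized by ROC and
precision-recall AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from ._rng import substream
from .datatypes import Hyperparameters, MultiNetwork, VariationalState
from .vb import FitOptions, fit

__all__ = [
    "HoldoutSplit",
    "make_holdout",
    "apply_holdout",
    "edge_probability",
    "score_test_pairs",
    "fit_with_missing",
    "evaluate_auc",
]


@dataclass
class HoldoutSplit:
    """A train/test split of one network's vertex pairs.

    ``train_mask`` is a symmetric boolean matrix marking pairs kept in the
    likelihood; ``test_pairs`` holds ``(i, j, label)`` triples in canonical
    ``i > j`` order for the held-out positives and the chosen negatives.
    """

    train_mask: np.ndarray
    test_pairs: list[tuple[int, int, int]]
    train_ratio: float
    seed: int
    target: int = 0


def make_holdout(
    net: MultiNetwork,
    train_ratio: float,
    seed: int,
    negatives: str = "balanced",
    target: int = 0,
) -> HoldoutSplit:
    """Hold out ``(1 - train_ratio) * |E|`` edges of network ``target``.

    Under ``negatives="balanced"`` an equal number of non-edge pairs is also
    masked out and used as test negatives, keeping the positive/negative
    ratio of the test set constant across training ratios.  Under
    ``negatives="all"`` only the held-out edges leave the likelihood and
    every non-edge pair serves as a test negative.
    """
    if not 0.0 < train_ratio < 1.0:
        raise ValueError("train_ratio must lie strictly in (0, 1)")
    if negatives not in ("balanced", "all"):
        raise ValueError(f"unknown negatives mode {negatives!r}")
    A = net.adjacency[target]
    N = net.n_vertices
    rng = substream(seed, "holdout")
    iu, ju = np.triu_indices(N, k=1)
    is_edge = A[iu, ju] > 0
    edge_idx = np.flatnonzero(is_edge)
    non_idx = np.flatnonzero(~is_edge)
    n_hold = int(round((1.0 - train_ratio) * edge_idx.size))
    if n_hold == 0:
        raise ValueError("train_ratio too high: no edges would be held out")
    held = rng.choice(edge_idx, size=n_hold, replace=False)
    mask = np.ones((N, N), dtype=bool)
    np.fill_diagonal(mask, False)
    test_pairs: list[tuple[int, int, int]] = []
    for idx in held:
        i, j = int(ju[idx]), int(iu[idx])  # canonical i > j
        mask[i, j] = mask[j, i] = False
        test_pairs.append((i, j, 1))
    if negatives == "balanced":
        if non_idx.size < n_hold:
            raise ValueError(
                f"only {non_idx.size} non-edges available for {n_hold} negatives"
            )
        neg = rng.choice(non_idx, size=n_hold, replace=False)
        for idx in neg:
            i, j = int(ju[idx]), int(iu[idx])
            mask[i, j] = mask[j, i] = False
            test_pairs.append((i, j, 0))
    else:
        for idx in non_idx:
            test_pairs.append((int(ju[idx]), int(iu[idx]), 0))
    return HoldoutSplit(mask, test_pairs, train_ratio, seed, target)


def apply_holdout(net: MultiNetwork, split: HoldoutSplit) -> MultiNetwork:
    """Copy of ``net`` with the split's mask installed on the target network."""
    masks = (
        [m.copy() for m in net.observed_mask]
        if net.observed_mask is not None
        else [np.ones((net.n_vertices, net.n_vertices), dtype=bool)
              for _ in range(net.n_networks)]
    )
    masks[split.target] = masks[split.target] & split.train_mask
    return MultiNetwork(
        [A.copy() for A in net.adjacency], list(net.vertex_ids), masks
    )


def edge_probability(state: VariationalState, i: int, j: int, t: int = 0) -> float:
    """Posterior probability of an edge between vertices ``i`` and ``j`` in
    network ``t``, from that network's soft assignments."""
    if i == j:
        raise ValueError("self pairs have no edge probability")
    mc = state.alpha_c_tilde / (state.alpha_c_tilde + state.beta_c_tilde)
    md = state.alpha_d_tilde / (state.alpha_d_tilde + state.beta_d_tilde)
    Qt = state.Q_t[t]
    return float((mc - md) * np.dot(Qt[i], Qt[j]) + md)


def score_test_pairs(state: VariationalState, split: HoldoutSplit) -> np.ndarray:
    """Edge probabilities for every test pair of a split (vectorized)."""
    mc = state.alpha_c_tilde / (state.alpha_c_tilde + state.beta_c_tilde)
    md = state.alpha_d_tilde / (state.alpha_d_tilde + state.beta_d_tilde)
    Qt = state.Q_t[split.target]
    ii = np.array([p[0] for p in split.test_pairs])
    jj = np.array([p[1] for p in split.test_pairs])
    return (mc - md) * np.sum(Qt[ii] * Qt[jj], axis=1) + md


def fit_with_missing(
    net: MultiNetwork, hyper: Hyperparameters, opts: FitOptions | None = None
) -> VariationalState:
    """Fit with held-out pairs excluded from every likelihood sum.

    Identical to the full fit except that the pair sums in the
    instantaneous-assignment and Beta-hyperparameter updates range only over
    observed pairs, as carried by ``net.observed_mask``.
    """
    if net.observed_mask is not None:
        observed_pairs = sum(
            net.pair_mask(t).sum(axis=1) for t in range(net.n_networks)
        )
        if (observed_pairs == 0).any():
            import warnings

            n_dead = int((observed_pairs == 0).sum())
            warnings.warn(
                f"{n_dead} vertices have no observed pairs in any network; "
                "their assignments are driven by the prior only",
                stacklevel=2,
            )
    return fit(net, hyper, opts)


def evaluate_auc(
    split: HoldoutSplit, scores: np.ndarray
) -> tuple[float, float]:
    """ROC AUC (trapezoidal, midrank ties) and PR AUC (average precision)."""
    labels = np.array([p[2] for p in split.test_pairs])
    scores = np.asarray(scores, dtype=float)
    if labels.size != scores.size:
        raise ValueError("scores and test pairs differ in length")
    if labels.min() == labels.max():
        raise ValueError("test set needs at least one positive and one negative")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )
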