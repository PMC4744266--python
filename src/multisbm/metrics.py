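"""Evaluation statistics for partitions and protein-complex predictions.

Partition agreement is measured by normalized mutual information with the
max-entropy normalization, NMI = MI / max(H, H'), in natural logarithms.
Complex-level evaluation against a reference catalogue uses the overlap
score ``omega(V1, V2) = |V1 n V2|^2 / (|V1| |V2|)`` with the conventional
match threshold 0.25 (reached when two equal-size complexes share half
their members), the contingency-table statistics Sn, PPV and their
geometric mean Acc, and the module-wise separation score Sep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .datatypes import ComplexSet, Partition

__all__ = [
    "ContingencyTable",
    "nmi",
    "overlap_score",
    "contingency",
    "frac_matched",
    "accuracy",
    "separation",
    "partition_to_complexes",
]


@dataclass
class ContingencyTable:
    """``t[i, j]``: members shared by reference complex ``i`` and predicted
    complex ``j``; ``ref_sizes[i]``: total size of reference complex ``i``."""

    t: np.ndarray
    ref_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.ref_sizes = np.asarray(self.ref_sizes, dtype=np.float64)
        if self.t.ndim != 2:
            raise ValueError("contingency table must be 2-d")
        if (self.t < 0).any() or (self.ref_sizes <= 0).any():
            raise ValueError("counts must be non-negative, sizes positive")
        if self.ref_sizes.size != self.t.shape[0]:
            raise ValueError("one reference size per table row required")


def nmi(truth: Partition, pred: Partition) -> float:
    """Normalized mutual information, MI / max(H(truth), H(pred)).

    Natural logarithms throughout, ``0 ln 0 := 0``.  When both partitions
    are single-cluster the MI and both entropies vanish; the value is
    defined as 0.
    """
    if len(truth) != len(pred):
        raise ValueError("partitions must have equal length")
    n = len(truth)
    joint = np.zeros((truth.n_modules(), pred.n_modules()))
    np.add.at(joint, (truth.labels, pred.labels), 1.0)
    p = joint / n
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / (pr * pc), 1.0)
    mi = float(np.sum(xlogy(p, ratio)))
    h_true = -float(np.sum(xlogy(pr, pr)))
    h_pred = -float(np.sum(xlogy(pc, pc)))
    denom = max(h_true, h_pred)
    if denom <= 0.0:
        return 0.0
    return mi / denom


def overlap_score(V1: set, V2: set) -> float:
    """``omega = |V1 n V2|^2 / (|V1| |V2|)``; symmetric, in [0, 1]."""
    if not V1 or not V2:
        raise ValueError("overlap score requires non-empty sets")
    inter = len(set(V1) & set(V2))
    return inter * inter / (len(V1) * len(V2))


def contingency(reference: ComplexSet, predicted: ComplexSet) -> ContingencyTable:
    """Shared-member counts between every reference/predicted complex pair."""
    t = np.array(
        [[len(r & p) for p in predicted.complexes] for r in reference.complexes],
        dtype=np.float64,
    )
    sizes = np.array([len(r) for r in reference.complexes], dtype=np.float64)
    return ContingencyTable(t, sizes)


def frac_matched(
    reference: ComplexSet, predicted: ComplexSet, threshold: float = 0.25
) -> float:
    """Fraction of reference complexes matched by some prediction.

    A reference complex counts as matched when at least one predicted
    complex overlaps it with ``omega`` strictly greater than ``threshold``.
    """
    if len(reference) == 0 or len(predicted) == 0:
        raise ValueError("both complex sets must be non-empty")
    matched = 0
    for r in reference.complexes:
        if any(overlap_score(r, p) > threshold for p in predicted.complexes):
            matched += 1
    return matched / len(reference)


def accuracy(table: ContingencyTable) -> tuple[float, float, float]:
    """(Sn, PPV, Acc): module-wise sensitivity, positive predictive value
    and their geometric mean.

    ``Sn = sum_i max_j t_ij / sum_i n_i`` rewards covering each reference
    complex with one prediction; ``PPV = sum_j max_i t_ij / sum_ij t_ij``
    rewards predictions pure with respect to the reference;
    ``Acc = sqrt(Sn * PPV)``.
    """
    t = table.t
    total = t.sum()
    if total <= 0:
        raise ValueError("contingency table is all zero")
    sn = float(t.max(axis=1).sum() / table.ref_sizes.sum())
    ppv = float(t.max(axis=0).sum() / total)
    return sn, ppv, float(np.sqrt(sn * ppv))


def separation(table: ContingencyTable) -> tuple[float, float, float]:
    """(Sep_ref, Sep_inf, Sep): products of row- and column-wise relative
    frequencies, aggregated per predicted (``/m``) and per reference
    (``/n``) complex and combined by geometric mean.

    Rows or columns summing to zero (complexes sharing no member with the
    other side) contribute 0.
    """
    t = table.t
    if t.sum() <= 0:
        raise ValueError("contingency table is all zero")
    n, m = t.shape
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        Fr = np.where(row > 0, t / np.where(row > 0, row, 1.0), 0.0)
        Fc = np.where(col > 0, t / np.where(col > 0, col, 1.0), 0.0)
    sep_ij = Fr * Fc
    total = float(sep_ij.sum())
    sep_ref = total / m
    sep_inf = total / n
    return sep_ref, sep_inf, float(np.sqrt(sep_ref * sep_inf))


def partition_to_complexes(
    p: Partition, vertex_ids: list[str] | None = None, min_size: int = 1
) -> ComplexSet:
    """Group vertices by module label; drop modules smaller than ``min_size``."""
    if vertex_ids is None:
        vertex_ids = [f"v{i:03d}" for i in range(len(p))]
    if len(vertex_ids) != len(p):
        raise ValueError("vertex_ids length must match the partition")
    groups: dict[int, set[str]] = {}
    for v, lab in zip(vertex_ids, p.labels):
        groups.setdefault(int(lab), set()).add(v)
    complexes = [
        frozenset(members)
        for lab, members in sorted(groups.items())
        if len(members) >= min_size
    ]
    return ComplexSet(complexes, name="modules")
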