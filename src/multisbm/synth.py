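"""Planted-partition benchmarks and degree-preserving noise.

The generator emulates the classical community-detection benchmark: ``N``
vertices split into ``K`` modules, each unordered pair connected
independently with probability ``theta_c`` inside a module and ``theta_d``
across modules.  The standard parameterisation fixes the expected total
degree and the expected between-module degree of a vertex (16 and 6 for the
N=128, K=4, 32-vertices-per-module benchmark), from which the two edge
probabilities follow.

Noisy observations are produced by Maslov-Sneppen rewiring: repeatedly pick
two distinct edges ``(i, j)`` and ``(k, l)`` and replace them with ``(i, l)``
and ``(j, k)`` unless that would create a self-loop or a duplicate edge.
Each accepted swap preserves every vertex degree exactly; the noise level is
the number of accepted swaps as a fraction of the edge count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .datatypes import MultiNetwork, Partition

__all__ = [
    "SynthSpec",
    "params_from_degree_targets",
    "generate_planted_partition",
    "maslov_sneppen_rewire",
    "generate_experiment_one",
    "generate_experiment_two",
]


@dataclass
class SynthSpec:
    """Parameters of one planted-partition draw.

    ``module_sizes`` fixes exact module sizes (they must sum to ``N``).
    Alternatively ``assignment_probs`` samples each vertex's module from a
    multinomial with those weights.  Exactly one of the two must be given;
    the benchmark default is exact equal sizes.
    """

    N: int
    K: int
    theta_c: float
    theta_d: float
    seed: int = 0
    module_sizes: list[int] | None = None
    assignment_probs: list[float] | None = None

    def __post_init__(self) -> None:
        if self.N < 1 or self.K < 1:
            raise ValueError("N and K must be positive")
        if not (0.0 <= self.theta_d <= self.theta_c <= 1.0):
            raise ValueError("need 0 <= theta_d <= theta_c <= 1")
        if self.module_sizes is None and self.assignment_probs is None:
            q, r = divmod(self.N, self.K)
            self.module_sizes = [q + (1 if k < r else 0) for k in range(self.K)]
        if self.module_sizes is not None and self.assignment_probs is not None:
            raise ValueError("give module_sizes or assignment_probs, not both")
        if self.module_sizes is not None:
            if len(self.module_sizes) != self.K or sum(self.module_sizes) != self.N:
                raise ValueError("module_sizes must be K values summing to N")

    @classmethod
    def benchmark(cls, seed: int = 0) -> "SynthSpec":
        """The N=128, K=4, degree-16/between-6 benchmark."""
        theta_c, theta_d = params_from_degree_targets(16.0, 6.0, 32, 128)
        return cls(N=128, K=4, theta_c=theta_c, theta_d=theta_d, seed=seed)


def params_from_degree_targets(
    avg_degree: float, avg_between_degree: float, module_size: int, N: int
) -> tuple[float, float]:
    """Edge probabilities matching expected total and between-module degree.

    A vertex in a module of size ``m`` has ``m - 1`` potential within-module
    partners and ``N - m`` between-module partners, so::

        theta_c = (avg_degree - avg_between_degree) / (module_size - 1)
        theta_d = avg_between_degree / (N - module_size)

    Raises a domain error when either probability leaves [0, 1].
    """
    if not 0 <= avg_between_degree < avg_degree:
        raise ValueError("require 0 <= avg_between_degree < avg_degree")
    if not 1 < module_size < N:
        raise ValueError("require 1 < module_size < N")
    theta_c = (avg_degree - avg_between_degree) / (module_size - 1)
    theta_d = avg_between_degree / (N - module_size)
    if not (0.0 <= theta_c <= 1.0 and 0.0 <= theta_d <= 1.0):
        raise ValueError(
            f"degree targets give probabilities outside [0, 1]: "
            f"theta_c={theta_c:.4g}, theta_d={theta_d:.4g}"
        )
    return theta_c, theta_d


def generate_planted_partition(spec: SynthSpec) -> tuple[MultiNetwork, Partition]:
    """Sample one planted-partition network and its ground-truth labels."""
    rng = substream(spec.seed, "planted")
    if spec.module_sizes is not None:
        labels = np.repeat(np.arange(spec.K), spec.module_sizes)
    else:
        probs = np.asarray(spec.assignment_probs, dtype=float)
        labels = rng.choice(spec.K, size=spec.N, p=probs / probs.sum())
    N = spec.N
    iu, ju = np.triu_indices(N, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(same, spec.theta_c, spec.theta_d)
    draw = rng.random(iu.size) < p
    A = np.zeros((N, N))
    A[iu[draw], ju[draw]] = 1.0
    A += A.T
    ids = [f"v{i:03d}" for i in range(N)]
    return MultiNetwork([A], ids), Partition(labels)


def maslov_sneppen_rewire(
    net: MultiNetwork, fraction: float, seed: int
) -> MultiNetwork:
    """Degree-preserving randomization of a single network.

    Performs ``round(fraction * |E|)`` *accepted* edge swaps.  A proposal
    draws two distinct edges uniformly from the current edge set, orients
    each endpoint pair uniformly at random, and crosses them as
    ``(i, j), (k, l) -> (i, l), (j, k)``; it is rejected (and not counted)
    when the crossing would create a self-loop or an edge that already
    exists.  Aborts if 1000x the quota of proposals fail to reach it.
    """
    if net.n_networks != 1:
        raise ValueError("rewiring operates on a single network")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    A = net.adjacency[0].copy()
    iu, ju = np.nonzero(np.triu(A, k=1))
    edges = [(int(a), int(b)) for a, b in zip(iu, ju)]
    quota = int(round(fraction * len(edges)))
    if quota == 0:
        return MultiNetwork([A], list(net.vertex_ids))
    if len(edges) < 2:
        raise ValueError("need at least two edges to rewire")
    edge_set = set(edges)
    rng = substream(seed, "rewire")
    done = 0
    proposals = 0
    limit = 1000 * quota
    while done < quota:
        if proposals >= limit:
            raise RuntimeError(
                f"rewiring stalled: {done}/{quota} swaps after {proposals} proposals"
            )
        proposals += 1
        e1, e2 = rng.choice(len(edges), size=2, replace=False)
        i, j = edges[e1]
        k, l = edges[e2]
        if rng.random() < 0.5:
            i, j = j, i
        if rng.random() < 0.5:
            k, l = l, k
        # proposed crossing: i-l and j-k
        if i == l or j == k:
            continue
        new1 = (min(i, l), max(i, l))
        new2 = (min(j, k), max(j, k))
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        old1, old2 = edges[e1], edges[e2]
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        done += 1
    B = np.zeros_like(A)
    for a, b in edges:
        B[a, b] = B[b, a] = 1.0
    return MultiNetwork([B], list(net.vertex_ids))


def _rewire_series(
    spec: SynthSpec, fractions: list[float]
) -> tuple[MultiNetwork, Partition]:
    base, truth = generate_planted_partition(spec)
    nets = []
    for t, frac in enumerate(fractions):
        sub = substream(spec.seed, "series", t)
        noisy = maslov_sneppen_rewire(base, frac, seed=int(sub.integers(2**31)))
        nets.append(noisy.adjacency[0])
    return MultiNetwork(nets, list(base.vertex_ids)), truth


def generate_experiment_one(spec: SynthSpec, T: int = 10) -> tuple[MultiNetwork, Partition]:
    """Graded noise: T independent rewirings at fractions 5%, 10%, ..., 50%.

    Each observation rewires the *same* planted draw independently; the
    fraction grows linearly from 0.05 at t=1 to 0.50 at t=T.
    """
    fractions = list(np.linspace(0.05, 0.50, T)) if T > 1 else [0.05]
    return _rewire_series(spec, fractions)


def generate_experiment_two(
    spec: SynthSpec, T: int = 10, fraction: float = 0.25
) -> tuple[MultiNetwork, Partition]:
    """Constant noise: T independent rewirings at one fraction (default 25%)."""
    return _rewire_series(spec, [fraction] * T)
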