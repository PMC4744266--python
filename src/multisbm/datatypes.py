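"""Core data containers for multi-network stochastic block modelling.

The model observes ``T`` undirected, simple, binary networks over a shared
vertex set of size ``N``.  A latent *root* module assignment ``z`` (one of
``K`` modules per vertex) generates per-network *instantaneous* assignments
``z^(t)`` through row-stochastic transition matrices ``P^(t)``; each network's
edges are then Bernoulli with within-module probability ``theta_c`` and
between-module probability ``theta_d``.

This module houses the shared containers (:class:`MultiNetwork`,
:class:`Hyperparameters`, :class:`VariationalState`, :class:`Partition`,
:class:`ComplexSet`), the exact joint log-probability of the generative
model, and the hard readout of soft assignments.

Conventions
-----------
* Module labels are 0-based in memory; file I/O (see :mod:`multisbm.io`)
  converts to 1-based labels at the boundary.
* Vertex pairs are unordered and enumerated as ``i > j`` (strict upper
  triangle); self-pairs never contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiNetwork",
    "Hyperparameters",
    "VariationalState",
    "Partition",
    "ComplexSet",
    "joint_log_prob",
    "hard_assignments",
]


def _check_adjacency(A: np.ndarray, N: int, t: int) -> np.ndarray:
    A = np.asarray(A)
    if A.shape != (N, N):
        raise ValueError(f"adjacency {t} has shape {A.shape}, expected {(N, N)}")
    if not np.isin(A, (0, 1)).all():
        raise ValueError(f"adjacency {t} has entries outside {{0, 1}}")
    A = A.astype(np.float64)
    if not np.array_equal(A, A.T):
        raise ValueError(f"adjacency {t} is not symmetric")
    if np.diagonal(A).any():
        raise ValueError(f"adjacency {t} has a non-zero diagonal (self-loop)")
    return A


@dataclass
class MultiNetwork:
    """``T`` binary adjacency matrices ``A^(t)`` on a shared vertex set.

    Parameters
    ----------
    adjacency:
        List of ``T`` symmetric binary ``(N, N)`` arrays with zero diagonal.
    vertex_ids:
        ``N`` string labels, shared (same order) by every network.
    observed_mask:
        Optional list of ``T`` symmetric boolean ``(N, N)`` arrays marking
        which vertex pairs enter the likelihood.  ``None`` means fully
        observed.  The diagonal is ignored (self-pairs never count).
    """

    adjacency: list[np.ndarray]
    vertex_ids: list[str]
    observed_mask: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.adjacency:
            raise ValueError("at least one network is required")
        N = len(self.vertex_ids)
        if len(set(self.vertex_ids)) != N:
            raise ValueError("vertex_ids contains duplicates")
        self.adjacency = [
            _check_adjacency(A, N, t) for t, A in enumerate(self.adjacency)
        ]
        if self.observed_mask is not None:
            if len(self.observed_mask) != len(self.adjacency):
                raise ValueError("observed_mask must have one entry per network")
            masks = []
            for t, M in enumerate(self.observed_mask):
                M = np.asarray(M, dtype=bool)
                if M.shape != (N, N):
                    raise ValueError(f"mask {t} has shape {M.shape}, expected {(N, N)}")
                if not np.array_equal(M, M.T):
                    raise ValueError(f"mask {t} is not symmetric")
                masks.append(M)
            self.observed_mask = masks

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_networks(self) -> int:
        return len(self.adjacency)

    def pair_mask(self, t: int) -> np.ndarray:
        """Float ``(N, N)`` indicator of observed off-diagonal pairs of network ``t``."""
        N = self.n_vertices
        M = np.ones((N, N))
        if self.observed_mask is not None:
            M *= self.observed_mask[t]
        np.fill_diagonal(M, 0.0)
        return M

    def single(self, t: int) -> "MultiNetwork":
        """Extract network ``t`` as a one-network :class:`MultiNetwork`."""
        mask = None if self.observed_mask is None else [self.observed_mask[t]]
        return MultiNetwork([self.adjacency[t].copy()], list(self.vertex_ids), mask)


@dataclass
class Hyperparameters:
    """Conjugate prior pseudo-counts of the multi-network SBM.

    ``n0`` parameterises the Dirichlet prior over the root assignment
    probabilities ``pi``; ``(alpha_c0, beta_c0)`` and ``(alpha_d0, beta_d0)``
    the Beta priors over the within/between edge probabilities; row ``k`` of
    ``eta0`` the Dirichlet prior over row ``k`` of every transition matrix
    ``P^(t)``.

    The defaults encode the two structural biases of the model: edges are
    denser within modules than between (prior mean of ``theta_c`` above that
    of ``theta_d``), and instantaneous assignments tend to agree with the
    root (diagonal of ``eta0`` above its off-diagonal).  Magnitudes are mild
    engineering choices and fully configurable.
    """

    n0: np.ndarray
    alpha_c0: float = 2.0
    beta_c0: float = 1.0
    alpha_d0: float = 1.0
    beta_d0: float = 2.0
    eta0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.n0 = np.asarray(self.n0, dtype=np.float64)
        if self.n0.ndim != 1 or self.n0.size < 1:
            raise ValueError("n0 must be a 1-d vector of length K")
        K = self.K
        if self.eta0 is None:
            self.eta0 = np.ones((K, K)) + 4.0 * np.eye(K)
        self.eta0 = np.asarray(self.eta0, dtype=np.float64)
        if self.eta0.shape != (K, K):
            raise ValueError(f"eta0 must be ({K}, {K})")
        for name in ("alpha_c0", "beta_c0", "alpha_d0", "beta_d0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (self.n0 > 0).all() or not (self.eta0 > 0).all():
            raise ValueError("all Dirichlet pseudo-counts must be strictly positive")

    @classmethod
    def default(cls, K: int, **overrides) -> "Hyperparameters":
        """Uniform ``n0`` and the default biased Beta/Dirichlet priors."""
        if K < 1:
            raise ValueError("K must be >= 1")
        return cls(n0=np.ones(K), **overrides)

    @property
    def K(self) -> int:
        return self.n0.size


@dataclass
class VariationalState:
    """Posterior factors of the mean-field approximation.

    ``Q`` (root) and each ``Q_t[t]`` (instantaneous) are ``(N, K)``
    row-stochastic matrices of soft assignments; the remaining fields are
    the posterior Dirichlet/Beta hyperparameters, plus the free-energy trace
    recorded over iterations.
    """

    Q: np.ndarray
    Q_t: list[np.ndarray]
    n_tilde: np.ndarray
    eta_tilde: list[np.ndarray]
    alpha_c_tilde: float
    beta_c_tilde: float
    alpha_d_tilde: float
    beta_d_tilde: float
    free_energy_trace: list[float] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.Q.shape[0]

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    @property
    def n_networks(self) -> int:
        return len(self.Q_t)

    @property
    def free_energy(self) -> float:
        if not self.free_energy_trace:
            raise ValueError("no free energy recorded yet")
        return self.free_energy_trace[-1]

    def validate(self, hyper: Hyperparameters | None = None, atol: float = 1e-10) -> None:
        """Check row-stochasticity and (optionally) posterior >= prior."""
        for name, M in [("Q", self.Q)] + [
            (f"Q_t[{t}]", Qt) for t, Qt in enumerate(self.Q_t)
        ]:
            rows = M.sum(axis=1)
            if not np.allclose(rows, 1.0, atol=atol):
                raise ValueError(f"rows of {name} do not sum to 1")
            if (M < 0).any():
                raise ValueError(f"{name} has negative entries")
        if hyper is not None:
            eps = 1e-9
            if (self.n_tilde < hyper.n0 - eps).any():
                raise ValueError("n_tilde below its prior")
            for t, eta in enumerate(self.eta_tilde):
                if (eta < hyper.eta0 - eps).any():
                    raise ValueError(f"eta_tilde[{t}] below its prior")
            for name, prior in [
                ("alpha_c_tilde", hyper.alpha_c0),
                ("beta_c_tilde", hyper.beta_c0),
                ("alpha_d_tilde", hyper.alpha_d0),
                ("beta_d_tilde", hyper.beta_d0),
            ]:
                if getattr(self, name) < prior - eps:
                    raise ValueError(f"{name} below its prior")


@dataclass
class Partition:
    """Hard module labels for ``N`` vertices, 0-based in memory."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-d vector")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0-based)")

    def __len__(self) -> int:
        return self.labels.size

    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def counts(self, K: int | None = None) -> np.ndarray:
        return np.bincount(self.labels, minlength=K or self.n_modules())


@dataclass
class ComplexSet:
    """A named collection of vertex-id sets (reference or predicted complexes)."""

    complexes: list[frozenset[str]]
    name: str = ""

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if any(len(c) == 0 for c in self.complexes):
            raise ValueError("complexes must be non-empty")

    def __len__(self) -> int:
        return len(self.complexes)


def joint_log_prob(
    net: MultiNetwork,
    root: Partition,
    instant: list[Partition],
    theta_c: float,
    theta_d: float,
    pi: np.ndarray,
    P: list[np.ndarray],
) -> float:
    """Log joint probability of assignments and adjacency matrices.

    Evaluates, in log space, the product of (a) the Bernoulli edge terms
    ``theta_c^{c_t^+} (1-theta_c)^{c_t^-} theta_d^{d_t^+} (1-theta_d)^{d_t^-}``
    accumulated over networks, where the four exponents count within/between
    (non-)edges over unordered pairs under ``instant[t]``; (b) the transition
    terms ``prod_t prod_i P^(t)[z_i, z_i^(t)]``; and (c) the root assignment
    term ``prod_k pi_k^{n_k}``.

    ``theta_c`` and ``theta_d`` must lie strictly inside (0, 1); zero entries
    of ``pi`` or ``P`` are permitted and contribute ``-inf`` only when
    actually selected by an assignment.
    """
    T, N = net.n_networks, net.n_vertices
    if not (0.0 < theta_c < 1.0 and 0.0 < theta_d < 1.0):
        raise ValueError("theta_c and theta_d must lie strictly in (0, 1)")
    if len(instant) != T or len(P) != T:
        raise ValueError("need one instantaneous partition and one P per network")
    if len(root) != N or any(len(p) != N for p in instant):
        raise ValueError("partition length does not match vertex count")
    pi = np.asarray(pi, dtype=np.float64)
    K = pi.size
    if root.labels.max(initial=0) >= K:
        raise ValueError("root labels exceed K")

    iu, ju = np.triu_indices(N, k=1)
    total = 0.0
    for t in range(T):
        A = net.adjacency[t]
        zt = instant[t].labels
        same = zt[iu] == zt[ju]
        a = A[iu, ju]
        c_plus = float(a[same].sum())
        c_minus = float((1 - a[same]).sum())
        d_plus = float(a[~same].sum())
        d_minus = float((1 - a[~same]).sum())
        total += (
            c_plus * np.log(theta_c)
            + c_minus * np.log1p(-theta_c)
            + d_plus * np.log(theta_d)
            + d_minus * np.log1p(-theta_d)
        )
        Pt = np.asarray(P[t], dtype=np.float64)
        if Pt.shape != (K, K):
            raise ValueError(f"P[{t}] must be ({K}, {K})")
        trans = Pt[root.labels, zt]
        with np.errstate(divide="ignore"):
            total += float(np.sum(np.log(trans)))
    n_k = root.counts(K)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pi = np.where(n_k > 0, np.log(pi), 0.0)
    total += float(np.sum(n_k * log_pi))
    return total


def hard_assignments(state: VariationalState, level: str | int = "root") -> Partition:
    """Hard readout: assign each vertex to the module maximizing its row.

    ``level`` is ``"root"`` for the root matrix ``Q`` or an integer network
    index for ``Q^(t)``.  Ties break to the lowest module index, so repeated
    runs are reproducible.
    """
    if level == "root":
        M = state.Q
    elif isinstance(level, (int, np.integer)) and not isinstance(level, bool):
        if not 0 <= level < state.n_networks:
            raise ValueError(f"network index {level} out of range")
        M = state.Q_t[level]
    else:
        raise ValueError(f"invalid level {level!r}: expected 'root' or a network index")
    return Partition(np.argmax(M, axis=1))
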