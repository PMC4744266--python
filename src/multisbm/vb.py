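"""Variational Bayes inference for the multi-network stochastic block model.

The posterior over the root assignment ``z``, the instantaneous assignments
``z^(t)``, the edge probabilities ``(theta_c, theta_d)``, the module weights
``pi`` and the transition matrices ``P^(t)`` is approximated by a fully
factorized (mean-field) distribution.  Conjugacy (Beta for the edge
probabilities, Dirichlet for ``pi`` and the rows of each ``P^(t)``) gives
closed-form coordinate updates; the objective is the variational free
energy, the negative evidence lower bound, which is non-increasing across
iterations and upper-bounds the negative log evidence.

The algorithm alternates two stages.  The *assignment stage* holds the
parameter posteriors fixed, computes their expected log-parameters
(digamma differences), and iterates the coupled updates of the root soft
assignments ``Q`` and the instantaneous soft assignments ``Q^(t)``
(synchronous whole-matrix steps, adaptively damped) to their fixed point.
The *parameter stage* then refreshes the Dirichlet posterior ``n_tilde``
over ``pi``, the Dirichlet posteriors ``eta_tilde^(t)`` over transition
rows, and the Beta posteriors over ``theta_c``/``theta_d`` from the
converged assignments, and records the free energy.  Running the
assignment stage to convergence before updating parameters matters: a
single pass from a random start leaves the within-module density at the
global density, the two Beta posteriors coincide, and the coupling signal
dies before any structure can form.

When a :class:`~multisbm.datatypes.MultiNetwork` carries an
``observed_mask``, every pair sum restricts to observed pairs, which is all
that held-out edge prediction requires.

The mean-field objective is multi-modal, so :func:`fit` runs several random
restarts and returns the state with the lowest final free energy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp, xlogy

from ._rng import substream
from .datatypes import Hyperparameters, MultiNetwork, VariationalState

__all__ = [
    "FitOptions",
    "Expectations",
    "init_state",
    "compute_expectations",
    "update_root",
    "update_instant",
    "update_dirichlet_root",
    "update_transition_hyper",
    "update_edge_hyper",
    "free_energy",
    "fit",
    "refine",
    "exact_log_evidence",
    "select_K",
]


@dataclass
class FitOptions:
    """Knobs of the coordinate-ascent loop.

    ``rel_tol`` stops the loop when the relative free-energy change drops
    below it; ``n_restarts`` random initializations guard against local
    optima (the benchmark protocol uses 100; tests use fewer).
    """

    max_iter: int = 500
    rel_tol: float = 1e-6
    n_restarts: int = 100
    seed: int = 0
    record_trace: bool = True
    inner_max_iter: int = 200
    inner_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.rel_tol > 0:
            raise ValueError("rel_tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.inner_max_iter < 1:
            raise ValueError("inner_max_iter must be >= 1")


@dataclass
class Expectations:
    """Expected log-parameters under the current variational posteriors.

    ``eln_pi[k] = E[ln pi_k]``; ``eln_trans[t][k, m] = E[ln P^(t)_km]``;
    ``nonedge[.] = E[ln (1-theta_d)/(1-theta_c)]`` (the penalty a non-edge
    pays for being within-module); ``edge = nonedge + E[ln theta_c/theta_d]``
    (the bonus an edge earns for being within-module).
    """

    eln_pi: np.ndarray
    eln_trans: list[np.ndarray]
    nonedge: float
    edge: float


def _row_normalize_log(L: np.ndarray) -> np.ndarray:
    """exp-normalize rows of a matrix of log-scores (max-subtraction)."""
    L = L - L.max(axis=1, keepdims=True)
    Q = np.exp(L)
    return Q / Q.sum(axis=1, keepdims=True)


def _ln_beta_vec(x: np.ndarray) -> float:
    """Multivariate beta function (log) of a pseudo-count vector."""
    return float(gammaln(x).sum() - gammaln(x.sum()))


def _ln_beta2(a: float, b: float) -> float:
    return float(gammaln(a) + gammaln(b) - gammaln(a + b))


def init_state(net: MultiNetwork, hyper: Hyperparameters, seed: int) -> VariationalState:
    """Random initialization: Dirichlet(1) rows for ``Q`` and every ``Q^(t)``,
    posterior hyperparameters set to their priors."""
    K = hyper.K
    if K < 1:
        raise ValueError("K must be >= 1")
    N, T = net.n_vertices, net.n_networks
    if K > N:
        warnings.warn(f"K={K} exceeds the number of vertices N={N}", stacklevel=2)
    rng = substream(seed, "init")

    def draw() -> np.ndarray:
        g = rng.gamma(shape=1.0, size=(N, K))
        return g / g.sum(axis=1, keepdims=True)

    return VariationalState(
        Q=draw(),
        Q_t=[draw() for _ in range(T)],
        n_tilde=hyper.n0.copy(),
        eta_tilde=[hyper.eta0.copy() for _ in range(T)],
        alpha_c_tilde=hyper.alpha_c0,
        beta_c_tilde=hyper.beta_c0,
        alpha_d_tilde=hyper.alpha_d0,
        beta_d_tilde=hyper.beta_d0,
    )


def compute_expectations(state: VariationalState) -> Expectations:
    """Digamma-difference expectations of all log-parameters."""
    for name in ("alpha_c_tilde", "beta_c_tilde", "alpha_d_tilde", "beta_d_tilde"):
        if not getattr(state, name) > 0:
            raise ValueError(f"{name} must be positive")
    if not (state.n_tilde > 0).all() or any((e <= 0).any() for e in state.eta_tilde):
        raise ValueError("Dirichlet posterior counts must be positive")
    eln_pi = digamma(state.n_tilde) - digamma(state.n_tilde.sum())
    eln_trans = [
        digamma(eta) - digamma(eta.sum(axis=1, keepdims=True))
        for eta in state.eta_tilde
    ]
    ac, bc = state.alpha_c_tilde, state.beta_c_tilde
    ad, bd = state.alpha_d_tilde, state.beta_d_tilde
    nonedge = float(digamma(bd) - digamma(ad + bd) - digamma(bc) + digamma(ac + bc))
    edge = float(digamma(ac) - digamma(bc) - digamma(ad) + digamma(bd))
    return Expectations(eln_pi, eln_trans, nonedge, edge)


def update_root(state: VariationalState, exps: Expectations) -> np.ndarray:
    """Root update: ``Q_ik`` proportional to ``exp{E[ln pi_k] +
    sum_t sum_m Q^(t)_im E[ln P^(t)_km]}``, rows normalized in log space."""
    L = np.tile(exps.eln_pi, (state.n_vertices, 1))
    for Qt, elnP in zip(state.Q_t, exps.eln_trans):
        L += Qt @ elnP.T
    return _row_normalize_log(L)


def _instant_logits(
    Q: np.ndarray,
    Qt: np.ndarray,
    Am: np.ndarray,
    M: np.ndarray,
    eln_trans_t: np.ndarray,
    nonedge: float,
    edge: float,
) -> np.ndarray:
    # pair coupling restricted to observed pairs: M is the observed-pair
    # indicator with zero diagonal, Am = A * M.
    return (edge * Am - nonedge * M) @ Qt + Q @ eln_trans_t


def update_instant(
    state: VariationalState, exps: Expectations, net: MultiNetwork, t: int
) -> np.ndarray:
    """Instantaneous update for network ``t`` (synchronous, from the
    pre-update ``Q^(t)``): edges attract vertices into shared modules with
    strength ``exps.edge``, observed non-edges repel with ``exps.nonedge``,
    and the root prior enters through the transition expectations."""
    M = net.pair_mask(t)
    Am = net.adjacency[t] * M
    L = _instant_logits(
        state.Q, state.Q_t[t], Am, M, exps.eln_trans[t], exps.nonedge, exps.edge
    )
    return _row_normalize_log(L)


def update_dirichlet_root(state: VariationalState, hyper: Hyperparameters) -> np.ndarray:
    """``n_tilde_k = sum_i Q_ik + n0_k``."""
    return state.Q.sum(axis=0) + hyper.n0


def update_transition_hyper(
    state: VariationalState, hyper: Hyperparameters, t: int
) -> np.ndarray:
    """``eta_tilde^(t) = Q' Q^(t) + eta0`` (expected co-assignment counts)."""
    return state.Q.T @ state.Q_t[t] + hyper.eta0


def _edge_hyper_sums(
    Q_t: list[np.ndarray], Ams: list[np.ndarray], Ms: list[np.ndarray]
) -> tuple[float, float, float, float]:
    """(expected within-pairs that are edges W, expected within-pairs S,
    observed edge count E, observed pair count Np), summed over networks."""
    W = S = E = Np = 0.0
    for Qt, Am, M in zip(Q_t, Ams, Ms):
        W += 0.5 * float(np.sum((Am @ Qt) * Qt))
        S += 0.5 * float(np.sum((M @ Qt) * Qt))
        E += 0.5 * float(Am.sum())
        Np += 0.5 * float(M.sum())
    return W, S, E, Np


def update_edge_hyper(
    state: VariationalState, net: MultiNetwork, hyper: Hyperparameters
) -> tuple[float, float, float, float]:
    """Beta posterior updates over the edge probabilities.

    The increments are expected pair counts: within-module edges for
    ``alpha_c``, within-module non-edges for ``beta_c``, between-module
    edges for ``alpha_d`` and between-module non-edges for ``beta_d``.
    Restricted to observed pairs, the four increments sum to the number of
    observed unordered pairs across networks.
    """
    Ms = [net.pair_mask(t) for t in range(net.n_networks)]
    Ams = [A * M for A, M in zip(net.adjacency, Ms)]
    W, S, E, Np = _edge_hyper_sums(state.Q_t, Ams, Ms)
    return (
        W + hyper.alpha_c0,
        (S - W) + hyper.beta_c0,
        (E - W) + hyper.alpha_d0,
        (Np - E) - (S - W) + hyper.beta_d0,
    )


def free_energy(
    state: VariationalState,
    net: MultiNetwork,
    hyper: Hyperparameters,
    single: bool = False,
) -> float:
    """Variational free energy (negative ELBO) at a consistent state.

    Valid when the posterior hyperparameters reflect the current ``Q``
    matrices (i.e. evaluated after a full iteration): the assignment
    entropies plus log-ratios of posterior to prior Beta/Dirichlet
    normalizers.  ``0 ln 0 := 0``.  With ``single=True`` the transition
    terms are dropped and the one tied assignment matrix is counted once
    (the single-network model has a single latent partition).
    """
    entropy = float(sum(xlogy(Qt, Qt).sum() for Qt in state.Q_t))
    if not single:
        entropy += float(xlogy(state.Q, state.Q).sum())
    eta_term = 0.0
    if not single:
        for eta in state.eta_tilde:
            for k in range(hyper.K):
                eta_term += _ln_beta_vec(eta[k]) - _ln_beta_vec(hyper.eta0[k])
    beta_dir_term = (
        _ln_beta2(state.alpha_c_tilde, state.beta_c_tilde)
        - _ln_beta2(hyper.alpha_c0, hyper.beta_c0)
        + _ln_beta2(state.alpha_d_tilde, state.beta_d_tilde)
        - _ln_beta2(hyper.alpha_d0, hyper.beta_d0)
        + _ln_beta_vec(state.n_tilde)
        - _ln_beta_vec(hyper.n0)
    )
    return entropy - eta_term - beta_dir_term


def _check_finite(name: str, it: int, *arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise FloatingPointError(
                f"non-finite values produced by step '{name}' at iteration {it}"
            )


def refine(
    net: MultiNetwork,
    hyper: Hyperparameters,
    opts: FitOptions,
    state: VariationalState,
    tie_single: bool = False,
) -> VariationalState:
    """Coordinate ascent from a given state until convergence.

    With ``tie_single=True`` (requires T=1) the root and instantaneous
    assignments are structurally tied (``Q == Q^(1)``), the transition
    machinery drops out, and the loop is exactly the single-network SBM's
    variational algorithm.
    """
    if tie_single and net.n_networks != 1:
        raise ValueError("tie_single requires exactly one network")
    T = net.n_networks
    Ms = [net.pair_mask(t) for t in range(T)]
    Ams = [A * M for A, M in zip(net.adjacency, Ms)]
    prev_F = None
    trace: list[float] = []
    for it in range(opts.max_iter):
        exps = compute_expectations(state)
        # assignment stage: iterate the Q / Q^(t) fixed point under the
        # current parameter posteriors before touching them again.  The
        # synchronous map can oscillate (the non-edge repulsion acts on all
        # vertices at once), so the step is damped adaptively: start with
        # full steps and halve the mixing weight whenever the residual
        # stops contracting.  Damping does not move the fixed points.
        lam = 1.0
        prev_delta = np.inf
        for _ in range(opts.inner_max_iter):
            delta = 0.0
            if tie_single:
                # one tied assignment: pair coupling plus the root prior
                L = (exps.edge * Ams[0] - exps.nonedge * Ms[0]) @ state.Q_t[0]
                L += exps.eln_pi[None, :]
                Qt = (1.0 - lam) * state.Q_t[0] + lam * _row_normalize_log(L)
                _check_finite("instant", it, Qt)
                delta = float(np.abs(Qt - state.Q_t[0]).max())
                state.Q_t[0] = Qt
                state.Q = Qt
            else:
                Q = (1.0 - lam) * state.Q + lam * update_root(state, exps)
                _check_finite("root", it, Q)
                delta = float(np.abs(Q - state.Q).max())
                state.Q = Q
                new_Qt = []
                for t in range(T):
                    L = _instant_logits(
                        state.Q, state.Q_t[t], Ams[t], Ms[t],
                        exps.eln_trans[t], exps.nonedge, exps.edge,
                    )
                    new_Qt.append(
                        (1.0 - lam) * state.Q_t[t] + lam * _row_normalize_log(L)
                    )
                _check_finite("instant", it, *new_Qt)
                delta = max(
                    delta,
                    max(float(np.abs(a - b).max())
                        for a, b in zip(new_Qt, state.Q_t)),
                )
                state.Q_t = new_Qt
            if delta < opts.inner_tol:
                break
            if delta > 0.95 * prev_delta:
                lam = max(0.5 * lam, 0.05)
            prev_delta = delta
        state.n_tilde = update_dirichlet_root(state, hyper)
        if not tie_single:
            state.eta_tilde = [
                update_transition_hyper(state, hyper, t) for t in range(T)
            ]
        W, S, E, Np = _edge_hyper_sums(state.Q_t, Ams, Ms)
        state.alpha_c_tilde = W + hyper.alpha_c0
        state.beta_c_tilde = (S - W) + hyper.beta_c0
        state.alpha_d_tilde = (E - W) + hyper.alpha_d0
        state.beta_d_tilde = (Np - E) - (S - W) + hyper.beta_d0
        _check_finite(
            "hyper", it,
            state.n_tilde,
            [state.alpha_c_tilde, state.beta_c_tilde,
             state.alpha_d_tilde, state.beta_d_tilde],
        )
        F = free_energy(state, net, hyper, single=tie_single)
        _check_finite("free_energy", it, [F])
        trace.append(F)
        if prev_F is not None and abs(F - prev_F) <= opts.rel_tol * abs(prev_F):
            break
        prev_F = F
    state.free_energy_trace = trace if opts.record_trace else trace[-1:]
    return state


def fit(
    net: MultiNetwork,
    hyper: Hyperparameters,
    opts: FitOptions | None = None,
    tie_single: bool = False,
) -> VariationalState:
    """Run the variational algorithm from ``n_restarts`` random
    initializations and return the state with the lowest final free energy."""
    opts = opts or FitOptions()
    restart_seeds = substream(opts.seed, "restart-seeds").integers(
        2**31, size=opts.n_restarts
    )
    best: VariationalState | None = None
    for r in range(opts.n_restarts):
        state = init_state(net, hyper, seed=int(restart_seeds[r]))
        if tie_single:
            state.Q = state.Q_t[0].copy()
        state = refine(net, hyper, opts, state, tie_single=tie_single)
        if best is None or state.free_energy < best.free_energy:
            best = state
    assert best is not None
    return best


def exact_log_evidence(net: MultiNetwork, hyper: Hyperparameters) -> float:
    """Log marginal likelihood by exhaustive enumeration (tiny instances).

    Sums, over every configuration of the root and all instantaneous
    assignments, the closed-form marginal of the generative model with
    ``theta``, ``pi`` and every ``P^(t)`` integrated out analytically
    through Beta/Dirichlet normalizer ratios.  Used as an independent bound
    oracle for the free energy: ``F >= -exact_log_evidence``.
    """
    if net.observed_mask is not None:
        raise ValueError("exact enumeration supports fully observed networks only")
    N, T, K = net.n_vertices, net.n_networks, hyper.K
    n_config = K ** (N * (T + 1))
    if n_config > 1_000_000:
        raise ValueError(
            f"instance too large for enumeration: K^(N(T+1)) = {n_config} > 1e6"
        )
    iu, ju = np.triu_indices(N, k=1)
    tri = [A[iu, ju].astype(int) for A in net.adjacency]
    ln_b_n0 = _ln_beta_vec(hyper.n0)
    ln_b_eta0 = [_ln_beta_vec(hyper.eta0[k]) for k in range(K)]
    ln_b_c0 = _ln_beta2(hyper.alpha_c0, hyper.beta_c0)
    ln_b_d0 = _ln_beta2(hyper.alpha_d0, hyper.beta_d0)
    terms = []
    for cfg in itertools.product(range(K), repeat=N * (T + 1)):
        z = np.array(cfg[:N])
        lp = _ln_beta_vec(hyper.n0 + np.bincount(z, minlength=K)) - ln_b_n0
        Cp = Cm = Dp = Dm = 0
        for t in range(T):
            zt = np.array(cfg[N * (t + 1): N * (t + 2)])
            same = zt[iu] == zt[ju]
            a = tri[t]
            Cp += int(a[same].sum())
            Cm += int((1 - a[same]).sum())
            Dp += int(a[~same].sum())
            Dm += int((1 - a[~same]).sum())
            counts = np.zeros((K, K))
            np.add.at(counts, (z, zt), 1)
            for k in range(K):
                lp += _ln_beta_vec(hyper.eta0[k] + counts[k]) - ln_b_eta0[k]
        lp += _ln_beta2(hyper.alpha_c0 + Cp, hyper.beta_c0 + Cm) - ln_b_c0
        lp += _ln_beta2(hyper.alpha_d0 + Dp, hyper.beta_d0 + Dm) - ln_b_d0
        terms.append(lp)
    return float(logsumexp(terms))


def select_K(
    net: MultiNetwork,
    K_candidates: list[int],
    opts: FitOptions | None = None,
    hyper_factory=None,
    return_details: bool = False,
):
    """Pick the number of modules by minimal converged free energy.

    The free energy approximates the negative log evidence, so the candidate
    with the lowest best-restart value is the Bayesian choice of ``K``.
    """
    if not K_candidates:
        raise ValueError("K_candidates must be non-empty")
    opts = opts or FitOptions()
    hyper_factory = hyper_factory or Hyperparameters.default
    scores: dict[int, float] = {}
    for K in K_candidates:
        state = fit(net, hyper_factory(K), opts)
        scores[K] = state.free_energy
    best_K = min(scores, key=lambda k: (scores[k], k))
    return (best_K, scores) if return_details else best_K
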