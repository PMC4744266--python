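"""Variational updates against scalar-loop oracles, free-energy properties,
exact-enumeration bounds, and module recovery."""

import itertools

import numpy as np
import pytest
from scipy.special import digamma, gammaln, logsumexp

from multisbm import (
    FitOptions,
    Hyperparameters,
    MultiNetwork,
    Partition,
    compute_expectations,
    exact_log_evidence,
    fit,
    free_energy,
    hard_assignments,
    init_state,
    nmi,
    refine,
    select_K,
    update_dirichlet_root,
    update_edge_hyper,
    update_instant,
    update_root,
    update_transition_hyper,
)
from multisbm._rng import substream
from multisbm.fixtures import two_clique_network

from conftest import assert_monotone_trace, random_multinetwork

OPTS_SMALL = FitOptions(max_iter=200, n_restarts=4, seed=0)


def make_state(N=6, K=3, T=2, seed=5):
    net = random_multinetwork(N, T, seed)
    hyper = Hyperparameters.default(K)
    state = init_state(net, hyper, seed=seed)
    return net, hyper, state


def perturb_posteriors(state, seed=0):
    """Move posterior hyperparameters off the prior to de-trivialize tests."""
    rng = substream(seed, "perturb")
    state.n_tilde = state.n_tilde + rng.random(state.K) * 3
    state.eta_tilde = [e + rng.random(e.shape) * 2 for e in state.eta_tilde]
    state.alpha_c_tilde += rng.random() * 5
    state.beta_c_tilde += rng.random() * 5
    state.alpha_d_tilde += rng.random() * 5
    state.beta_d_tilde += rng.random() * 5
    return state


class TestInit:
    def test_rows_sum_to_one_and_posteriors_equal_priors(self):
        net, hyper, state = make_state()
        assert np.allclose(state.Q.sum(1), 1.0, atol=1e-12)
        for Qt in state.Q_t:
            assert np.allclose(Qt.sum(1), 1.0, atol=1e-12)
        assert np.array_equal(state.n_tilde, hyper.n0)
        assert state.alpha_c_tilde == hyper.alpha_c0
        assert state.beta_d_tilde == hyper.beta_d0
        for eta in state.eta_tilde:
            assert np.array_equal(eta, hyper.eta0)

    def test_same_seed_identical(self):
        net, hyper, _ = make_state()
        a = init_state(net, hyper, seed=3)
        b = init_state(net, hyper, seed=3)
        assert np.array_equal(a.Q, b.Q)
        assert all(np.array_equal(x, y) for x, y in zip(a.Q_t, b.Q_t))

    def test_k_above_n_warns(self):
        net = random_multinetwork(3, 1, 0)
        with pytest.warns(UserWarning, match="exceeds"):
            init_state(net, Hyperparameters.default(5), seed=0)


class TestExpectations:
    def test_digamma_identity_for_uniform_dirichlet(self):
        _, _, state = make_state(K=2)
        state.n_tilde = np.array([1.0, 1.0])
        exps = compute_expectations(state)
        # psi(1) - psi(2) = -1
        assert exps.eln_pi[0] == pytest.approx(-1.0, abs=1e-12)

    def test_symmetric_beta_posteriors_give_zero(self):
        _, _, state = make_state()
        for name in ("alpha_c_tilde", "beta_c_tilde", "alpha_d_tilde", "beta_d_tilde"):
            setattr(state, name, 2.5)
        exps = compute_expectations(state)
        assert exps.nonedge == pytest.approx(0.0, abs=1e-12)
        assert exps.edge == pytest.approx(0.0, abs=1e-12)

    def test_dirichlet_log_expectation_matches_sampling(self):
        _, _, state = make_state(K=3)
        state.n_tilde = np.array([2.0, 3.0, 4.0])
        exps = compute_expectations(state)
        rng = substream(0, "mc-dirichlet")
        draws = np.log(rng.dirichlet(state.n_tilde, size=200_000))
        mc = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(mc - exps.eln_pi) < 3 * se)

    def test_nonpositive_posterior_rejected(self):
        _, _, state = make_state()
        state.alpha_c_tilde = 0.0
        with pytest.raises(ValueError):
            compute_expectations(state)


class TestUpdateOracles:
    """Every vectorized update equals an independently coded scalar loop."""

    def test_root_update_matches_loop(self):
        net, hyper, state = make_state()
        state = perturb_posteriors(state)
        exps = compute_expectations(state)
        Q = update_root(state, exps)
        N, K, T = state.n_vertices, state.K, state.n_networks
        for i in range(N):
            logits = np.zeros(K)
            for k in range(K):
                logits[k] = exps.eln_pi[k]
                for t in range(T):
                    for m in range(K):
                        logits[k] += state.Q_t[t][i, m] * exps.eln_trans[t][k, m]
            row = np.exp(logits - logits.max())
            row /= row.sum()
            assert np.allclose(Q[i], row, atol=1e-12)

    def test_instant_update_matches_loop(self):
        net, hyper, state = make_state()
        state = perturb_posteriors(state)
        exps = compute_expectations(state)
        t = 1
        Qt_new = update_instant(state, exps, net, t)
        N, K = state.n_vertices, state.K
        A = net.adjacency[t]
        for i in range(N):
            logits = np.zeros(K)
            for k in range(K):
                for j in range(N):
                    if j == i:
                        continue
                    logits[k] += (
                        exps.edge * A[i, j] - exps.nonedge
                    ) * state.Q_t[t][j, k]
                for s in range(K):
                    logits[k] += state.Q[i, s] * exps.eln_trans[t][s, k]
            row = np.exp(logits - logits.max())
            row /= row.sum()
            assert np.allclose(Qt_new[i], row, atol=1e-12)

    def test_instant_update_uninformative_theta_pushes_root_prior(self):
        net, hyper, state = make_state()
        exps = compute_expectations(state)
        exps.nonedge = 0.0
        exps.edge = 0.0
        Qt = update_instant(state, exps, net, 0)
        expected_logits = state.Q @ exps.eln_trans[0]
        L = expected_logits - expected_logits.max(axis=1, keepdims=True)
        expected = np.exp(L) / np.exp(L).sum(axis=1, keepdims=True)
        assert np.allclose(Qt, expected, atol=1e-12)

    def test_dirichlet_root_update(self):
        net, hyper, state = make_state()
        n = update_dirichlet_root(state, hyper)
        assert np.allclose(n, state.Q.sum(0) + hyper.n0, atol=1e-12)
        assert n.sum() == pytest.approx(state.n_vertices + hyper.n0.sum())

    def test_transition_hyper_one_hot(self):
        net, hyper, state = make_state(N=6, K=2, T=1)
        labels = np.array([0, 0, 1, 1, 1, 0])
        one_hot = np.eye(2)[labels]
        state.Q = one_hot.copy()
        state.Q_t = [one_hot.copy()]
        eta = update_transition_hyper(state, hyper, 0)
        added = eta - hyper.eta0
        assert added[0, 0] == pytest.approx(3)
        assert added[1, 1] == pytest.approx(3)
        assert added[0, 1] == added[1, 0] == 0
        assert added.sum() == pytest.approx(6)  # mass conservation = N

    def test_edge_hyper_two_triangles(self):
        """Two disjoint K_3 components with matching one-hot assignments:
        6 within-edges, 0 within-non-edges, 0 between-edges, 9 between
        non-edges."""
        net, truth = two_clique_network(clique_size=3, T=1)
        hyper = Hyperparameters.default(2)
        state = init_state(net, hyper, seed=0)
        one_hot = np.eye(2)[truth.labels]
        state.Q = one_hot.copy()
        state.Q_t = [one_hot.copy()]
        ac, bc, ad, bd = update_edge_hyper(state, net, hyper)
        assert ac - hyper.alpha_c0 == pytest.approx(6)
        assert bc - hyper.beta_c0 == pytest.approx(0)
        assert ad - hyper.alpha_d0 == pytest.approx(0)
        assert bd - hyper.beta_d0 == pytest.approx(9)

    def test_edge_hyper_uniform_q_gives_half_edges(self):
        net, hyper, state = make_state(N=8, K=2, T=1)
        state.Q_t = [np.full((8, 2), 0.5)]
        ac, *_ = update_edge_hyper(state, net, hyper)
        n_edges = net.adjacency[0].sum() / 2
        assert ac - hyper.alpha_c0 == pytest.approx(n_edges / 2)

    def test_pair_count_conservation(self):
        net, hyper, state = make_state(N=7, K=3, T=2)
        ac, bc, ad, bd = update_edge_hyper(state, net, hyper)
        increments = (
            (ac - hyper.alpha_c0) + (bc - hyper.beta_c0)
            + (ad - hyper.alpha_d0) + (bd - hyper.beta_d0)
        )
        assert increments == pytest.approx(2 * 7 * 6 / 2, rel=1e-12)


def free_energy_oracle(state, net, hyper):
    """Term-by-term scalar reimplementation of the free energy."""

    def lnB(v):
        return sum(gammaln(x) for x in v) - gammaln(sum(v))

    total = 0.0
    for Qt in state.Q_t:
        for row in Qt:
            for q in row:
                if q > 0:
                    total += q * np.log(q)
    for row in state.Q:
        for q in row:
            if q > 0:
                total += q * np.log(q)
    for eta in state.eta_tilde:
        for k in range(hyper.K):
            total -= lnB(eta[k]) - lnB(hyper.eta0[k])
    total -= lnB([state.alpha_c_tilde, state.beta_c_tilde]) - lnB(
        [hyper.alpha_c0, hyper.beta_c0]
    )
    total -= lnB([state.alpha_d_tilde, state.beta_d_tilde]) - lnB(
        [hyper.alpha_d0, hyper.beta_d0]
    )
    total -= lnB(state.n_tilde) - lnB(hyper.n0)
    return total


class TestFreeEnergy:
    def test_matches_term_by_term_oracle(self):
        net, hyper, state = make_state()
        state = perturb_posteriors(state)
        assert free_energy(state, net, hyper) == pytest.approx(
            free_energy_oracle(state, net, hyper), rel=1e-12
        )

    def test_monotone_on_seeded_runs(self, two_cliques):
        net, _ = two_cliques
        state = fit(net, Hyperparameters.default(2), OPTS_SMALL)
        assert_monotone_trace(state.free_energy_trace)

    def test_monotone_on_planted_multinetwork(self):
        from multisbm import SynthSpec, generate_experiment_two

        net, _ = generate_experiment_two(
            SynthSpec(N=40, K=2, theta_c=0.5, theta_d=0.1, seed=2), T=3
        )
        state = fit(net, Hyperparameters.default(2),
                    FitOptions(n_restarts=3, seed=1))
        assert_monotone_trace(state.free_energy_trace)


class TestExactEvidence:
    def test_single_vertex_k1_is_certain(self):
        A = np.zeros((1, 1))
        net = MultiNetwork([A], ["a"])
        assert exact_log_evidence(net, Hyperparameters.default(1)) == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("edge", [0, 1])
    def test_two_vertices_beta_bernoulli_closed_form(self, edge):
        A = np.array([[0.0, edge], [edge, 0.0]])
        net = MultiNetwork([A], ["a", "b"])
        hyper = Hyperparameters.default(1)

        def lnB(a, b):
            return gammaln(a) + gammaln(b) - gammaln(a + b)

        expected = lnB(hyper.alpha_c0 + edge, hyper.beta_c0 + 1 - edge) - lnB(
            hyper.alpha_c0, hyper.beta_c0
        )
        assert exact_log_evidence(net, hyper) == pytest.approx(expected, rel=1e-12)

    def test_matches_monte_carlo_prior_sampling(self):
        """Evidence by enumeration agrees with E_prior[p(A | parameters)]."""
        net = random_multinetwork(N=4, T=2, seed=17)
        hyper = Hyperparameters.default(2)
        exact = exact_log_evidence(net, hyper)

        K, N, T = 2, 4, 2
        configs = np.array(list(itertools.product(range(K), repeat=N)))
        iu, ju = np.triu_indices(N, k=1)
        same = configs[:, iu] == configs[:, ju]  # (16, 6)
        tri = [A[iu, ju] for A in net.adjacency]
        # transition counts for every (z, zt) pair: (16, 16, K, K)
        trans_counts = np.zeros((16, 16, K, K))
        for a, z in enumerate(configs):
            for b, zt in enumerate(configs):
                np.add.at(trans_counts[a, b], (z, zt), 1)

        rng = substream(1, "mc-evidence")
        M = 4000
        samples = np.empty(M)
        for m in range(M):
            theta_c = rng.beta(hyper.alpha_c0, hyper.beta_c0)
            theta_d = rng.beta(hyper.alpha_d0, hyper.beta_d0)
            pi = rng.dirichlet(hyper.n0)
            lp_z = np.log(pi)[configs].sum(axis=1)  # (16,)
            total_per_z = lp_z.copy()
            for t in range(T):
                P = np.vstack([rng.dirichlet(hyper.eta0[k]) for k in range(K)])
                p_pair = np.where(same, theta_c, theta_d)
                lp_at = np.where(tri[t] > 0, np.log(p_pair), np.log(1 - p_pair)).sum(
                    axis=1
                )  # (16,) per zt
                lp_trans = (trans_counts * np.log(P)).sum(axis=(2, 3))  # (16,16)
                total_per_z += logsumexp(lp_at[None, :] + lp_trans, axis=1)
            samples[m] = logsumexp(total_per_z)
        w = np.exp(samples)
        mc = w.mean()
        se = w.std(ddof=1) / np.sqrt(M)
        assert abs(np.exp(exact) - mc) < 3 * se

    def test_refuses_large_instances(self):
        net = random_multinetwork(N=10, T=2, seed=0)
        with pytest.raises(ValueError, match="too large"):
            exact_log_evidence(net, Hyperparameters.default(4))


class TestFit:
    def test_free_energy_bounds_negative_log_evidence(self):
        """F >= -ln p(A | K) on enumerable instances."""
        for seed in (3, 17):
            net = random_multinetwork(N=4, T=2, seed=seed)
            hyper = Hyperparameters.default(2)
            state = fit(net, hyper, FitOptions(n_restarts=5, seed=1))
            bound = -exact_log_evidence(net, hyper)
            assert state.free_energy >= bound - 1e-9

    def test_two_cliques_recovered(self, two_cliques):
        net, truth = two_cliques
        state = fit(net, Hyperparameters.default(2), OPTS_SMALL)
        assert nmi(truth, hard_assignments(state, "root")) == pytest.approx(1.0)
        for t in range(2):
            assert nmi(truth, hard_assignments(state, t)) == pytest.approx(1.0)

    def test_row_stochastic_and_posterior_dominance_after_fit(self, two_cliques):
        net, _ = two_cliques
        hyper = Hyperparameters.default(2)
        state = fit(net, hyper, OPTS_SMALL)
        state.validate(hyper)

    def test_same_seed_identical_output(self, two_cliques):
        net, _ = two_cliques
        a = fit(net, Hyperparameters.default(2), OPTS_SMALL)
        b = fit(net, Hyperparameters.default(2), OPTS_SMALL)
        assert np.array_equal(a.Q, b.Q)
        assert a.free_energy_trace == b.free_energy_trace

    def test_label_permutation_equivariance(self, two_cliques):
        net, _ = two_cliques
        hyper = Hyperparameters.default(2)
        opts = FitOptions(max_iter=60, n_restarts=1, seed=0)
        perm = np.array([1, 0])
        s1 = init_state(net, hyper, seed=4)
        s2 = init_state(net, hyper, seed=4)
        s2.Q = s2.Q[:, perm]
        s2.Q_t = [Qt[:, perm] for Qt in s2.Q_t]
        r1 = refine(net, hyper, opts, s1)
        r2 = refine(net, hyper, opts, s2)
        assert r1.free_energy == pytest.approx(r2.free_energy, rel=1e-8)
        assert np.allclose(r1.Q[:, perm], r2.Q, atol=1e-6)

    def test_parameter_recovery_on_clean_replicates(self):
        """Posterior means of theta_c/theta_d within 0.03 of the generating
        values on T=3 exact copies of a clean planted partition."""
        from multisbm import SynthSpec, generate_planted_partition

        spec = SynthSpec(N=256, K=4, theta_c=0.32, theta_d=0.06, seed=12)
        base, truth = generate_planted_partition(spec)
        A = base.adjacency[0]
        net = MultiNetwork([A.copy() for _ in range(3)], base.vertex_ids)
        state = fit(net, Hyperparameters.default(4),
                    FitOptions(n_restarts=3, seed=2))
        mean_c = state.alpha_c_tilde / (state.alpha_c_tilde + state.beta_c_tilde)
        mean_d = state.alpha_d_tilde / (state.alpha_d_tilde + state.beta_d_tilde)
        assert abs(mean_c - 0.32) < 0.03
        assert abs(mean_d - 0.06) < 0.03


class TestSelectK:
    def test_single_candidate_returned(self, two_cliques):
        net, _ = two_cliques
        assert select_K(net, [3], FitOptions(n_restarts=1, seed=0)) == 3

    def test_empty_candidates_rejected(self, two_cliques):
        net, _ = two_cliques
        with pytest.raises(ValueError):
            select_K(net, [])

    def test_planted_k_recovered(self):
        from multisbm import SynthSpec, generate_experiment_two

        net, _ = generate_experiment_two(SynthSpec.benchmark(seed=6), T=3)
        best = select_K(net, [2, 4, 8], FitOptions(n_restarts=2, seed=1))
        assert best == 4
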