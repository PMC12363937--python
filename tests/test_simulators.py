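import numpy as np
import pytest

from cipher.covariance import estimate_covariance
from cipher.data_io import delta_expression, filter_dataset, normalize_perturbation_labels
from cipher.forward import optimal_single_perturbation
from cipher.simulate import (
    HillNetworkParams,
    LinearNetworkParams,
    NotHurwitzError,
    TeamsNetworkParams,
    burst_model_moments,
    critical_coupling,
    hill_critical_interaction,
    hill_fixed_point,
    hill_force,
    hill_jacobian,
    hill_linear_response_error,
    make_perturbation_fixture,
    sample_interaction_matrix,
    simulate_linear_network,
    simulate_teams_network,
    soft_mode_covariance,
    solve_lyapunov,
    trajectory_covariance,
)

FAST_TEAMS = dict(total_time=2e4, record_every=10)


class TestInteractionMatrix:
    def test_zero_coupling_is_identity(self, rng):
        np.testing.assert_array_equal(sample_interaction_matrix(5, 0.0, rng),
                                      np.eye(5))

    def test_offdiagonal_statistics(self):
        eps = 0.07
        A = sample_interaction_matrix(500, eps, np.random.default_rng(0))
        off = A[~np.eye(500, dtype=bool)]
        se = eps / np.sqrt(off.size)
        assert abs(off.mean()) < 3 * se
        assert abs(off.std() - eps) < 3 * se

    def test_seed_determinism(self):
        a = sample_interaction_matrix(6, 0.2, np.random.default_rng(5))
        b = sample_interaction_matrix(6, 0.2, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestLinearNetwork:
    def test_decoupled_stationary_variance_matches_diffusion(self):
        # eps=0: J=-I so the stationary covariance is D * I
        p = LinearNetworkParams(n_genes=4, epsilon=0.0, total_time=2000.0, seed=0)
        traj = simulate_linear_network(p)
        var = traj.stationary_states().var(axis=0)
        np.testing.assert_allclose(var, p.diffusion, rtol=0.1)

    def test_supercritical_run_flagged_unstable(self):
        n = 50
        p = LinearNetworkParams(n_genes=n, epsilon=3.0 * critical_coupling(n),
                                total_time=300.0, seed=1)
        traj = simulate_linear_network(p)
        assert traj.unstable

    def test_forced_mean_shift_matches_fixed_point(self):
        # subcritical: stationary mean under constant forcing is A^-1 u
        n = 8
        eps = 0.3 * critical_coupling(n)
        A = sample_interaction_matrix(n, eps, np.random.default_rng(2))
        u = np.zeros(n)
        u[0] = 2.0
        shifts = [
            simulate_linear_network(
                LinearNetworkParams(n_genes=n, epsilon=eps, total_time=2000.0,
                                    seed=s), forcing=u, A=A).stationary_mean()
            for s in range(3)
        ]
        np.testing.assert_allclose(np.mean(shifts, axis=0)[0],
                                   np.linalg.solve(A, u)[0], rtol=0.1)

    def test_bit_reproducible(self):
        p = LinearNetworkParams(n_genes=3, epsilon=0.1, total_time=10.0, seed=9)
        a = simulate_linear_network(p)
        b = simulate_linear_network(p)
        np.testing.assert_array_equal(a.states, b.states)


class TestLyapunov:
    def test_identity_case(self):
        np.testing.assert_allclose(solve_lyapunov(-np.eye(3), np.eye(3)), np.eye(3))

    def test_scalar_closed_form(self):
        np.testing.assert_allclose(solve_lyapunov(np.array([[-4.0]]),
                                                  np.array([[2.0]])),
                                   [[0.5]])

    def test_matches_monte_carlo(self):
        A = sample_interaction_matrix(2, 0.2, np.random.default_rng(4))
        D = 0.5 * np.eye(2)
        oracle = solve_lyapunov(-A, D)
        traj = simulate_linear_network(
            LinearNetworkParams(n_genes=2, epsilon=0.2, total_time=5000.0, seed=4),
            A=A)
        emp = np.cov(traj.stationary_states().T)
        assert np.linalg.norm(emp - oracle) / np.linalg.norm(oracle) < 0.1

    def test_unstable_rejected(self):
        with pytest.raises(NotHurwitzError):
            solve_lyapunov(np.eye(2), np.eye(2))


class TestSoftMode:
    def test_strong_gap_rank_one(self):
        sm = soft_mode_covariance(np.diag([-0.01, -10.0]), np.eye(2))
        assert sm.correction_norm < 0.01
        assert not sm.no_spectral_gap
        assert sm.gap_ratio > 100

    def test_degenerate_spectrum_warns(self):
        sm = soft_mode_covariance(-np.eye(2), np.eye(2))
        assert sm.no_spectral_gap
        assert sm.correction_norm > 0.3

    def test_response_parallel_to_inverse_under_gap(self, rng):
        # strong gap: Sigma u and -J^-1 u within 5 degrees
        P = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        J = P @ np.diag([-0.01, -5.0, -8.0]) @ np.linalg.inv(P)
        sigma = solve_lyapunov(J, np.eye(3))
        u = rng.normal(size=3)
        a = sigma @ u
        b = -np.linalg.solve(J, u)
        cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 5.0


class TestHillNetwork:
    def test_zero_interactions_pure_decay(self):
        p = HillNetworkParams(n_genes=4, seed=0, max_iter=5000)
        x, ok = hill_fixed_point(p, G=np.zeros((4, 4)))
        assert ok
        np.testing.assert_allclose(x, 0.0, atol=1e-9)
        f = np.full(4, 2.0)
        x2, _ = hill_fixed_point(p, forcing=f, G=np.zeros((4, 4)))
        np.testing.assert_allclose(x2, 2.0, rtol=1e-8)

    def test_hill_zero_exponent_closed_form(self):
        # n=0: Hill term is 1/2, fixed point solves gamma x = G 1/2
        p = HillNetworkParams(n_genes=3, n=0.0, seed=1, max_iter=5000)
        G = p.interaction_matrix()
        x, _ = hill_fixed_point(p, G=G)
        np.testing.assert_allclose(x, G.sum(axis=1) / (2 * p.gamma), rtol=1e-8)

    def test_residual_small_at_fixed_point(self):
        p = HillNetworkParams(seed=3, max_iter=20000)
        G = p.interaction_matrix()
        x, ok = hill_fixed_point(p, G=G)
        assert ok
        assert np.abs(hill_force(x, G, p)).max() < 1e-9

    def test_jacobian_matches_finite_differences(self):
        p = HillNetworkParams(n_genes=3, seed=5)
        G = p.interaction_matrix()
        x = np.array([3.0, 8.0, 15.0])
        J = hill_jacobian(x, G, p)
        eps = 1e-6
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = eps
            fd = (hill_force(x + dx, G, p) - hill_force(x - dx, G, p)) / (2 * eps)
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-5, atol=1e-8)

    def test_linear_regime_error_negligible(self):
        p = HillNetworkParams(n=0.0, seed=1)
        u = np.zeros(10)
        u[0] = 0.5
        assert hill_linear_response_error(p, u) < 1e-6

    def test_null_perturbation_rejected(self):
        with pytest.raises(ValueError):
            hill_linear_response_error(HillNetworkParams(seed=0), np.zeros(10))


class TestHillCritical:
    def test_closed_form_n4(self):
        # x_min = K (n-1)^(1/n); hand-evaluated value for n=4, K=10, gamma=1, N=10
        p = HillNetworkParams(n_genes=10, n=4.0, K=10.0, gamma=1.0)
        assert hill_critical_interaction(p) == pytest.approx(1.7548, abs=5e-4)

    def test_n1_limit(self):
        p = HillNetworkParams(n_genes=10, n=1.0, K=10.0, gamma=1.0)
        assert hill_critical_interaction(p) == pytest.approx(1.0, rel=1e-4)

    def test_matches_bruteforce_grid(self):
        p = HillNetworkParams(n_genes=10, n=4.0, K=10.0, gamma=1.0)
        xs = np.linspace(1e-3, 200.0, 400001)
        grid = (p.gamma / p.n_genes) * np.min((p.K**p.n + xs**p.n) / xs**(p.n - 1))
        assert hill_critical_interaction(p) == pytest.approx(grid, rel=1e-3)

    def test_no_threshold_without_cooperativity(self):
        with pytest.raises(ValueError):
            hill_critical_interaction(HillNetworkParams(n=0.0))

    def test_simulation_brackets_transition(self):
        # homogeneous network leaves zero state just above G*, stays below it
        p = HillNetworkParams(n_genes=10, n=4.0, K=10.0, gamma=1.0,
                              max_iter=20000)
        g_star = hill_critical_interaction(p)
        # for n>1 the zero state is locally stable; the transition at G* is a
        # saddle-node, so the kick must exceed the unstable branch (~K(n-1)^(1/n))
        x0 = np.full(10, 20.0)
        for factor, escapes in ((1.1, True), (0.9, False)):
            G = np.full((10, 10), factor * g_star)
            x, _ = hill_fixed_point(p, G=G, x0=x0)
            assert (x.max() > 1.0) == escapes


@pytest.fixture(scope="module")
def short_run():
    return simulate_teams_network(TeamsNetworkParams(seed=5, **FAST_TEAMS))


class TestTeamsNetwork:
    def test_isolated_on_gene_equilibrates_to_beta_over_gamma(self):
        # beta=50, gamma=4, promoter pinned on: x -> 12.5
        p = TeamsNetworkParams(seed=0)
        x = 0.0
        for _ in range(2000):
            x += (p.beta * 1 - p.gamma * x) * p.dt
        assert x == pytest.approx(p.beta / p.gamma, rel=1e-6)

    def test_bimodal_team_averages(self, short_run):
        states = short_run.stationary_states()
        diff = states[:, :10].mean(axis=1) - states[:, 10:].mean(axis=1)
        committed = np.abs(diff) > 3.0
        assert committed.mean() > 0.5            # mostly in a committed state
        signs = np.sign(diff[committed])
        assert (signs > 0).any() and (signs < 0).any()   # both modes visited
        assert np.sum(signs[1:] != signs[:-1]) >= 2       # collective toggles

    def test_knockout_gene_stays_silent(self):
        traj = simulate_teams_network(
            TeamsNetworkParams(seed=5, **FAST_TEAMS), knockout=0)
        p = TeamsNetworkParams()
        assert traj.stationary_mean()[0] < 0.01 * p.beta / p.gamma

    def test_covariance_block_sign_structure(self, short_run):
        sigma = trajectory_covariance(short_run).sigma
        within = np.concatenate([sigma[:10, :10][np.triu_indices(10, 1)],
                                 sigma[10:, 10:][np.triu_indices(10, 1)]])
        cross = sigma[:10, 10:].ravel()
        assert (within > 0).mean() > 0.9
        assert (cross < 0).mean() > 0.9

    def test_bit_reproducible(self):
        p = TeamsNetworkParams(seed=8, total_time=2000.0, record_every=10)
        a = simulate_teams_network(p)
        b = simulate_teams_network(p)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.promoter_states, b.promoter_states)

    def test_trajectory_covariance_matches_estimator(self, short_run):
        direct = trajectory_covariance(short_run).sigma
        manual = estimate_covariance(short_run.stationary_states()).sigma
        np.testing.assert_array_equal(direct, manual)

    def test_knockout_response_is_low_dimensional(self, short_run):
        # the collective team mode carries the knockout response: PR ~ 1-2,
        # versus a dense random response on an isotropic covariance
        from cipher.covariance import CovarianceModel
        from cipher.modes import eigendecompose, project_response

        ko = simulate_teams_network(TeamsNetworkParams(seed=5, **FAST_TEAMS),
                                    knockout=0)
        sigma = trajectory_covariance(short_run)
        proj = project_response(eigendecompose(sigma),
                                ko.stationary_mean() - short_run.stationary_mean(),
                                K=20)
        assert proj.participation_ratio < 3.0
        iso = eigendecompose(CovarianceModel(np.eye(30),
                                             [f"g{i:02d}" for i in range(30)]))
        dense = project_response(iso, np.random.default_rng(0).normal(size=30),
                                 K=30)
        assert dense.participation_ratio > 5.0  # E[PR] ~ K/3 for Gaussian loads

    def test_joint_double_knockout_fit_beats_baseline(self):
        # joint two-gene forcing vs the average-of-singles null on double KOs
        from cipher.forward import (baseline_mean_response, compute_r2,
                                    optimal_subset_perturbation)

        p = TeamsNetworkParams(seed=9, **FAST_TEAMS)
        ctrl = simulate_teams_network(p)
        sigma = trajectory_covariance(ctrl)
        m0 = ctrl.stationary_mean()

        def dx_for(ko, seed_shift):
            params = TeamsNetworkParams(seed=9 + seed_shift, **FAST_TEAMS)
            traj = simulate_teams_network(params, knockout=ko)
            return delta_expression_like(traj.stationary_mean() - m0, sigma)

        def delta_expression_like(values, sig):
            from cipher.data_io import DeltaExpression
            return DeltaExpression(values, sig.gene_ids, "ko", 1, 1)

        wins = 0
        pairs = [(0, 10), (1, 11), (2, 3)]
        for n_pair, (i, j) in enumerate(pairs):
            dx_i = dx_for(i, 100 + n_pair)
            dx_j = dx_for(j, 200 + n_pair)
            dx_ij = dx_for([i, j], 300 + n_pair)
            joint = optimal_subset_perturbation(sigma, dx_ij, [i, j]).r2
            base = baseline_mean_response(dx_i, dx_j)
            wins += joint >= compute_r2(dx_ij, base.values)
        assert wins >= 2


class TestBurstMoments:
    def test_plug_in_values(self):
        m = burst_model_moments(kon=1.0, koff=1.0, beta=10.0, gamma=1.0)
        assert m.burst_size == 10.0
        assert m.r == 1.0
        assert m.p == pytest.approx(10.0 / 11.0)
        assert m.mean == 10.0

    def test_negative_binomial_identity(self, rng):
        for _ in range(20):
            kon, koff, beta, gamma = rng.uniform(0.1, 5.0, size=4)
            m = burst_model_moments(kon, koff, beta, gamma)
            assert m.mean == pytest.approx(m.r * m.p / (1 - m.p), rel=1e-9)

    def test_exponential_limit(self):
        # geometric regime (r = kon/gamma = 1) with large burst size: the NB
        # converges to an exponential of matching mean
        import scipy.stats

        b = 2000.0
        m = burst_model_moments(kon=1.0, koff=1.0, beta=b, gamma=1.0)
        assert m.r == 1.0
        rng = np.random.default_rng(0)
        nb = rng.negative_binomial(m.r, 1 - m.p, size=100_000)
        ks = scipy.stats.kstest(nb, scipy.stats.expon(scale=m.mean).cdf)
        assert ks.statistic < 0.02

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            burst_model_moments(0.0, 1.0, 1.0, 1.0)


class TestFixtureGenerator:
    def test_survives_standard_filter(self, planted_fixture):
        ds, _ = planted_fixture
        out = filter_dataset(ds)
        assert out.n_genes > 0 and len(out.perturbation_names()) == 3

    def test_labels_carry_guide_suffixes(self, planted_fixture):
        ds, truth = planted_fixture
        names = ds.perturbation_names()
        stripped = normalize_perturbation_labels(names)
        assert set(stripped) == set(truth["targets"])

    def test_planted_forcing_recovered_by_forward_fit(self, planted_fixture):
        ds, truth = planted_fixture
        sigma = estimate_covariance(ds.control_counts(), gene_ids=ds.gene_ids)
        r2s = []
        for gene, idx in truth["targets"].items():
            dx = delta_expression(ds, gene + "_g1")
            r2s.append(optimal_single_perturbation(sigma, dx, idx).r2)
        assert np.mean(r2s) > 0.8

    def test_reproducible(self):
        a, _ = make_perturbation_fixture(n_genes=20, n_control_cells=50,
                                         n_cells_per_perturbation=20,
                                         n_perturbations=2, seed=4)
        b, _ = make_perturbation_fixture(n_genes=20, n_control_cells=50,
                                         n_cells_per_perturbation=20,
                                         n_perturbations=2, seed=4)
        np.testing.assert_array_equal(a.dense_counts(), b.dense_counts())
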