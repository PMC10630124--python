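"""Oracle checks of the Gibbs kernels: each conditional is compared with the
closed-form conjugate posterior (or a brute-force density ratio) on toys
small enough to verify by hand."""

import numpy as np
import pytest
import scipy.stats

from gsfa._gibbs import (
    Hyperpriors,
    sample_effects,
    sample_loadings,
    slab_log_marginal,
    z_posterior_params,
)
from gsfa.model import GuidedSparseFactorModel, ModelConfig
from gsfa.simulate import SimConfig, simulate_normal


def make_model(Y, G, K, **kw):
    return GuidedSparseFactorModel(Y, G, n_factors=K, **kw)


# ---------------------------------------------------------------------------
# initialization


def test_init_svd_exact_rank(rng):
    K = 3
    Z0 = rng.standard_normal((12, K))
    W0 = rng.standard_normal((8, K))
    Y = Z0 @ W0.T  # exact rank K
    G = rng.integers(0, 2, size=(12, 2))
    st = make_model(Y, G, K).init_state()
    np.testing.assert_allclose(st.Z @ st.W.T, Y, atol=1e-8)


def test_init_deterministic_and_k1_power_iteration(rng):
    Y = rng.standard_normal((10, 6))
    G = rng.integers(0, 2, size=(10, 1))
    m = make_model(Y, G, 1)
    a, b = m.init_state(seed=3), m.init_state(seed=3)
    np.testing.assert_array_equal(a.Z, b.Z)
    np.testing.assert_array_equal(a.W, b.W)
    # power-iteration oracle for the leading right singular vector
    v = np.ones(6)
    for _ in range(500):
        v = Y.T @ (Y @ v)
        v /= np.linalg.norm(v)
    cos = abs(v @ a.W[:, 0]) / np.linalg.norm(a.W[:, 0])
    assert cos > 1 - 1e-8


def test_init_rejects_too_many_factors(rng):
    Y = rng.standard_normal((5, 4))
    with pytest.raises(ValueError):
        make_model(Y, np.zeros((5, 1), dtype=int), 4)


# ---------------------------------------------------------------------------
# loading updates (W, F)


def test_slab_log_marginal_is_bayesian_ridge():
    """The site posterior mean/variance equal the closed-form ridge solution."""
    rng = np.random.default_rng(0)
    z = rng.standard_normal(9)
    y = 0.8 * z + 0.1 * rng.standard_normal(9)
    psi, v = 0.7, 2.0
    s, b = z @ z / psi, z @ y / psi
    _, mu, var = slab_log_marginal(s, b, v)
    ridge_mean = np.linalg.solve(
        np.atleast_2d(z @ z / psi + 1 / v), np.atleast_1d(z @ y / psi)
    )
    assert mu == pytest.approx(ridge_mean[0], rel=1e-12)
    assert var == pytest.approx(1 / (z @ z / psi + 1 / v), rel=1e-12)


def test_loading_update_matches_ridge_in_dense_limit(rng):
    """pi -> 1, c -> 1: the mixture collapses and the W draw is a plain
    Bayesian ridge; the empirical draw mean matches the closed form."""
    N, P = 15, 3
    Z = rng.standard_normal((N, 1))
    W_true = np.array([[1.0], [-0.5], [0.2]])
    Y = Z @ W_true.T + 0.3 * rng.standard_normal((N, P))
    model = make_model(Y, np.zeros((N, 1), dtype=np.int8), 1, c=0.999999)
    st = model.init_state()
    st.pi[:] = 1 - 1e-12
    st.sigma2[:] = 1.0
    st.psi[:] = 0.09
    st.Z = Z
    draws = []
    for i in range(4000):
        s2 = st.copy()
        sample_loadings(np.random.default_rng(i), s2, Y, c=0.999999,
                        prior_type="normal_mixture")
        draws.append(s2.W[:, 0])
    emp = np.mean(draws, axis=0)
    closed = (Z[:, 0] @ Y / 0.09) / (Z[:, 0] @ Z[:, 0] / 0.09 + 1.0)
    post_sd = np.sqrt(1 / (Z[:, 0] @ Z[:, 0] / 0.09 + 1.0))
    np.testing.assert_allclose(emp, closed, atol=4 * post_sd / np.sqrt(4000))


def test_foreground_probability_matches_analytic_mixture_posterior(rng):
    """1-gene/1-factor: empirical P(F=1) equals the two-component posterior
    odds computed from exact multivariate-normal marginal likelihoods."""
    N = 7
    z = rng.standard_normal(N)
    y = 0.6 * z + rng.standard_normal(N) * 0.5
    psi, sigma2, c, pi = 0.25, 1.0, 0.3, 0.4
    # exact marginal likelihoods N(y; 0, v zz' + psi I)
    def ml(v):
        cov = v * np.outer(z, z) + psi * np.eye(N)
        return scipy.stats.multivariate_normal(np.zeros(N), cov).pdf(y)

    p_analytic = pi * ml(sigma2) / (pi * ml(sigma2) + (1 - pi) * ml(sigma2 * c * c))

    Y = np.column_stack([y, rng.standard_normal(N)])  # second gene: pure noise
    model = make_model(Y, np.zeros((N, 1), dtype=np.int8), 1, c=c)
    st = model.init_state()
    st.Z = z[:, None]
    st.pi[:] = pi
    st.sigma2[:] = sigma2
    st.psi[:] = psi
    hits = 0
    n_rep = 4000
    for i in range(n_rep):
        s2 = st.copy()
        sample_loadings(np.random.default_rng(i), s2, Y, c=c,
                        prior_type="normal_mixture")
        hits += int(s2.F[0, 0])
    se = np.sqrt(p_analytic * (1 - p_analytic) / n_rep)
    assert hits / n_rep == pytest.approx(p_analytic, abs=4 * se + 1e-3)


def test_no_signal_loadings_concentrate_near_zero(rng):
    N, P = 20, 4
    Y = np.zeros((N, P))
    Z = rng.standard_normal((N, 1))
    model = make_model(rng.standard_normal((N, P)), np.zeros((N, 1), dtype=np.int8), 1)
    st = model.init_state()
    st.Z = Z
    st.sigma2[:] = 1.0
    sample_loadings(np.random.default_rng(0), st, Y, c=0.25, prior_type="normal_mixture")
    assert np.abs(st.W).mean() < 1.0  # well below the prior slab sd


def test_spike_slab_zeroes_background_loadings(rng):
    Y, G, _ = simulate_normal(SimConfig(n_cells=60, n_genes=30, n_factors=3,
                                        n_perturbations=2,
                                        effect_matrix=np.zeros((2, 3)), seed=0))
    model = make_model(Y, G, 3, prior_type="spike_slab")
    res = model.fit(n_iter=50, n_use=20, seed=0)
    W, F = res.samples.W, res.samples.F
    assert np.all(W[F == 0] == 0)


# ---------------------------------------------------------------------------
# effect updates (beta, gamma)


def test_effect_update_matches_conjugate_regression(rng):
    """p_m -> 1 forces gamma = 1; the stationary mean of the single-site
    sweep is the closed-form Bayesian regression posterior mean."""
    N, M, K = 40, 2, 2
    G = (rng.random((N, M)) < 0.4).astype(np.int8)
    beta_true = np.array([[0.8, 0.0], [0.0, -0.6]])
    Z = G @ beta_true + rng.standard_normal((N, K))
    d2 = 0.5
    model = make_model(rng.standard_normal((N, 5)), G, K)
    st = model.init_state()
    st.Z = Z
    st.p[:] = 1 - 1e-12
    st.d2[:] = d2
    st.beta[:] = 0.0
    rng_chain = np.random.default_rng(0)
    rows = [np.arange(N)]
    draws = []
    for i in range(4000):
        sample_effects(rng_chain, st, G, rows)
        if i >= 100:
            draws.append(st.beta[0].copy())
    emp = np.mean(draws, axis=0)
    Gf = G.astype(float)
    closed = np.linalg.solve(Gf.T @ Gf + np.eye(M) / d2, Gf.T @ Z)
    np.testing.assert_allclose(emp, closed, atol=0.06)


def test_null_effects_inclusion_near_prior(rng):
    """Z independent of G: empirical P(gamma=1) stays near the prior p_m."""
    N, M, K = 300, 3, 4
    G = (rng.random((N, M)) < 0.1).astype(np.int8)
    Z = rng.standard_normal((N, K))
    model = make_model(rng.standard_normal((N, 6)), G, K)
    st = model.init_state()
    st.Z = Z
    st.p[:] = 0.3
    st.d2[:] = 0.1  # weakly informative slab: the null Bayes factor stays near 1
    st.beta[:] = 0.0
    rng_chain = np.random.default_rng(1)
    tot = 0.0
    n_rep = 400
    for _ in range(n_rep):
        sample_effects(rng_chain, st, G, [np.arange(N)])
        tot += st.gamma.mean()
    assert tot / n_rep == pytest.approx(0.3, abs=0.15)


# ---------------------------------------------------------------------------
# factor updates (Z)


def test_z_posterior_matches_hand_assembled_conditional(rng):
    N, P, K = 6, 5, 2
    W = rng.standard_normal((P, K))
    psi = rng.uniform(0.5, 2.0, P)
    Y = rng.standard_normal((N, P))
    prior_mean = rng.standard_normal((N, K))
    mean, prec = z_posterior_params(W, psi, Y, prior_mean)
    prec_oracle = W.T @ np.diag(1 / psi) @ W + np.eye(K)
    np.testing.assert_allclose(prec, prec_oracle, atol=1e-10)
    for i in range(N):
        rhs = W.T @ np.diag(1 / psi) @ Y[i] + prior_mean[i]
        np.testing.assert_allclose(mean[i], np.linalg.solve(prec_oracle, rhs),
                                   atol=1e-10)


def test_z_no_data_limit_is_prior(rng):
    """W = 0: the conditional is exactly N(G beta, I)."""
    N, K = 8, 3
    Y = rng.standard_normal((N, 4))
    prior_mean = rng.standard_normal((N, K))
    mean, prec = z_posterior_params(np.zeros((4, K)), np.ones(4), Y, prior_mean)
    np.testing.assert_allclose(mean, prior_mean, atol=1e-12)
    np.testing.assert_allclose(prec, np.eye(K), atol=1e-12)


def test_z_data_dominant_limit(rng):
    """psi -> 0 with square invertible W: mean -> Y W (W'W)^-1."""
    N, K = 5, 3
    W = rng.standard_normal((K, K)) + 2 * np.eye(K)
    Y = rng.standard_normal((N, K))
    mean, _ = z_posterior_params(W, np.full(K, 1e-10), Y, np.zeros((N, K)))
    np.testing.assert_allclose(mean, Y @ W @ np.linalg.inv(W.T @ W), atol=1e-6)


# ---------------------------------------------------------------------------
# variance and hyperparameter conditionals (density-ratio oracle)


def test_psi_conditional_density_ratio():
    """The inverse-gamma conditional density ratio equals the prior-times-
    likelihood ratio at arbitrary points (Metropolis would always accept)."""
    a, b = 2.0, 1.0
    N, ss = 12, 3.7  # residual sum of squares for one gene
    cond = scipy.stats.invgamma(a + N / 2, scale=b + ss / 2)
    prior = scipy.stats.invgamma(a, scale=b)

    def log_target(psi):
        # prior x N(residuals; 0, psi) likelihood with ss = sum of squares
        return prior.logpdf(psi) - 0.5 * (
            N * np.log(2 * np.pi * psi) + ss / psi
        )

    for p1, p2 in [(0.3, 1.1), (0.8, 2.5)]:
        lhs = cond.logpdf(p1) - cond.logpdf(p2)
        rhs = log_target(p1) - log_target(p2)
        assert lhs == pytest.approx(rhs, abs=1e-10)


def test_pi_and_sigma2_conditionals_density_ratio():
    a0, b0 = 1.0, 10.0
    P, n1 = 30, 7
    cond = scipy.stats.beta(a0 + n1, b0 + P - n1)
    prior = scipy.stats.beta(a0, b0)
    for q1, q2 in [(0.1, 0.4), (0.2, 0.7)]:
        lhs = cond.logpdf(q1) - cond.logpdf(q2)
        rhs = (prior.logpdf(q1) + n1 * np.log(q1) + (P - n1) * np.log1p(-q1)) - (
            prior.logpdf(q2) + n1 * np.log(q2) + (P - n1) * np.log1p(-q2)
        )
        assert lhs == pytest.approx(rhs, abs=1e-10)
    # sigma2 with the mixture scale factor: W_jk ~ N(0, sigma2 * f_jk)
    rng = np.random.default_rng(0)
    w = rng.standard_normal(6)
    f = np.array([1.0, 0.0625, 1.0, 0.0625, 1.0, 1.0])  # c = 0.25
    a_s, b_s = 2.0, 1.0
    ssw = np.sum(w**2 / f)
    cond = scipy.stats.invgamma(a_s + len(w) / 2, scale=b_s + ssw / 2)
    prior = scipy.stats.invgamma(a_s, scale=b_s)

    def log_lik(s2):
        return float(np.sum(scipy.stats.norm(0, np.sqrt(s2 * f)).logpdf(w)))

    for s1, s2_ in [(0.5, 1.5), (0.9, 2.0)]:
        lhs = cond.logpdf(s1) - cond.logpdf(s2_)
        rhs = (prior.logpdf(s1) + log_lik(s1)) - (prior.logpdf(s2_) + log_lik(s2_))
        assert lhs == pytest.approx(rhs, abs=1e-10)


# ---------------------------------------------------------------------------
# full chain


def test_chain_seeded_determinism():
    Y, G, _ = simulate_normal(SimConfig(n_cells=50, n_genes=30, n_factors=3,
                                        n_perturbations=2,
                                        effect_matrix=np.array([[0.5, 0, 0],
                                                                [0, 0.4, 0]]),
                                        seed=2))
    kw = dict(n_iter=40, n_use=10, seed=9)
    r1 = make_model(Y, G, 3).fit(**kw)
    r2 = make_model(Y, G, 3).fit(**kw)
    np.testing.assert_array_equal(r1.samples.beta, r2.samples.beta)
    np.testing.assert_array_equal(r1.samples.W, r2.samples.W)
    np.testing.assert_array_equal(r1.samples.F, r2.samples.F)
    np.testing.assert_array_equal(r1.log_joint_trace, r2.log_joint_trace)


def test_chain_rejects_nan_input(rng):
    Y = rng.standard_normal((10, 5))
    Y[0, 0] = np.nan
    with pytest.raises(Exception, match="NaN|finite"):
        make_model(Y, np.zeros((10, 1), dtype=np.int8), 2)


def test_log_joint_finite_and_stabilizes():
    Y, G, _ = simulate_normal(SimConfig(n_cells=120, n_genes=60, n_factors=4,
                                        n_perturbations=3,
                                        effect_matrix=0.4 * np.eye(3, 4),
                                        factor_density=0.2, seed=4))
    res = make_model(Y, G, 4).fit(n_iter=300, n_use=100, seed=0)
    tr = res.log_joint_trace
    assert np.all(np.isfinite(tr))
    third = len(tr) // 3
    assert tr[-third:].mean() >= tr[:third].mean() - 50.0


def test_two_group_null_betas_agree():
    """Identically generated groups: group-specific effects agree within
    posterior uncertainty."""
    Y, G, _ = simulate_normal(SimConfig(n_cells=600, n_genes=150, n_factors=4,
                                        n_perturbations=2,
                                        effect_matrix=np.array([[0.6, 0, 0, 0],
                                                                [0, 0.5, 0, 0]]),
                                        factor_density=0.2, seed=11))
    groups = np.arange(600) % 2
    res = make_model(Y, G, 4, groups=groups).fit(n_iter=400, n_use=150, seed=1)
    from gsfa.results import mean_beta

    mb0 = mean_beta(res.samples, group=0)
    mb1 = mean_beta(res.samples, group=1)
    sd0, sd1 = res.sd_beta(group=0), res.sd_beta(group=1)
    tol = 3 * np.sqrt(sd0**2 + sd1**2) + 0.1
    assert np.all(np.abs(mb0 - mb1) <= tol)


def test_parameter_recovery_on_model_simulated_data():
    """Effects >= 0.3 are recovered within 2 posterior sds (with the mild
    sparsity-induced downward shrinkage) on matched factors."""
    from gsfa.evaluate import match_factors

    Y, G, truth = simulate_normal(SimConfig(n_cells=4000, n_genes=600,
                                            factor_density=0.1, seed=21))
    res = make_model(Y, G, 10).fit(n_iter=600, n_use=200, seed=21)
    fmap = match_factors(truth.Z, res.z_mean)
    mb = np.asarray(res.mean_beta)
    sd = res.sd_beta()
    for m in range(6):
        k_true = int(np.flatnonzero(truth.beta[m])[0])
        effect = truth.beta[m, k_true]
        if effect < 0.3:
            continue
        k_inf, _ = fmap[k_true]
        est = abs(mb[m, k_inf])
        assert abs(est - effect) <= 2 * sd[m, k_inf] + 0.05, (
            f"perturbation {m}: estimate {est:.3f} vs truth {effect}"
        )
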