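"""GEE/GLM fitting, dispersion and correlation estimation, residual scores."""

import numpy as np
import pytest
import statsmodels.api as sm

import mvgmdr as m
from mvgmdr.gee import ALPHA_EPS
from conftest import make_panel


def _covars(n, rng, ids=None):
    vals = np.c_[np.ones(n), rng.standard_normal(n), rng.integers(0, 2, n)]
    return m.CovariateTable(ids if ids is not None else
                            [f"s{i}" for i in range(n)],
                            ["intercept", "x1", "x2"], vals)


def _copula_binary(p, rho, t, rng):
    """Correlated binary occasions with exact marginals p (Gaussian copula)."""
    n = len(p)
    R = (1 - rho) * np.eye(t) + rho * np.ones((t, t))
    L = rng.standard_normal((n, t)) @ np.linalg.cholesky(R).T
    from scipy.special import ndtr
    return (ndtr(L) < p[:, None]).astype(float)


# ---------------------------------------------------------------------------
# closed forms and GLM equivalence
# ---------------------------------------------------------------------------

def test_intercept_only_binomial_balanced():
    P = make_panel(np.r_[np.ones(50), np.zeros(50)])
    fit = m.fit_null_model(P, structure="independence")
    assert fit.gamma[0] == pytest.approx(0.0, abs=1e-10)
    assert fit.mu_hat[0, 0] == pytest.approx(0.5)


def test_intercept_only_gaussian_is_grand_mean(rng):
    y = rng.standard_normal((40, 3)) + 2.0
    P = make_panel(y, family="gaussian")
    fit = m.fit_null_model(P, structure="independence")
    assert fit.gamma[0] == pytest.approx(y.mean(), abs=1e-9)
    # single shared intercept -> one grand mean, not per-occasion means
    assert np.allclose(fit.mu_hat, y.mean())


@pytest.mark.parametrize("family", ["binomial", "gaussian"])
@pytest.mark.parametrize("seed", range(5))
def test_independence_t1_matches_statsmodels_glm(family, seed):
    rng = np.random.default_rng(seed)
    n = 200
    Z = _covars(n, rng)
    eta = Z.values @ np.array([-0.5, 0.8, 0.4])
    if family == "binomial":
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        smfam = sm.families.Binomial()
    else:
        y = eta + rng.standard_normal(n)
        smfam = sm.families.Gaussian()
    P = make_panel(y, family=family)
    fit = m.fit_null_model(P, Z, structure="independence")
    oracle = sm.GLM(y, Z.values, family=smfam).fit()
    np.testing.assert_allclose(fit.gamma, oracle.params, atol=1e-6)


def test_gaussian_independence_equals_ols(rng):
    n = 150
    Z = _covars(n, rng)
    y = Z.values @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(n)
    fit = m.fit_null_model(make_panel(y, "gaussian"), Z,
                           structure="independence")
    beta_ols, *_ = np.linalg.lstsq(Z.values, y, rcond=None)
    np.testing.assert_allclose(fit.gamma, beta_ols, atol=1e-8)


def test_exchangeable_gee_close_to_statsmodels(rng):
    n, t = 400, 3
    Z = _covars(n, rng)
    p = 1 / (1 + np.exp(-(Z.values @ np.array([-1.0, 0.5, 0.3]))))
    y = _copula_binary(p, 0.5, t, rng)
    fit = m.fit_null_model(make_panel(y), Z, structure="exchangeable")
    groups = np.repeat(np.arange(n), t)
    oracle = sm.GEE(y.ravel(), np.repeat(Z.values, t, axis=0), groups,
                    family=sm.families.Binomial(),
                    cov_struct=sm.cov_struct.Exchangeable()).fit()
    np.testing.assert_allclose(fit.gamma, oracle.params, atol=0.02)
    np.testing.assert_allclose(np.sqrt(np.diag(fit.cov_robust)),
                               oracle.bse, rtol=0.1)


# ---------------------------------------------------------------------------
# dispersion and working correlation
# ---------------------------------------------------------------------------

class TestDispersionAlpha:
    def test_zero_residuals_guarded(self):
        phi, alpha = m.estimate_dispersion_and_alpha(
            np.zeros((10, 2)), "exchangeable")
        assert phi <= 1e-12
        assert alpha == pytest.approx(0.0, abs=1e-6)

    def test_perfectly_correlated_pairs_clip(self, rng):
        r = np.repeat(rng.standard_normal((200, 1)), 2, axis=1)
        phi, alpha = m.estimate_dispersion_and_alpha(r, "exchangeable")
        assert alpha == pytest.approx(1 - ALPHA_EPS)

    def test_exchangeable_undefined_for_t1(self):
        with pytest.raises(ValueError, match="t=1"):
            m.estimate_dispersion_and_alpha(np.ones((5, 1)), "exchangeable")

    def test_gaussian_alpha_recovery(self):
        rng = np.random.default_rng(5)
        n, rho = 2000, 0.5
        R = np.array([[1, rho], [rho, 1.0]])
        r = rng.standard_normal((n, 2)) @ np.linalg.cholesky(R).T
        phi, alpha = m.estimate_dispersion_and_alpha(r, "exchangeable")
        assert abs(alpha - rho) < 0.05
        assert phi == pytest.approx(1.0, abs=0.1)

    def test_unstructured_recovers_matrix(self):
        rng = np.random.default_rng(6)
        R = np.array([[1.0, 0.2, 0.5], [0.2, 1.0, 0.3], [0.5, 0.3, 1.0]])
        r = rng.standard_normal((4000, 3)) @ np.linalg.cholesky(R).T
        _, Rhat = m.estimate_dispersion_and_alpha(r, "unstructured")
        np.testing.assert_allclose(Rhat, R, atol=0.06)
        assert np.allclose(np.diag(Rhat), 1.0)

    def test_alpha_vanishes_for_independent_data(self):
        # working exchangeable on truly independent outcomes
        alphas = []
        for seed in range(11):
            rng = np.random.default_rng(seed)
            n = 5000
            Z = _covars(n, rng)
            y = rng.binomial(1, 0.2, size=(n, 2)).astype(float)
            fit = m.fit_null_model(make_panel(y), Z, structure="exchangeable")
            alphas.append(fit.working_corr.alpha)
        assert abs(np.median(alphas)) < 0.05


# ---------------------------------------------------------------------------
# residual scores
# ---------------------------------------------------------------------------

def test_scores_are_raw_residuals_under_independence(rng):
    n = 120
    Z = _covars(n, rng)
    p = 1 / (1 + np.exp(-(Z.values @ np.array([-0.8, 0.5, 0.2]))))
    y = rng.binomial(1, np.c_[p, p]).astype(float)
    P = make_panel(y)
    fit = m.fit_null_model(P, Z, structure="independence")
    assert fit.phi == 1.0  # binomial convention
    sc = m.residual_scores(fit, P)
    np.testing.assert_allclose(sc.per_occasion, y - fit.mu_hat, atol=1e-12)
    assert abs(sc.aggregated.sum()) < 1e-8  # intercept score identity
    np.testing.assert_allclose(sc.aggregated, sc.per_occasion.sum(axis=1))


def test_balanced_case_control_scores_are_half():
    P = make_panel(np.r_[np.ones(30), np.zeros(30)])
    sc = m.residual_scores(m.fit_null_model(P, structure="independence"), P)
    assert set(np.round(sc.aggregated, 12)) == {0.5, -0.5}


def test_multivariate_worked_example_against_brute_solve():
    """t=2 gaussian, phi=1, exchangeable alpha=0.5, residual (1,0)."""
    P = make_panel(np.array([[1.0, 0.0]]), family="gaussian")
    fit = m.NullModelFit(
        gamma=np.zeros(1), names=["intercept"],
        mu_hat=np.zeros((1, 2)), phi=1.0,
        working_corr=m.WorkingCorrelation("exchangeable", 0.5, 2),
        family="gaussian", cov_model=np.eye(1), cov_robust=np.eye(1),
        converged=True, n_iter=1)
    sc = m.residual_scores(fit, P)
    np.testing.assert_allclose(sc.per_occasion[0], [4 / 3, -2 / 3], atol=1e-12)
    assert sc.aggregated[0] == pytest.approx(2 / 3)
    # brute-force oracle: S = B V^{-1} (y - mu) via a dense linear solve
    V = 1.0 * np.array([[1.0, 0.5], [0.5, 1.0]])
    oracle = np.eye(2) @ np.linalg.solve(V, np.array([1.0, 0.0]))
    np.testing.assert_allclose(sc.per_occasion[0], oracle, atol=1e-12)


def test_scores_follow_subjects_under_permutation(rng):
    n = 80
    Z = _covars(n, rng)
    y = rng.binomial(1, 0.3, size=(n, 2)).astype(float)
    P = make_panel(y)
    fit = m.fit_null_model(P, Z, structure="exchangeable")
    sc = m.residual_scores(fit, P)
    perm = rng.permutation(n)
    P2 = P.restrict(perm)
    Z2 = Z.restrict(perm)
    fit2 = m.fit_null_model(P2, Z2, structure="exchangeable")
    sc2 = m.residual_scores(fit2, P2)
    by_id = dict(zip(sc.subject_ids, sc.aggregated))
    for sid, s in zip(sc2.subject_ids, sc2.aggregated):
        assert s == pytest.approx(by_id[sid], abs=1e-9)


def test_partial_occasions_use_submatrices(rng):
    n = 60
    y = rng.binomial(1, 0.4, size=(n, 3)).astype(float)
    y[:10, 2] = np.nan  # ten subjects miss occasion 3
    P = make_panel(y)
    fit = m.fit_null_model(P, structure="exchangeable")
    sc = m.residual_scores(fit, P)
    assert np.isnan(sc.per_occasion[:10, 2]).all()
    assert np.isfinite(sc.aggregated).all()
    # complete subjects see the full 3x3 working correlation
    assert np.isfinite(sc.per_occasion[10:]).all()


# ---------------------------------------------------------------------------
# robust inference
# ---------------------------------------------------------------------------

def test_wald_trivial_values(rng):
    n = 500
    Z = _covars(n, rng)
    g = rng.integers(0, 3, n).astype(float)
    y = rng.binomial(1, 0.3, size=(n, 2)).astype(float)
    fit = m.fit_marginal_model(make_panel(y), Z, structure="exchangeable",
                               genotype=g)
    w = m.wald_test_genetic_effect(fit)
    assert w.df == 2 and 0 <= w.p_value <= 1
    # chi2(1) at z=1.96 corresponds to p ~= 0.05
    from scipy import stats
    assert stats.chi2.sf(1.96 ** 2, 1) == pytest.approx(0.05, abs=1e-3)
    fit.params[: fit.n_beta] = 0.0
    w0 = m.wald_test_genetic_effect(fit)
    assert w0.statistic == 0.0 and w0.p_value == 1.0


def test_wald_type_one_error_calibrated():
    rej = 0
    reps = 500
    for seed in range(reps):
        rng = np.random.default_rng(10_000 + seed)
        n = 300
        Z = _covars(n, rng)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, 0.25, size=(n, 2)).astype(float)  # no G effect
        fit = m.fit_marginal_model(make_panel(y), Z,
                                   structure="exchangeable", genotype=g)
        if m.wald_test_genetic_effect(fit).p_value < 0.05:
            rej += 1
    assert 0.03 <= rej / reps <= 0.08


def test_sandwich_matches_model_cov_when_correctly_specified():
    rng = np.random.default_rng(3)
    n, t, rho = 5000, 2, 0.4
    Z = _covars(n, rng)
    mu = Z.values @ np.array([0.5, 1.0, -0.5])
    R = np.array([[1, rho], [rho, 1.0]])
    eps = rng.standard_normal((n, t)) @ np.linalg.cholesky(R).T
    y = mu[:, None] + eps
    fit = m.fit_null_model(make_panel(y, "gaussian"), Z,
                           structure="exchangeable")
    ratio = np.sqrt(np.diag(fit.cov_robust) / np.diag(fit.cov_model))
    assert np.all((ratio > 0.9) & (ratio < 1.1))


# ---------------------------------------------------------------------------
# degenerate inputs
# ---------------------------------------------------------------------------

def test_constant_binary_outcome_refused():
    P = make_panel(np.ones(40))
    with pytest.raises(m.ConvergenceError, match="constant"):
        m.fit_null_model(P, structure="independence")


def test_separation_raises_diagnostic_error(rng):
    n = 60
    x = np.r_[np.zeros(30), np.ones(30)]
    Z = m.CovariateTable([f"s{i}" for i in range(n)], ["intercept", "x"],
                         np.c_[np.ones(n), x])
    y = x.copy()  # perfectly separated
    with pytest.raises(m.ConvergenceError):
        m.fit_null_model(make_panel(y), Z, structure="independence")


def test_exchangeable_refused_for_single_occasion(rng):
    P = make_panel(rng.binomial(1, 0.4, 50).astype(float))
    with pytest.raises(ValueError, match="t=1"):
        m.fit_null_model(P, structure="exchangeable")
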