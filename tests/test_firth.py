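"""Firth / FLIC estimation against closed forms, grid oracles and ML cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit
from scipy.stats import chi2

from confsel import firth

# ---------------------------------------------------------------------------
# closed forms


@pytest.mark.parametrize(
    "k,n",
    [(3, 6), (0, 4), (1, 10), (10, 10), (2, 7)],
)
def test_intercept_only_closed_form(k, n):
    """Firth intercept-only estimate is logit((k + 1/2) / (n + 1))."""
    y = np.concatenate([np.ones(k), np.zeros(n - k)])
    fit = firth.fit_firth(np.ones((n, 1)), y, tol=1e-12)
    assert fit.converged
    assert fit.coefficients[0] == pytest.approx(logit((k + 0.5) / (n + 1)), abs=1e-8)


def test_intercept_only_grid_oracle():
    """The returned optimum dominates a fine 1-D grid of the penalized likelihood."""
    y = np.concatenate([np.ones(2), np.zeros(7)])
    X = np.ones((9, 1))
    fit = firth.fit_firth(X, y, tol=1e-10)

    def pll(b):
        pi = expit(b)
        info = 9 * pi * (1 - pi)
        return 2 * b + 9 * (-np.logaddexp(0, b)) + 0.5 * np.log(info)

    grid = np.linspace(-4, 2, 30001)
    vals = pll(grid)
    assert pll(fit.coefficients[0]) >= vals.max() - 1e-10
    assert abs(grid[vals.argmax()] - fit.coefficients[0]) < 1e-3


def test_two_parameter_grid_oracle():
    """2-D grid maximization of the penalized likelihood agrees to 1e-4."""
    rng = np.random.default_rng(3)
    n = 40
    x = rng.standard_normal(n)
    y = (rng.random(n) < expit(0.8 * x - 0.3)).astype(float)
    X = np.column_stack([np.ones(n), x])
    fit = firth.fit_firth(X, y, tol=1e-12)

    def pll(b0, b1):
        eta = b0 + b1 * x
        pi = expit(eta)
        w = pi * (1 - pi)
        info = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
        return (
            y @ eta - np.logaddexp(0, eta).sum() + 0.5 * np.linalg.slogdet(info)[1]
        )

    # coarse-to-fine grid search around a generous box
    b0s = np.linspace(-2, 2, 81)
    b1s = np.linspace(-1, 3, 81)
    best = max(((pll(a, b), a, b) for a in b0s for b in b1s))
    for _ in range(4):
        _, a0, b0 = best
        span = (b0s[1] - b0s[0]) * 2
        b0s = np.linspace(a0 - span, a0 + span, 41)
        b1s = np.linspace(b0 - span, b0 + span, 41)
        best = max(((pll(a, b), a, b) for a in b0s for b in b1s))
    assert fit.coefficients[0] == pytest.approx(best[1], abs=1e-4)
    assert fit.coefficients[1] == pytest.approx(best[2], abs=1e-4)
    assert pll(*fit.coefficients) >= best[0] - 1e-10


def test_complete_separation_finite():
    """Separated data yield finite estimates; symmetric design has zero intercept."""
    X = np.column_stack([np.ones(4), [-2.0, -1.0, 1.0, 2.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    fit = firth.fit_firth(X, y, tol=1e-10)
    assert fit.converged
    assert np.all(np.isfinite(fit.coefficients))
    assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)
    # oracle for the slope: 1-D grid over the profile (intercept = 0 by symmetry)
    x = X[:, 1]

    def pll(b):
        eta = b * x
        pi = expit(eta)
        w = pi * (1 - pi)
        info = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
        return y @ eta - np.logaddexp(0, eta).sum() + 0.5 * np.linalg.slogdet(info)[1]

    grid = np.linspace(0.0, 4.0, 40001)
    b_star = grid[np.argmax([pll(b) for b in grid])]
    assert fit.coefficients[1] == pytest.approx(b_star, abs=1e-3)


def test_all_events_degenerate_allowed():
    fit = firth.fit_firth(np.ones((5, 1)), np.ones(5), tol=1e-10)
    assert fit.coefficients[0] == pytest.approx(logit(5.5 / 6.0), abs=1e-8)


# ---------------------------------------------------------------------------
# FLIC


def test_flic_mean_prediction_identity(logistic_data):
    X, y = logistic_data
    fit = firth.fit_flic(X, y)
    assert fit.converged
    assert abs(fit.fitted_probabilities.mean() - y.mean()) < 1e-8


def test_flic_slopes_equal_firth_slopes(logistic_data):
    X, y = logistic_data
    base = firth.fit_firth(X, y)
    flic = firth.fit_flic(X, y, firth_fit=base)
    np.testing.assert_array_equal(flic.coefficients[1:], base.coefficients[1:])


def test_flic_intercept_only_is_plain_ml():
    y = np.concatenate([np.ones(4), np.zeros(6)])
    fit = firth.fit_flic(np.ones((10, 1)), y)
    assert fit.coefficients[0] == pytest.approx(logit(0.4), abs=1e-8)


# ---------------------------------------------------------------------------
# invariants


def test_hat_diagonals_trace_identity(logistic_data):
    X, y = logistic_data
    for fit in (firth.fit_firth(X, y), firth.fit_flic(X, y), firth.fit_ml(X, y)):
        h = fit.hat_diagonals
        assert np.all(h >= -1e-12) and np.all(h <= 1 + 1e-12)
        assert h.sum() == pytest.approx(X.shape[1], abs=1e-8)
        assert np.all((fit.fitted_probabilities > 0) & (fit.fitted_probabilities < 1))


def test_covariance_matches_numeric_information(logistic_data):
    """inv(covariance) equals the numerically differentiated observed information."""
    X, y = logistic_data
    fit = firth.fit_firth(X, y, tol=1e-10)
    p = X.shape[1]
    eps = 1e-5

    def grad(beta):
        pi = expit(X @ beta)
        return X.T @ (y - pi)

    H = np.zeros((p, p))
    for j in range(p):
        e = np.zeros(p)
        e[j] = eps
        H[:, j] = (grad(fit.coefficients + e) - grad(fit.coefficients - e)) / (2 * eps)
    info_num = -H
    info_rep = np.linalg.inv(fit.covariance)
    np.testing.assert_allclose(info_rep, info_num, rtol=1e-4)


def test_firth_shrinks_toward_ml_with_n():
    """Firth-ML coefficient gap decays at an O(1/n)-compatible rate."""
    beta_true = np.array([-0.4, 0.7, 0.5])
    gaps = []
    for n in (100, 1000, 10000):
        r = np.random.default_rng(42)
        x = r.standard_normal((n, 2))
        X = np.column_stack([np.ones(n), x])
        y = (r.random(n) < expit(X @ beta_true)).astype(float)
        f1 = firth.fit_firth(X, y, tol=1e-10)
        f2 = firth.fit_ml(X, y, tol=1e-10)
        gaps.append(np.max(np.abs(f1.coefficients - f2.coefficients)))
    assert gaps[0] > gaps[1] > gaps[2]
    # 100-fold n increase should shrink the gap by at least ~20x if O(1/n)
    assert gaps[2] < gaps[0] / 20


def test_ml_agrees_with_statsmodels(logistic_data):
    statsmodels = pytest.importorskip("statsmodels.api")
    X, y = logistic_data
    ours = firth.fit_ml(X, y, tol=1e-10)
    ref = statsmodels.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-6)
    np.testing.assert_allclose(ours.plain_loglik, ref.llf, atol=1e-8)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(30, 120))
def test_firth_fit_properties_random_designs(seed, n):
    """Hat trace, probability bounds and penalized-likelihood optimality flags."""
    r = np.random.default_rng(seed)
    x = r.standard_normal((n, 2))
    X = np.column_stack([np.ones(n), x])
    y = (r.random(n) < expit(0.5 * x[:, 0] - 0.2)).astype(float)
    fit = firth.fit_firth(X, y)
    assert fit.converged
    assert fit.hat_diagonals.sum() == pytest.approx(3, abs=1e-6)
    assert np.all((fit.fitted_probabilities > 0) & (fit.fitted_probabilities < 1))
    ev = np.linalg.eigvalsh(fit.covariance)
    assert np.all(ev > 0)


# ---------------------------------------------------------------------------
# errors


def test_rank_deficiency_names_columns():
    X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
    y = (np.arange(20) % 2).astype(float)
    with pytest.raises(firth.RankDeficientError) as err:
        firth.fit_firth(X, y)
    assert set(err.value.columns) >= {1, 2}


def test_max_iter_exceeded_returns_unconverged(logistic_data):
    X, y = logistic_data
    fit = firth.fit_firth(X, y, max_iter=1)
    assert not fit.converged


# ---------------------------------------------------------------------------
# penalized LR test


def test_plr_identical_models_p_one(logistic_data):
    X, y = logistic_data
    fit = firth.fit_firth(X, y)
    assert firth.plr_test(fit, fit) == 1.0


def test_plr_chi2_reference():
    assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=2e-4)


def test_plr_strong_covariate_significant():
    r = np.random.default_rng(5)
    n = 500
    x = r.standard_normal(n)
    y = (r.random(n) < expit(1.0 * x)).astype(float)
    X = np.column_stack([np.ones(n), x])
    fit_full = firth.fit_firth(X, y)
    fit_red = firth.fit_firth(X[:, :1], y)
    assert firth.plr_test(fit_full, fit_red) < 1e-3


def test_plr_non_nested_error(logistic_data):
    X, y = logistic_data
    fit_full = firth.fit_firth(X[:, :3], y)
    fit_other = firth.fit_firth(X[:, [0, 3]], y)
    with pytest.raises(ValueError, match="nested"):
        firth.plr_test(fit_full, fit_other)


# ---------------------------------------------------------------------------
# profile penalized likelihood CIs


def test_profile_ci_defining_equation(logistic_data):
    X, y = logistic_data
    fit = firth.fit_firth(X, y, tol=1e-10)
    lo, hi = firth.profile_penalized_likelihood_ci(X, y, 1, 0.95, fit=fit)
    assert lo < fit.coefficients[1] < hi
    threshold = chi2.ppf(0.95, 1)
    for b in (lo, hi):
        pll_b, _ = firth._profile_pll(X, y, 1, b, fit.coefficients)
        assert 2 * (fit.penalized_loglik - pll_b) == pytest.approx(threshold, abs=1e-6)


def test_profile_ci_symmetric_intercept_only():
    y = np.concatenate([np.ones(3), np.zeros(3)])
    X = np.ones((6, 1))
    lo, hi = firth.profile_penalized_likelihood_ci(X, y, 0, 0.95)
    assert lo == pytest.approx(-hi, abs=1e-6)


def test_profile_ci_finite_under_separation():
    X = np.column_stack([np.ones(4), [-2.0, -1.0, 1.0, 2.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    lo, hi = firth.profile_penalized_likelihood_ci(X, y, 1, 0.95)
    assert np.isfinite(lo) and np.isfinite(hi) and lo < hi
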