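"""Penalized logistic regression: Firth bias reduction, FLIC, and penalized-likelihood inference.

Firth's correction maximizes the penalized log-likelihood

    pl(beta) = l(beta) + 1/2 * log|I(beta)|,

where ``I(beta) = X' W X`` is the Fisher information of the logistic model and
``W = diag(pi_i (1 - pi_i))``.  The penalty removes the leading O(1/n) term of
the small-sample bias of the ML estimator and guarantees finite coefficient
estimates even under complete or quasi-complete separation.  The gradient of
the penalty is available in closed form, giving the modified score

    U*_j = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_ij,

with ``h_i`` the diagonals of the weighted hat matrix
``H = W^{1/2} X I^{-1} X' W^{1/2}``.

FLIC (Firth logistic regression with intercept correction) keeps the Firth
slopes but re-estimates the intercept by plain maximum likelihood with the
Firth linear predictor (minus intercept) as an offset.  Its defining property
is that the mean fitted probability equals the observed event fraction, which
makes it the appropriate basis for standardized (g-computation) risk
estimates in rare-event settings.

Confidence intervals for single coefficients are obtained by profiling the
penalized likelihood: the coefficient of interest is fixed and the penalized
likelihood (with the penalty of the *full* model) is maximized over the
remaining parameters; interval endpoints solve the chi-squared(1) deviance
equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "FitResult",
    "fit_firth",
    "fit_ml",
    "fit_flic",
    "plr_test",
    "profile_penalized_likelihood_ci",
    "RankDeficientError",
    "ProfileBracketError",
]


class RankDeficientError(ValueError):
    """Design matrix is not of full column rank."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(str(c) for c in self.columns)
        )


class ProfileBracketError(RuntimeError):
    """Profile deviance did not cross the confidence threshold within the bracket."""

    def __init__(self, side, bracket):
        self.side = side
        self.bracket = bracket
        super().__init__(
            f"profile penalized likelihood did not cross the threshold on the "
            f"{side} side within bracket {bracket}"
        )


@dataclass
class FitResult:
    """A fitted (possibly penalized) logistic regression model.

    ``coefficients`` are on the log-odds scale with the intercept first.  The
    ``covariance`` is the inverse of the Fisher information ``X'WX`` evaluated
    at the optimum (the usual Wald covariance of penalized-likelihood
    software).  ``penalized_loglik`` equals ``plain_loglik`` for ML fits.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    hat_diagonals: np.ndarray
    penalized_loglik: float
    plain_loglik: float
    fitted_probabilities: np.ndarray
    converged: bool
    n_iterations: int
    method_tag: str  # "ML" | "Firth" | "FLIC"
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    offset: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return self.coefficients.shape[0]

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def wald_ci(self, index: int, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = float(np.sqrt(self.covariance[index, index]))
        b = float(self.coefficients[index])
        return b - z * se, b + z * se

    def summary_table(self) -> str:
        lines = ["index  coef        se"]
        se = self.standard_errors()
        for j, (b, s) in enumerate(zip(self.coefficients, se)):
            lines.append(f"{j:<6d} {b:>10.5f} {s:>9.5f}")
        return "\n".join(lines)


def _check_rank(X: np.ndarray) -> None:
    # SVD-based rank check; name offending columns via the trailing right
    # singular vectors so the caller can see what is collinear.
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if s[0] > 0 else 0.0
    deficient = s <= tol
    if deficient.any():
        cols: set[int] = set()
        for row in vt[deficient]:
            cols.update(np.nonzero(np.abs(row) > 1e-8)[0].tolist())
        raise RankDeficientError(sorted(cols))


def _loglik(y, eta):
    # sum y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _penalized_core(X, beta, y, offset, penalized):
    """Return (pll, pi, w, cho, logdet) at beta."""
    eta = X @ beta
    if offset is not None:
        eta = eta + offset
    pi = special.expit(eta)
    w = pi * (1.0 - pi)
    ll = _loglik(y, eta)
    if not penalized:
        return ll, pi, w, None, 0.0
    info = (X.T * w) @ X
    cho = cho_factor(info, lower=True, check_finite=False)
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    return ll + 0.5 * logdet, pi, w, cho, logdet


def _newton_logistic(
    X,
    y,
    *,
    penalized,
    offset=None,
    beta_init=None,
    max_iter=50,
    tol=1e-6,
    max_halvings=5,
    free_mask=None,
):
    """Shared Newton core for ML and Firth fits, optionally with frozen coordinates.

    When ``free_mask`` is given, only the marked coordinates are updated while
    the penalty (if any) is still that of the full design — this is what
    profiling the penalized likelihood requires.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, float).copy()
    if free_mask is None:
        free_mask = np.ones(p, dtype=bool)
    free_idx = np.nonzero(free_mask)[0]

    pll, pi, w, cho, _ = _penalized_core(X, beta, y, offset, penalized)
    converged = False
    it = 0
    h = np.zeros(n)
    if free_idx.size == 0:
        # nothing to optimize: evaluate at the fixed point
        if penalized and cho is not None:
            V = cho_solve(cho, X.T, check_finite=False).T
            h = np.einsum("ij,ij->i", V, X) * w
        return beta, pll, pi, w, h, True, 0
    for it in range(1, max_iter + 1):
        if penalized:
            # h_i = w_i x_i' (X'WX)^{-1} x_i
            V = cho_solve(cho, X.T, check_finite=False).T
            h = np.einsum("ij,ij->i", V, X) * w
            resid = y - pi + h * (0.5 - pi)
        else:
            resid = y - pi
        score = X.T @ resid
        score_free = score[free_idx]
        if np.max(np.abs(score_free)) < tol:
            converged = True
            break
        if penalized:
            info = cho  # cholesky of full information
            if free_idx.size == p:
                delta_free = cho_solve(info, score, check_finite=False)[free_idx]
            else:
                sub = ((X.T * w) @ X)[np.ix_(free_idx, free_idx)]
                delta_free = np.linalg.solve(sub, score_free)
        else:
            info_full = (X.T * w) @ X
            sub = info_full[np.ix_(free_idx, free_idx)]
            delta_free = np.linalg.solve(sub, score_free)
        delta = np.zeros(p)
        delta[free_idx] = delta_free
        # step-halving: insist the (penalized) likelihood does not decrease
        step = 1.0
        for _ in range(max_halvings + 1):
            cand = beta + step * delta
            try:
                pll_new, pi_new, w_new, cho_new, _ = _penalized_core(
                    X, cand, y, offset, penalized
                )
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if pll_new >= pll - 1e-10:
                break
            step *= 0.5
        else:
            # accept the most-halved step; Firth iterations recover from this
            cand = beta + step * delta
            pll_new, pi_new, w_new, cho_new, _ = _penalized_core(
                X, cand, y, offset, penalized
            )
        beta, pll, pi, w, cho = cand, pll_new, pi_new, w_new, cho_new
    if penalized and (cho is not None) and not converged:
        V = cho_solve(cho, X.T, check_finite=False).T
        h = np.einsum("ij,ij->i", V, X) * w
    return beta, pll, pi, w, h, converged, it


def _finalize(X, y, offset, beta, pll, pi, w, h, converged, it, tag) -> FitResult:
    info = (X.T * w) @ X
    cov = np.linalg.inv(info)
    cov = 0.5 * (cov + cov.T)
    eta = X @ beta
    if offset is not None:
        eta = eta + offset
    plain = _loglik(y, eta)
    if tag == "ML":
        # for ML the 'penalized' likelihood is the plain one; recompute hat
        # diagonals at the optimum for the trace identity
        cho = cho_factor(info, lower=True, check_finite=False)
        V = cho_solve(cho, X.T, check_finite=False).T
        h = np.einsum("ij,ij->i", V, X) * w
        pll = plain
    return FitResult(
        coefficients=beta,
        covariance=cov,
        hat_diagonals=h,
        penalized_loglik=float(pll),
        plain_loglik=plain,
        fitted_probabilities=pi,
        converged=converged,
        n_iterations=it,
        method_tag=tag,
        X=X,
        y=y,
        offset=None if offset is None else np.asarray(offset, float),
    )


def fit_firth(
    X,
    y,
    *,
    offset=None,
    beta_init=None,
    max_iter=50,
    tol=1e-6,
    max_halvings=5,
    check_rank=True,
) -> FitResult:
    """Firth-penalized logistic regression by modified-score Newton iteration.

    Parameters
    ----------
    X : (n, p) design matrix, intercept column included by the caller.
    y : (n,) binary response.
    offset : optional (n,) fixed addition to the linear predictor.
    beta_init : warm start (defaults to zero).
    tol : convergence on the max absolute modified score.

    Estimates are finite even under complete separation and for degenerate
    all-0 / all-1 responses.  Raises :class:`RankDeficientError` when the
    design is collinear; returns ``converged=False`` (never raises) when
    ``max_iter`` is exhausted.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if check_rank:
        _check_rank(X)
    beta, pll, pi, w, h, conv, it = _newton_logistic(
        X,
        y,
        penalized=True,
        offset=offset,
        beta_init=beta_init,
        max_iter=max_iter,
        tol=tol,
        max_halvings=max_halvings,
    )
    return _finalize(X, y, offset, beta, pll, pi, w, h, conv, it, "Firth")


def fit_ml(X, y, *, offset=None, beta_init=None, max_iter=50, tol=1e-6) -> FitResult:
    """Unpenalized maximum-likelihood logistic regression (same Newton core)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_rank(X)
    beta, pll, pi, w, h, conv, it = _newton_logistic(
        X, y, penalized=False, offset=offset, beta_init=beta_init,
        max_iter=max_iter, tol=tol,
    )
    return _finalize(X, y, offset, beta, pll, pi, w, h, conv, it, "ML")


def fit_flic(X, y, *, max_iter=50, tol=1e-6, firth_fit: FitResult | None = None) -> FitResult:
    """FLIC: Firth slopes with an ML-corrected intercept.

    The first column of ``X`` must be the intercept.  Slopes are fixed at the
    Firth estimates; the intercept solves the plain ML score equation with the
    Firth linear predictor (minus intercept) as offset, so that
    ``mean(fitted) == mean(y)`` exactly.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("FLIC requires an intercept in the first design column")
    base = fit_firth(X, y, max_iter=max_iter, tol=tol) if firth_fit is None else firth_fit
    lin = X @ base.coefficients - base.coefficients[0]
    # 1-D Newton for the intercept; monotone score, guarded bisection fallback
    b0 = float(base.coefficients[0])
    ybar = y.mean()
    conv = False
    n_it = base.n_iterations
    for _ in range(max_iter):
        pi = special.expit(b0 + lin)
        g = y.sum() - pi.sum()
        if abs(g) < tol:
            conv = True
            break
        wsum = (pi * (1.0 - pi)).sum()
        b0 += g / wsum
        n_it += 1
    if 0.0 < ybar < 1.0 and not conv:
        # bisection rescue: the score is strictly decreasing in b0
        lo, hi = b0 - 20.0, b0 + 20.0
        f = lambda b: y.sum() - special.expit(b + lin).sum()
        if f(lo) > 0 > f(hi):
            b0 = optimize.brentq(f, lo, hi, xtol=1e-12)
            conv = True
    beta = base.coefficients.copy()
    beta[0] = b0
    eta = X @ beta
    pi = special.expit(eta)
    w = pi * (1.0 - pi)
    info = (X.T * w) @ X
    cho = cho_factor(info, lower=True, check_finite=False)
    V = cho_solve(cho, X.T, check_finite=False).T
    h = np.einsum("ij,ij->i", V, X) * w
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    plain = _loglik(y, eta)
    cov = base.covariance.copy()
    cov[0, 0] = 1.0 / w.sum()  # offset-model intercept variance
    return FitResult(
        coefficients=beta,
        covariance=cov,
        hat_diagonals=h,
        penalized_loglik=plain + 0.5 * logdet,
        plain_loglik=plain,
        fitted_probabilities=pi,
        converged=bool(base.converged and conv),
        n_iterations=n_it,
        method_tag="FLIC",
        X=X,
        y=y,
    )


def _is_nested(fit_full: FitResult, fit_reduced: FitResult) -> bool:
    """Every column of the reduced design must occur in the full design."""
    Xf, Xr = fit_full.X, fit_reduced.X
    if Xr.shape[0] != Xf.shape[0] or Xr.shape[1] > Xf.shape[1]:
        return False
    for j in range(Xr.shape[1]):
        if not np.any(np.all(np.isclose(Xf, Xr[:, j][:, None]), axis=0)):
            return False
    return True


def constrained_pll(X, y, fixed: dict, beta_init=None, max_iter=50, tol=1e-6):
    """Maximized penalized loglik with some coefficients frozen.

    The penalty is always that of the *full* design, which is what both the
    penalized LR test and profile-likelihood intervals require: comparing
    penalized likelihoods of models with different dimension would let the
    Jeffreys penalty itself (about 1/2 log of the information per parameter)
    masquerade as evidence.  Returns (pll, beta).
    """
    p = X.shape[1]
    free = np.ones(p, dtype=bool)
    start = np.zeros(p) if beta_init is None else np.asarray(beta_init, float).copy()
    for idx, value in fixed.items():
        free[idx] = False
        start[idx] = value
    beta, pll, *_rest = _newton_logistic(
        X, y, penalized=True, beta_init=start, max_iter=max_iter, tol=tol,
        free_mask=free,
    )
    return pll, beta


def plr_test(fit_full: FitResult, fit_reduced: FitResult) -> float:
    """Penalized likelihood-ratio test of a reduced against a full model.

    The full model is refitted with the coefficients of the columns absent
    from the reduced design constrained to zero (keeping the full-model
    penalty); the statistic ``2 * (pl_full - pl_constrained)``, floored at
    zero, is referred to chi-squared with df = number of dropped columns.
    Returns the p-value.
    """
    if not (fit_full.converged and fit_reduced.converged):
        raise ValueError("both fits must have converged")
    if not _is_nested(fit_full, fit_reduced):
        raise ValueError("reduced model is not nested in the full model")
    stat, df = plr_test_statistic(fit_full, fit_reduced)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def plr_test_statistic(fit_full: FitResult, fit_reduced: FitResult) -> tuple[float, int]:
    """(statistic, df) of the penalized LR test; see :func:`plr_test`."""
    Xf, Xr = fit_full.X, fit_reduced.X
    dropped = [
        j
        for j in range(Xf.shape[1])
        if not np.any(np.all(np.isclose(Xr, Xf[:, j][:, None]), axis=0))
    ]
    if not dropped:
        return 0.0, 0
    pll0, _ = constrained_pll(
        Xf, fit_full.y, {j: 0.0 for j in dropped}, beta_init=fit_full.coefficients
    )
    stat = max(0.0, 2.0 * (fit_full.penalized_loglik - pll0))
    return stat, len(dropped)


def _profile_pll(X, y, index, value, beta_init, max_iter=50, tol=1e-6):
    """Maximized full-penalty penalized loglik with coefficient ``index`` fixed."""
    return constrained_pll(
        X, y, {index: value}, beta_init=beta_init, max_iter=max_iter, tol=tol
    )


def profile_penalized_likelihood_ci(
    X, y, coef_index: int, level: float = 0.95, *, fit: FitResult | None = None,
    tol: float = 1e-8, max_expand: int = 12,
) -> tuple[float, float]:
    """Profile-penalized-likelihood confidence interval for one coefficient.

    Endpoints ``b`` solve ``2*(pl_hat - pl_profile(b)) = chi2_1(level)``; they
    are located by expanding Wald-scaled brackets outward from the estimate
    and root-finding on the (monotone away from the optimum) profile deviance.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if fit is None:
        fit = fit_firth(X, y)
    est = float(fit.coefficients[coef_index])
    se = float(np.sqrt(fit.covariance[coef_index, coef_index]))
    threshold = float(stats.chi2.ppf(level, 1))
    pll_hat = fit.penalized_loglik

    def dev(b):
        pll_b, _ = _profile_pll(X, y, coef_index, b, fit.coefficients)
        return 2.0 * (pll_hat - pll_b) - threshold

    out = []
    for sign in (-1.0, 1.0):
        width = max(se, 1e-2)
        lo = est
        hi = est + sign * width
        found = False
        for _ in range(max_expand):
            if dev(hi) > 0:
                found = True
                break
            lo = hi
            hi = est + sign * (abs(hi - est) * 2.0)
        if not found:
            raise ProfileBracketError("lower" if sign < 0 else "upper", (lo, hi))
        a, b = (hi, lo) if sign < 0 else (lo, hi)
        root = optimize.brentq(dev, a, b, xtol=tol)
        out.append(root)
    lower, upper = out
    return float(lower), float(upper)
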