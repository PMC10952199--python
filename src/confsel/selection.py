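"""Backward elimination of candidate confounders from the outcome model.

Classical one-at-a-time backward elimination: starting from the model with
every candidate covariate, each step refits the model with each remaining
candidate removed singly, computes the removal p-value (penalized
likelihood-ratio test by default, Wald optionally), and drops the candidate
with the largest p-value if it exceeds the retention threshold ``alpha``
(default 0.157, approximating AIC-based selection).  The intercept and the
exposure are forced to stay.  Ties are broken by the lowest column index and
there is no re-entry, so the procedure is deterministic given the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import firth as _firth
from .dgm import Dataset
from .estimators import EXPOSURE_COL, build_design
from .firth import FitResult

__all__ = ["SelectionResult", "backward_eliminate", "backward_eliminate_design"]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one backward-elimination run.

    ``retained_indices`` and the trace refer to covariate indices (columns of
    ``dataset.L``), not design-matrix columns.
    """

    retained_indices: tuple[int, ...]
    elimination_trace: tuple[tuple[int, float], ...]
    final_fit: FitResult
    alpha: float

    def eliminated_indices(self) -> tuple[int, ...]:
        return tuple(j for j, _ in self.elimination_trace)

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"step": k + 1, "covariate": j, "p_value": p}
                for k, (j, p) in enumerate(self.elimination_trace)
            ]
        )


class NonConvergenceError(RuntimeError):
    """An intermediate fit failed to converge during elimination."""

    def __init__(self, step, candidate):
        self.step = step
        self.candidate = candidate
        super().__init__(
            f"fit did not converge at elimination step {step} "
            f"(dropping candidate {candidate})"
        )


def _batched_removal_pvalues(
    X, y, fit, cand_pos, tol=1e-4, max_iter=40, max_halvings=5
):
    """Penalized-LR removal p-values for every candidate in one batched Newton.

    Fits all single-coefficient-constrained models simultaneously as a
    (k, n, p) tensor iteration (warm-started at the current estimates, full
    design penalty, constraint imposed by zeroing the frozen coordinate's
    score row/column).  Numerically equivalent to the one-at-a-time profile
    fits; raises ``numpy.linalg.LinAlgError`` if any batch member's
    information loses positive definiteness, in which case the caller falls
    back to the scalar path.
    """
    from scipy.special import expit

    n, p = X.shape
    cand_pos = np.asarray(cand_pos)
    k = cand_pos.size
    rows = np.arange(k)
    beta = np.tile(fit.coefficients, (k, 1))
    beta[rows, cand_pos] = 0.0

    def core(b):
        eta = b @ X.T
        pi = expit(eta)
        w = pi * (1.0 - pi)
        Xw = X[None, :, :] * w[:, :, None]
        info = X.T @ Xw
        chol = np.linalg.cholesky(info)
        logdet = 2.0 * np.log(np.einsum("kii->ki", chol)).sum(axis=1)
        ll = eta @ y - np.logaddexp(0.0, eta).sum(axis=1)
        return ll + 0.5 * logdet, pi, w, info

    pll_out = np.empty(k)
    active = np.arange(k)  # members still iterating; converged ones retire
    pll, pi, w, info = core(beta)
    for _ in range(max_iter):
        ka = active.size
        rows_a = np.arange(ka)
        fixed = cand_pos[active]
        T = np.linalg.solve(info, np.broadcast_to(X.T, (ka, p, n)).copy())
        h = np.einsum("np,kpn->kn", X, T) * w
        resid = y[None, :] - pi + h * (0.5 - pi)
        score = resid @ X
        score[rows_a, fixed] = 0.0
        done = np.abs(score).max(axis=1) < tol
        if done.any():
            pll_out[active[done]] = pll[done]
            keep_m = ~done
            active = active[keep_m]
            if active.size == 0:
                break
            beta, score = beta[keep_m], score[keep_m]
            pll, pi, w, info = pll[keep_m], pi[keep_m], w[keep_m], info[keep_m]
            ka = active.size
            rows_a = np.arange(ka)
            fixed = cand_pos[active]
        A = info.copy()
        A[rows_a, fixed, :] = 0.0
        A[rows_a, :, fixed] = 0.0
        A[rows_a, fixed, fixed] = 1.0
        delta = np.linalg.solve(A, score[..., None])[..., 0]
        step = np.ones(ka)
        for _ in range(max_halvings + 1):
            trial = beta + step[:, None] * delta
            pll_new, pi_new, w_new, info_new = core(trial)
            worse = pll_new < pll - 1e-10
            if not worse.any():
                break
            step[worse] *= 0.5
        beta, pll, pi, w, info = trial, pll_new, pi_new, w_new, info_new
    if active.size:
        pll_out[active] = pll  # max_iter exhausted; report best available
    stat = np.maximum(0.0, 2.0 * (fit.penalized_loglik - pll_out))
    return stats.chi2.sf(stat, 1)


def _removal_pvalue(fit_full, X, y, drop_pos, method):
    """p-value for dropping design column ``drop_pos`` from the current model.

    The penalized LR test profiles the current model's penalty with the
    candidate's coefficient constrained to zero (warm-started at the current
    estimates), so the test compares likelihoods of equal dimension.
    """
    if method == "wald":
        se = np.sqrt(fit_full.covariance[drop_pos, drop_pos])
        z = fit_full.coefficients[drop_pos] / se
        return float(2.0 * stats.norm.sf(abs(z)))
    pll0, _ = _firth.constrained_pll(
        X, y, {drop_pos: 0.0}, beta_init=fit_full.coefficients
    )
    stat = max(0.0, 2.0 * (fit_full.penalized_loglik - pll0))
    return float(stats.chi2.sf(stat, 1))


def backward_eliminate_design(
    X: np.ndarray,
    y: np.ndarray,
    candidate_cols,
    *,
    alpha: float = 0.157,
    fitter: str = "flic",
    p_value_method: str = "plr",
) -> tuple[tuple[int, ...], tuple[tuple[int, float], ...], FitResult]:
    """Backward elimination on an explicit design matrix.

    ``X`` must carry the intercept in column 0 and the exposure in column 1;
    ``candidate_cols`` are the design columns eligible for removal (neither 0
    nor 1).  Returns (retained design columns, trace, final fit).
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    candidate_cols = sorted(int(c) for c in candidate_cols)
    if any(c in (0, EXPOSURE_COL) for c in candidate_cols):
        raise ValueError("intercept and exposure columns cannot be candidates")
    if fitter not in ("firth", "flic"):
        raise ValueError("fitter must be 'firth' or 'flic'")
    if p_value_method not in ("plr", "wald"):
        raise ValueError("p_value_method must be 'plr' or 'wald'")

    y = np.asarray(y, float)
    forced = [c for c in range(X.shape[1]) if c not in candidate_cols]
    remaining = list(candidate_cols)
    trace: list[tuple[int, float]] = []
    warm_full = None
    step = 0
    while True:
        step += 1
        keep = sorted(forced + remaining)
        Xc = X[:, keep]
        beta0 = None
        if warm_full is not None:
            beta0 = warm_full[keep]
        fit_c = _firth.fit_firth(Xc, y, beta_init=beta0, check_rank=(step == 1))
        if not fit_c.converged:
            raise NonConvergenceError(step, None)
        warm_full = np.zeros(X.shape[1])
        warm_full[keep] = fit_c.coefficients
        if not remaining:
            break
        # removal p-value for each remaining candidate, one at a time
        cand_local = [i for i, col in enumerate(keep) if col in remaining]
        if p_value_method == "plr" and len(cand_local) > 1:
            try:
                ps = _batched_removal_pvalues(Xc, y, fit_c, cand_local)
            except np.linalg.LinAlgError:
                ps = [
                    _removal_pvalue(fit_c, Xc, y, i, p_value_method)
                    for i in cand_local
                ]
        else:
            ps = [
                _removal_pvalue(fit_c, Xc, y, i, p_value_method)
                for i in cand_local
            ]
        pvals = [(keep[i], float(p)) for i, p in zip(cand_local, ps)]
        worst_col, worst_p = max(pvals, key=lambda t: (t[1], -t[0]))
        if worst_p <= alpha:
            break
        remaining.remove(worst_col)
        trace.append((worst_col, worst_p))

    keep = sorted(forced + remaining)
    if fitter == "flic":
        final = _firth.fit_flic(X[:, keep], y)
    else:
        final = _firth.fit_firth(X[:, keep], y, beta_init=warm_full[keep], check_rank=False)
    if not final.converged:
        raise NonConvergenceError(step, None)
    return tuple(remaining), tuple(trace), final


def backward_eliminate(
    dataset: Dataset,
    candidate_indices=None,
    alpha: float = 0.157,
    fitter: str = "flic",
    *,
    p_value_method: str = "plr",
) -> SelectionResult:
    """Backward elimination of covariates from a dataset's outcome model.

    ``candidate_indices`` are columns of ``dataset.L`` (default: all of
    them).  The exposure itself is not a covariate column and may never be a
    candidate.  Returns a :class:`SelectionResult` whose final fit keeps the
    intercept and exposure plus the retained covariates.
    """
    p = dataset.L.shape[1]
    if candidate_indices is None:
        candidate_indices = range(p)
    candidate_indices = sorted(int(j) for j in candidate_indices)
    if any(j < 0 or j >= p for j in candidate_indices):
        raise ValueError(
            "candidate indices must be covariate columns of L (the exposure "
            "is not eligible for elimination)"
        )
    X = build_design(dataset)
    design_cols = [j + 2 for j in candidate_indices]
    retained_d, trace_d, final = backward_eliminate_design(
        X, dataset.Y, design_cols, alpha=alpha, fitter=fitter,
        p_value_method=p_value_method,
    )
    return SelectionResult(
        retained_indices=tuple(c - 2 for c in retained_d),
        elimination_trace=tuple((c - 2, pv) for c, pv in trace_d),
        final_fit=final,
        alpha=alpha,
    )
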