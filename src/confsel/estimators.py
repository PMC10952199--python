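"""Causal effect estimates from a fitted outcome model.

The conditional odds ratio (cOR) is the exponentiated exposure coefficient of
the multivariable logistic model and is read off directly on the log scale.
Marginal effects are obtained by standardization (g-computation): for every
subject the fitted model predicts the outcome probability with the exposure
set to 1 and to 0, covariates held at their observed values, and the
predictions are averaged:

    log mRR = log( mean(p1) / mean(p0) )
    log mOR = logit(mean(p1)) - logit(mean(p0))
    mRD     = mean(p1) - mean(p0)

Marginal and conditional odds ratios differ even without confounding
(noncollapsibility); with covariates in the model, |log mOR| <= |log cOR|.

Estimation strategies
---------------------
``full``        FLIC fit with every candidate covariate.
``backward``    FLIC fit on the covariates retained by backward elimination.
``unadjusted``  exposure-only FLIC fit (collapsible: log cOR == log mOR).
Potential-outcome predictions always use the FLIC fit, whose corrected
intercept makes the mean fitted risk equal the observed event fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from . import firth as _firth
from .dgm import Dataset
from .firth import FitResult

__all__ = [
    "EffectEstimates",
    "conditional_log_or",
    "marginal_effects",
    "build_design",
    "fit_strategy",
    "estimate_effects",
]

#: design-matrix layout used throughout: intercept, exposure, covariates
INTERCEPT_COL = 0
EXPOSURE_COL = 1


@dataclass(frozen=True)
class EffectEstimates:
    """The four effect estimates for one dataset under one strategy."""

    log_cor: float
    log_mrr: float
    log_mor: float
    mrd: float
    strategy_tag: str
    converged: bool = True
    n_retained: int | None = None

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.log_cor, self.log_mrr, self.log_mor, self.mrd)


def build_design(dataset: Dataset, covariate_indices=None) -> np.ndarray:
    """Design matrix [1, A, L_j...] for the outcome model."""
    if covariate_indices is None:
        covariate_indices = range(dataset.L.shape[1])
    idx = list(covariate_indices)
    return np.column_stack(
        [np.ones(dataset.n), dataset.A] + [dataset.L[:, j] for j in idx]
    )


def conditional_log_or(fit: FitResult, exposure_index: int = EXPOSURE_COL) -> float:
    """Exposure coefficient on the log-odds scale (the log cOR)."""
    if exposure_index >= fit.n_params:
        raise ValueError("exposure column not present in the fitted design")
    return float(fit.coefficients[exposure_index])


def marginal_effects(
    fit: FitResult, X: np.ndarray | None = None, exposure_index: int = EXPOSURE_COL
) -> tuple[float, float, float]:
    """(log mRR, log mOR, mRD) by standardization over the fitting data.

    ``X`` defaults to the design the model was fitted on; it must have the
    exposure in column ``exposure_index``.
    """
    if X is None:
        X = fit.X
    eta_base = X @ fit.coefficients - X[:, exposure_index] * fit.coefficients[exposure_index]
    b_a = fit.coefficients[exposure_index]
    p1 = special.expit(eta_base + b_a).mean()
    p0 = special.expit(eta_base).mean()
    if p0 <= 0.0:
        raise ZeroDivisionError("mean unexposed risk is zero; risk ratio undefined")
    log_mrr = float(np.log(p1 / p0))
    log_mor = float(special.logit(p1) - special.logit(p0))
    return log_mrr, log_mor, float(p1 - p0)


def fit_strategy(
    dataset: Dataset,
    strategy: str,
    *,
    alpha: float = 0.157,
    p_value_method: str = "plr",
):
    """Fit the outcome model under one strategy; returns (FitResult, SelectionResult|None)."""
    from .selection import backward_eliminate  # local import to avoid a cycle

    if strategy == "full":
        X = build_design(dataset)
        return _firth.fit_flic(X, dataset.Y), None
    if strategy in ("unadjusted", "omit"):
        X = build_design(dataset, covariate_indices=[])
        return _firth.fit_flic(X, dataset.Y), None
    if strategy == "backward":
        sel = backward_eliminate(
            dataset, alpha=alpha, p_value_method=p_value_method
        )
        return sel.final_fit, sel
    raise ValueError(f"unknown strategy {strategy!r}")


def estimate_effects(
    dataset: Dataset,
    strategy: str = "full",
    *,
    alpha: float = 0.157,
    p_value_method: str = "plr",
) -> EffectEstimates:
    """All four effect estimates for one dataset under one strategy."""
    fit, sel = fit_strategy(
        dataset, strategy, alpha=alpha, p_value_method=p_value_method
    )
    return effects_from_fit(fit, strategy, selection=sel)


def effects_from_fit(fit: FitResult, strategy: str, selection=None) -> EffectEstimates:
    log_cor = conditional_log_or(fit)
    log_mrr, log_mor, mrd = marginal_effects(fit)
    return EffectEstimates(
        log_cor=log_cor, log_mrr=log_mrr, log_mor=log_mor, mrd=mrd,
        strategy_tag=strategy, converged=bool(fit.converged),
        n_retained=None if selection is None else len(selection.retained_indices),
    )
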