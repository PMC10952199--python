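"""Closed-form bias-variance trade-off for including versus omitting a covariate.

For a linear outcome model ``Y = theta*A + beta_LY*L + eps`` fitted by OLS,
with Cov(A, L) = rho * sd(A) * sd(L), omitting ``L`` from the regression
gives the classical omitted-variable results for the exposure-effect
estimator:

    bias_omit = beta_LY * Cov(A, L) / Var(A)
    var_full  = sigma2 / (n * Var(A) * (1 - rho^2))
    var_omit  = (sigma2 + beta_LY^2 * Var(L) * (1 - rho^2)) / (n * Var(A))

with MSE_full = var_full (the full model is unbiased) and
MSE_omit = bias_omit^2 + var_omit.  Omission is beneficial in MSE terms
exactly when

    bias_omit^2 < var_full - var_omit,                              (*)

and since both variances scale as 1/n while the bias does not, there is a
crossover sample size

    n* = (var_full(n=1) - var_omit(n=1)) / bias_omit^2

below which (*) holds.  n* grows with a stronger exposure-covariate
association, shrinks with a stronger covariate-outcome association, and (at
fixed Cov(A, L)) grows as the exposure variance falls.  When the covariate
is an instrument (beta_LY = 0, rho != 0), omitting it strictly reduces MSE
at every n and there is no crossover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "OlsTradeoffInputs",
    "ols_mse_components",
    "mse_curves",
    "crossover_n",
    "NoCrossoverError",
]


@dataclass(frozen=True)
class OlsTradeoffInputs:
    """Parameters of the one-covariate linear model.

    ``sigma2`` is the residual outcome variance; ``rho_al`` the
    exposure-covariate correlation; ``n`` the sample size (ignored by
    :func:`crossover_n`).
    """

    theta: float
    beta_ly: float
    var_a: float
    var_l: float
    rho_al: float
    sigma2: float
    n: int = 100

    def __post_init__(self):
        if self.var_a <= 0 or self.var_l <= 0 or self.sigma2 <= 0:
            raise ValueError("variances must be positive")
        if not abs(self.rho_al) < 1:
            raise ValueError("|rho_al| must be below 1")
        if self.n < 3:
            raise ValueError("n must be at least 3")


class NoCrossoverError(ValueError):
    """Omitting the covariate never (or always) beats including it."""


def ols_mse_components(inputs: OlsTradeoffInputs) -> tuple[float, float, float]:
    """(bias_omit, var_full, var_omit) of the OLS exposure-effect estimator."""
    cov_al = inputs.rho_al * math.sqrt(inputs.var_a * inputs.var_l)
    r2 = inputs.rho_al ** 2
    bias_omit = inputs.beta_ly * cov_al / inputs.var_a
    var_full = inputs.sigma2 / (inputs.n * inputs.var_a * (1.0 - r2))
    var_omit = (
        inputs.sigma2 + inputs.beta_ly ** 2 * inputs.var_l * (1.0 - r2)
    ) / (inputs.n * inputs.var_a)
    return bias_omit, var_full, var_omit


def mse_curves(inputs: OlsTradeoffInputs, n_values) -> pd.DataFrame:
    """MSE of both strategies over a range of sample sizes (re-plottable curve)."""
    rows = []
    for n in n_values:
        b, vf, vo = ols_mse_components(replace(inputs, n=int(n)))
        rows.append({"n": int(n), "mse_full": vf, "mse_omit": b * b + vo})
    return pd.DataFrame(rows)


def crossover_n(inputs: OlsTradeoffInputs) -> float:
    """Sample size below which omitting the covariate lowers the MSE.

    Solves ``bias_omit^2 = var_full(n) - var_omit(n)``; both variances are
    proportional to 1/n so the root is available in closed form.  Raises
    :class:`NoCrossoverError` when the variance difference at n = 1 is not
    positive (then omission either always or never pays, regardless of n) and
    ``ValueError`` when the omitted-variable bias vanishes.
    """
    bias, _, _ = ols_mse_components(inputs)
    if bias == 0.0:
        raise ValueError("bias_omit is zero; the crossover is not defined")
    unit = replace(inputs, n=3)
    _, vf, vo = ols_mse_components(unit)
    diff1 = (vf - vo) * unit.n  # variance difference at n = 1
    if diff1 <= 0.0:
        raise NoCrossoverError(
            "var_full does not exceed var_omit; inequality never holds"
        )
    return float(diff1 / bias ** 2)
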