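"""Bootstrap confidence intervals and selection-stability diagnostics.

After data-driven covariate selection, model-based ("selected-model")
confidence intervals condition on the chosen covariate set and ignore the
uncertainty of the selection itself, so they tend to be too narrow.  The
*global* bootstrap repeats the entire selection process inside every
resample and therefore propagates selection uncertainty; its intervals are
at least as wide in expectation when selection is unstable.

Two resampling-based diagnostics quantify what selection does to the
estimate (both compare the globally re-selected bootstrap estimates ``t_b``
with the full-model estimate ``t_full`` on the original data):

* RCB, relative conditional bias (percent):
  ``100 * (mean_b t_b - t_full) / t_full``
* RMSDR, root mean squared difference ratio:
  ``sqrt(mean_b (t_b - t_full)^2) / SE_full``,
  where ``SE_full`` is the full model's standard error of the same estimand
  (model-based Wald for the log cOR; bootstrap SD of full-model resamples
  for marginal estimands).  Values above 1 indicate selection-induced
  variance inflation.

All intervals are percentile bootstrap intervals (B = 500 resamples by
default); endpoints are order statistics of the resampled estimates and are
exactly reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dgm import Dataset
from .estimators import (
    EffectEstimates,
    build_design,
    effects_from_fit,
    estimate_effects,
)

__all__ = [
    "IntervalEstimate",
    "StabilityMeasures",
    "bootstrap_ci",
    "stability_measures",
    "TooManyDroppedResamplesError",
]

_ESTIMAND_FIELDS = ("log_cor", "log_mrr", "log_mor", "mrd")


@dataclass(frozen=True)
class IntervalEstimate:
    lower: float
    upper: float
    level: float
    method: str  # "PPL" | "wald" | "boot_full" | "boot_selected" | "boot_global"
    B: int | None = None
    n_dropped: int = 0

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class StabilityMeasures:
    rcb_percent: float
    rmsdr: float
    B: int


class TooManyDroppedResamplesError(RuntimeError):
    def __init__(self, dropped, B):
        self.dropped = dropped
        self.B = B
        super().__init__(
            f"{dropped} of {B} bootstrap resamples dropped for non-convergence "
            "(more than 10%)"
        )


def _resample(dataset: Dataset, rng) -> Dataset:
    idx = rng.integers(0, dataset.n, size=dataset.n)
    return Dataset(
        L=dataset.L[idx], A=dataset.A[idx], Y=dataset.Y[idx],
        seed_record=dataset.seed_record,
    )


def _resolve_estimand(estimand) -> tuple[str, callable]:
    """Accept a field name of EffectEstimates or a callable(Dataset, strategy)->float."""
    if callable(estimand):
        return "custom", estimand
    if estimand not in _ESTIMAND_FIELDS:
        raise ValueError(f"unknown estimand {estimand!r}")

    def fn(effects: EffectEstimates) -> float:
        return getattr(effects, estimand)

    return estimand, fn


def _bootstrap_estimates(
    dataset, extract, mode, B, seed, alpha, p_value_method, max_drop_frac=0.10
):
    """Resampled estimates under one bootstrap mode; drops non-convergent fits."""
    if mode not in ("full", "boot_global", "boot_selected"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "boot_selected":
        # selection done once, on the original data
        from .selection import backward_eliminate

        sel = backward_eliminate(dataset, alpha=alpha, p_value_method=p_value_method)
        fixed_covariates = sel.retained_indices
    vals = []
    dropped = 0
    for _ in range(B):
        ds_b = _resample(dataset, rng)
        try:
            if mode == "full":
                eff = estimate_effects(ds_b, "full")
            elif mode == "boot_global":
                eff = estimate_effects(
                    ds_b, "backward", alpha=alpha, p_value_method=p_value_method
                )
            else:
                from . import firth as _firth

                Xb = build_design(ds_b, covariate_indices=fixed_covariates)
                fit = _firth.fit_flic(Xb, ds_b.Y)
                eff = effects_from_fit(fit, "backward")
        except (RuntimeError, np.linalg.LinAlgError, ZeroDivisionError):
            dropped += 1
            continue
        if not eff.converged:
            dropped += 1
            continue
        vals.append(extract(eff))
    if dropped > max_drop_frac * B:
        raise TooManyDroppedResamplesError(dropped, B)
    return np.asarray(vals), dropped


def bootstrap_ci(
    dataset: Dataset,
    estimand="log_cor",
    mode: str = "full",
    B: int = 500,
    level: float = 0.95,
    seed: int = 0,
    *,
    alpha: float = 0.157,
    p_value_method: str = "plr",
) -> IntervalEstimate:
    """Percentile bootstrap confidence interval for one estimand.

    ``mode`` selects what is refitted in each of the ``B`` row-resamples:
    ``full`` refits the full model; ``boot_selected`` refits the covariate
    set selected once on the original data; ``boot_global`` reruns backward
    elimination inside every resample.  Endpoints are the empirical
    (1-level)/2 and 1-(1-level)/2 quantiles of the resampled estimates.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    _, fn = _resolve_estimand(estimand)
    vals, dropped = _bootstrap_estimates(
        dataset, fn, mode, B, seed, alpha, p_value_method
    )
    lo, hi = np.quantile(vals, [(1 - level) / 2.0, 1 - (1 - level) / 2.0])
    return IntervalEstimate(
        lower=float(lo), upper=float(hi), level=level,
        method={"full": "boot_full"}.get(mode, mode), B=B, n_dropped=dropped,
    )


def stability_measures(
    dataset: Dataset,
    B: int = 500,
    seed: int = 0,
    *,
    estimand: str = "log_cor",
    alpha: float = 0.157,
    p_value_method: str = "plr",
    se_full: str = "auto",
) -> StabilityMeasures:
    """RCB and RMSDR of backward elimination relative to the full model.

    ``se_full`` chooses the RMSDR denominator: ``"model"`` uses the full
    model's Wald standard error (only available for the log cOR),
    ``"bootstrap"`` the SD of full-model estimates over the same resamples,
    ``"auto"`` picks model-based for the log cOR and bootstrap otherwise.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    name, fn = _resolve_estimand(estimand)
    full_fit, _ = _fit_full(dataset)
    t_full = fn(effects_from_fit(full_fit, "full"))
    if t_full == 0.0:
        raise ZeroDivisionError("full-model estimate is zero; RCB undefined")
    t_b, _ = _bootstrap_estimates(
        dataset, fn, "boot_global", B, seed, alpha, p_value_method
    )
    rcb = 100.0 * (t_b.mean() - t_full) / t_full
    if se_full == "auto":
        se_full = "model" if name == "log_cor" else "bootstrap"
    if se_full == "model":
        from .estimators import EXPOSURE_COL

        se = float(np.sqrt(full_fit.covariance[EXPOSURE_COL, EXPOSURE_COL]))
    elif se_full == "bootstrap":
        full_b, _ = _bootstrap_estimates(
            dataset, fn, "full", B, seed, alpha, p_value_method
        )
        se = float(full_b.std(ddof=1))
    else:
        raise ValueError("se_full must be 'auto', 'model' or 'bootstrap'")
    rmsdr = float(np.sqrt(np.mean((t_b - t_full) ** 2)) / se)
    return StabilityMeasures(rcb_percent=float(rcb), rmsdr=rmsdr, B=B)


def _fit_full(dataset: Dataset):
    from . import firth as _firth

    X = build_design(dataset)
    fit = _firth.fit_flic(X, dataset.Y)
    return fit, X


def interval_summary_frame(rows) -> "pandas.DataFrame":
    """Tabulate (estimand, model, estimate, IntervalEstimate) tuples CI-table style."""
    import pandas as pd

    recs = []
    for estimand, model, estimate, interval in rows:
        recs.append(
            {
                "estimand": estimand,
                "model": model,
                "estimate": estimate,
                "method": interval.method,
                "lower": interval.lower,
                "upper": interval.upper,
                "width": interval.width,
            }
        )
    return pd.DataFrame(recs)
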