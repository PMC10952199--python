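"""Data-generating mechanisms for the two simulation experiments.

Both experiments draw continuous covariates ``L``, a binary exposure
``A ~ Bernoulli(expit(alpha0 + beta_LA . L))`` and a binary outcome
``Y ~ Bernoulli(expit(gamma0 + theta * A + beta_LY . L))``, so ``theta`` is
the conditional log odds ratio of the exposure by construction.

Experiment 1 (proof of concept): a single standard-normal covariate, null
exposure effect, n in {60, 120}, event fraction in {0.5, 0.2}, and
covariate-exposure / covariate-outcome log-odds associations on a six-point
grid spanning [0, 0.5] - 144 scenarios in total.

Experiment 2 (realistic): 24 covariates, multivariate normal with unit
variances and pairwise correlation 0.3.  Twelve covariates are fixed weak
confounders at (log 1.05, log 1.05); the other twelve form four exchangeable
sets of three, each set assigned one (beta_LA, beta_LY) pair from
{0, log 1.05, log 1.2}^2 - a mixture of true confounders, (near-)
instruments, (near-)predictors of the outcome and noise.  Crossing the 495
distinct mixture assignments with theta in {0, log 1.5}, expected events in
{50, 200} and event fraction in {0.2, 0.03} gives 3960 scenarios with
n in {250, 1000, 1667, 6667}.

Intercepts are calibrated by monotone root-finding so that the expected
exposure prevalence and the expected (marginal) event fraction hit their
targets; expectations are taken over a frozen-seed Monte-Carlo sample of the
covariate linear predictors, which are jointly normal, so only the two
scalar projections ``beta_LA . L`` and ``beta_LY . L`` need to be drawn.
True marginal estimands are obtained by a large-sample approximation
(default N = 1,000,000).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "CovariateEffect",
    "ScenarioExp1",
    "ScenarioExp2",
    "Dataset",
    "TrueEffects",
    "LOG105",
    "LOG12",
    "MIXTURE_LEVELS",
    "EXP1_GRID",
    "enumerate_scenarios_exp1",
    "enumerate_scenarios_exp2",
    "calibrate_intercepts",
    "calibrated",
    "generate_dataset",
    "true_marginal_effects",
    "scenarios_to_frame",
    "scenarios_from_frame",
    "dataset_to_frame",
]

LOG105 = math.log(1.05)
LOG12 = math.log(1.2)
#: association levels used for the Experiment-2 mixture sets
MIXTURE_LEVELS = (0.0, LOG105, LOG12)
#: Experiment-1 grid: six equally spaced log-odds associations on [0, 0.5]
EXP1_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)

#: frozen seed for the calibration Monte-Carlo sample (reproducibility of
#: intercepts across runs and processes)
CALIBRATION_SEED = 202212


@dataclass(frozen=True)
class CovariateEffect:
    """Covariate-exposure and covariate-outcome log-odds associations."""

    beta_la: float
    beta_ly: float

    @property
    def role_label(self) -> str:
        if self.beta_la == 0.0 and self.beta_ly == 0.0:
            return "noise"
        if self.beta_la > 0.0 and self.beta_ly == 0.0:
            return "instrument-class"
        if self.beta_la == 0.0 and self.beta_ly > 0.0:
            return "predictor-class"
        return "confounder"


@dataclass(frozen=True)
class ScenarioExp1:
    """One Experiment-1 configuration: a single covariate, null exposure effect."""

    scenario_id: int
    beta_la: float
    beta_ly: float
    n: int
    event_fraction: float
    theta: float = 0.0
    alpha0: float | None = None
    gamma0: float | None = None

    experiment: int = 1
    rho: float = 0.0

    @property
    def beta_la_vector(self) -> np.ndarray:
        return np.array([self.beta_la])

    @property
    def beta_ly_vector(self) -> np.ndarray:
        return np.array([self.beta_ly])

    @property
    def n_covariates(self) -> int:
        return 1


@dataclass(frozen=True)
class ScenarioExp2:
    """One Experiment-2 configuration: 24 correlated covariates."""

    scenario_id: int
    theta: float
    covariates: tuple[CovariateEffect, ...]
    expected_events: int
    event_fraction: float
    rho: float = 0.3
    alpha0: float | None = None
    gamma0: float | None = None

    experiment: int = 2

    def __post_init__(self):
        if len(self.covariates) != 24:
            raise ValueError("Experiment-2 scenarios carry exactly 24 covariates")

    @property
    def n(self) -> int:
        return round(self.expected_events / self.event_fraction)

    @property
    def beta_la_vector(self) -> np.ndarray:
        return np.array([c.beta_la for c in self.covariates])

    @property
    def beta_ly_vector(self) -> np.ndarray:
        return np.array([c.beta_ly for c in self.covariates])

    @property
    def n_covariates(self) -> int:
        return 24

    def role_counts(self) -> dict[str, int]:
        out = {"confounder": 0, "instrument-class": 0, "predictor-class": 0, "noise": 0}
        for c in self.covariates:
            out[c.role_label] += 1
        return out

    def composition_class(self) -> str:
        """Table-style DGM composition: instruments / noise / neither.

        ``>=3 instruments`` counts full instrumental variables (associated
        with the exposure only); ``>=3 noise`` counts pure noise covariates;
        a scenario can fall in both; ``neither`` means fewer than three of
        each.
        """
        rc = self.role_counts()
        labels = []
        if rc["instrument-class"] >= 3:
            labels.append("instruments")
        if rc["noise"] >= 3:
            labels.append("noise")
        return "+".join(labels) if labels else "neither"

    def true_confounder_indices(self) -> list[int]:
        return [j for j, c in enumerate(self.covariates) if c.role_label == "confounder"]


@dataclass(frozen=True)
class Dataset:
    """One simulated replicate: covariates, exposure, outcome."""

    L: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    seed_record: tuple

    def __post_init__(self):
        n = self.L.shape[0]
        if not (self.A.shape == (n,) and self.Y.shape == (n,)):
            raise ValueError("L, A, Y row counts must align")

    @property
    def n(self) -> int:
        return self.L.shape[0]


@dataclass(frozen=True)
class TrueEffects:
    """Large-sample values of the four estimands for one scenario."""

    log_cor: float
    log_mrr: float
    log_mor: float
    mrd: float
    approx_n: int


def enumerate_scenarios_exp1() -> list[ScenarioExp1]:
    """All 144 Experiment-1 scenarios in a deterministic, stable order.

    Order: n (60, 120) x event fraction (0.5, 0.2) x beta_LA x beta_LY, each
    association running over the six-point grid.
    """
    out = []
    sid = 0
    for n in (60, 120):
        for ef in (0.5, 0.2):
            for bla in EXP1_GRID:
                for bly in EXP1_GRID:
                    out.append(
                        ScenarioExp1(
                            scenario_id=sid, beta_la=bla, beta_ly=bly,
                            n=n, event_fraction=ef,
                        )
                    )
                    sid += 1
    return out


def _mixture_assignments() -> list[tuple[tuple[float, float], ...]]:
    """The 495 order-canonical multisets of four (beta_LA, beta_LY) pairs."""
    pairs = sorted(itertools.product(MIXTURE_LEVELS, MIXTURE_LEVELS))
    return list(itertools.combinations_with_replacement(pairs, 4))


def enumerate_scenarios_exp2() -> list[ScenarioExp2]:
    """All 3960 Experiment-2 scenarios in a deterministic, stable order.

    The four mixture sets are exchangeable, so assignments are enumerated as
    sorted multisets (495 of them) and crossed with theta x expected events x
    event fraction (8 arms).
    """
    assignments = _mixture_assignments()
    fixed = tuple(CovariateEffect(LOG105, LOG105) for _ in range(12))
    out = []
    sid = 0
    for theta in (0.0, math.log(1.5)):
        for events in (50, 200):
            for ef in (0.2, 0.03):
                for assign in assignments:
                    mixture = tuple(
                        CovariateEffect(bla, bly)
                        for (bla, bly) in assign
                        for _ in range(3)
                    )
                    out.append(
                        ScenarioExp2(
                            scenario_id=sid, theta=theta,
                            covariates=fixed + mixture,
                            expected_events=events, event_fraction=ef,
                        )
                    )
                    sid += 1
    return out


def _projection_moments(scenario) -> tuple[float, float, float]:
    """(var of beta_LA.L, var of beta_LY.L, their covariance) under the scenario's Sigma."""
    ba = scenario.beta_la_vector
    by = scenario.beta_ly_vector
    rho = scenario.rho
    va = (1 - rho) * float(ba @ ba) + rho * float(ba.sum()) ** 2
    vy = (1 - rho) * float(by @ by) + rho * float(by.sum()) ** 2
    c = (1 - rho) * float(ba @ by) + rho * float(ba.sum()) * float(by.sum())
    return va, vy, c


def _draw_projections(scenario, size, rng) -> tuple[np.ndarray, np.ndarray]:
    """Joint draws of (beta_LA . L, beta_LY . L); exact, since L is Gaussian."""
    va, vy, c = _projection_moments(scenario)
    z1 = rng.standard_normal(size)
    z2 = rng.standard_normal(size)
    sa = math.sqrt(va)
    ta = sa * z1
    if sa > 0:
        b = c / sa
        resid = vy - b * b
        ty = b * z1 + math.sqrt(max(resid, 0.0)) * z2
    else:
        ty = math.sqrt(vy) * z2
    return ta, ty


class CalibrationError(RuntimeError):
    def __init__(self, which, bracket):
        self.which = which
        self.bracket = bracket
        super().__init__(
            f"intercept calibration for {which} did not converge within bracket {bracket}"
        )


def calibrate_intercepts(
    scenario,
    target_exposure_prevalence: float = 0.5,
    tol: float = 1e-4,
    *,
    n_mc: int = 1_000_000,
    seed: int = CALIBRATION_SEED,
) -> tuple[float, float]:
    """Solve for (alpha0, gamma0) hitting the exposure-prevalence and event-fraction targets.

    Both maps intercept -> expected probability are strictly increasing, so
    each intercept is found by Brent root-finding on a frozen-seed Monte-Carlo
    sample of the covariate linear predictors.  The event-fraction target is
    marginal over the exposure distribution induced by ``alpha0``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    rng = np.random.default_rng(seed)
    ta, ty = _draw_projections(scenario, n_mc, rng)
    bracket = (-30.0, 30.0)

    def f_alpha(a):
        return special.expit(a + ta).mean() - target_exposure_prevalence

    if not (f_alpha(bracket[0]) < 0 < f_alpha(bracket[1])):
        raise CalibrationError("alpha0", bracket)
    alpha0 = optimize.brentq(f_alpha, *bracket, xtol=min(tol, 1e-6))

    p_a = special.expit(alpha0 + ta)
    theta = scenario.theta

    def f_gamma(g):
        py = p_a * special.expit(g + theta + ty) + (1.0 - p_a) * special.expit(g + ty)
        return py.mean() - scenario.event_fraction

    if not (f_gamma(bracket[0]) < 0 < f_gamma(bracket[1])):
        raise CalibrationError("gamma0", bracket)
    gamma0 = optimize.brentq(f_gamma, *bracket, xtol=min(tol, 1e-6))
    return float(alpha0), float(gamma0)


def calibrated(scenario, target_exposure_prevalence: float = 0.5, **kwargs):
    """Return a copy of ``scenario`` with calibrated intercepts filled in."""
    a0, g0 = calibrate_intercepts(scenario, target_exposure_prevalence, **kwargs)
    return replace(scenario, alpha0=a0, gamma0=g0)


def generate_dataset(scenario, seed) -> Dataset:
    """Draw one replicate dataset; reproducible given (scenario_id, seed).

    ``seed`` may be an int or a tuple of ints (e.g. (root_seed, replicate)).
    """
    if scenario.alpha0 is None or scenario.gamma0 is None:
        raise ValueError("scenario must be calibrated before data generation")
    seed_tuple = tuple(seed) if isinstance(seed, (tuple, list)) else (int(seed),)
    ss = np.random.SeedSequence(list(seed_tuple) + [scenario.scenario_id])
    rng = np.random.default_rng(ss)
    n, p, rho = scenario.n, scenario.n_covariates, scenario.rho
    if p > 1 and rho > 0:
        # one-factor representation of the equicorrelation matrix
        z0 = rng.standard_normal(n)
        Z = rng.standard_normal((n, p))
        L = math.sqrt(rho) * z0[:, None] + math.sqrt(1.0 - rho) * Z
    else:
        L = rng.standard_normal((n, p))
    p_a = special.expit(scenario.alpha0 + L @ scenario.beta_la_vector)
    A = (rng.random(n) < p_a).astype(float)
    p_y = special.expit(
        scenario.gamma0 + scenario.theta * A + L @ scenario.beta_ly_vector
    )
    Y = (rng.random(n) < p_y).astype(float)
    return Dataset(L=L, A=A, Y=Y, seed_record=seed_tuple)


def true_marginal_effects(
    scenario, approx_N: int = 1_000_000, seed: int = CALIBRATION_SEED + 1
) -> TrueEffects:
    """True marginal estimands by large-sample approximation.

    Averages the potential-outcome probabilities under exposure-for-all and
    exposure-for-none over ``approx_N`` covariate draws.  When ``theta`` is
    exactly zero the two probabilities coincide rowwise and all marginal
    effects are exactly null.
    """
    if scenario.gamma0 is None:
        raise ValueError("scenario must be calibrated first")
    theta = scenario.theta
    if theta == 0.0:
        return TrueEffects(0.0, 0.0, 0.0, 0.0, approx_N)
    rng = np.random.default_rng(seed)
    _, ty = _draw_projections(scenario, approx_N, rng)
    p1 = special.expit(scenario.gamma0 + theta + ty).mean()
    p0 = special.expit(scenario.gamma0 + ty).mean()
    log_mrr = math.log(p1 / p0)
    log_mor = math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))
    return TrueEffects(
        log_cor=theta, log_mrr=float(log_mrr), log_mor=float(log_mor),
        mrd=float(p1 - p0), approx_n=approx_N,
    )


# ---------------------------------------------------------------------------
# CSV round-tripping of scenario grids (debugging / external runs)


def scenarios_to_frame(scenarios) -> pd.DataFrame:
    rows = []
    for s in scenarios:
        row = {
            "scenario_id": s.scenario_id,
            "experiment": s.experiment,
            "theta": s.theta,
            "event_fraction": s.event_fraction,
            "n": s.n,
            "alpha0": s.alpha0,
            "gamma0": s.gamma0,
        }
        if s.experiment == 2:
            row["expected_events"] = s.expected_events
        ba, by = s.beta_la_vector, s.beta_ly_vector
        for j in range(len(ba)):
            row[f"beta_la_{j + 1}"] = ba[j]
            row[f"beta_ly_{j + 1}"] = by[j]
        rows.append(row)
    return pd.DataFrame(rows)


def scenarios_from_frame(frame: pd.DataFrame):
    out = []
    for _, row in frame.iterrows():
        exp = int(row["experiment"])
        a0 = None if pd.isna(row["alpha0"]) else float(row["alpha0"])
        g0 = None if pd.isna(row["gamma0"]) else float(row["gamma0"])
        if exp == 1:
            out.append(
                ScenarioExp1(
                    scenario_id=int(row["scenario_id"]),
                    beta_la=float(row["beta_la_1"]), beta_ly=float(row["beta_ly_1"]),
                    n=int(row["n"]), event_fraction=float(row["event_fraction"]),
                    theta=float(row["theta"]), alpha0=a0, gamma0=g0,
                )
            )
        else:
            cov = tuple(
                CovariateEffect(float(row[f"beta_la_{j + 1}"]), float(row[f"beta_ly_{j + 1}"]))
                for j in range(24)
            )
            out.append(
                ScenarioExp2(
                    scenario_id=int(row["scenario_id"]), theta=float(row["theta"]),
                    covariates=cov, expected_events=int(row["expected_events"]),
                    event_fraction=float(row["event_fraction"]), alpha0=a0, gamma0=g0,
                )
            )
    return out


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    cols = {"Y": dataset.Y, "A": dataset.A}
    for j in range(dataset.L.shape[1]):
        cols[f"L{j + 1}"] = dataset.L[:, j]
    return pd.DataFrame(cols)
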