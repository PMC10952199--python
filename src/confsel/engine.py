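"""Monte-Carlo orchestration: replicates, performance measures, aggregation.

For each scenario the engine generates replicate datasets, applies the
requested estimation strategies (full model, backward elimination,
unadjusted), and summarizes each strategy x estimand cell by Monte-Carlo
bias, variance and MSE against the scenario's true effect values (the
conditional log OR equals ``theta`` by construction; marginal truths come
from the large-sample approximation).  Relative efficiency is
MSE(backward) / MSE(full) — values above 1 favor the full model.

Replicate seed streams are derived deterministically from
``(root_seed, replicate, scenario_id)``, so per-scenario results do not
depend on execution order or worker scheduling, and a partially completed
grid can be resumed with bitwise-identical output for finished scenarios.

The bias-variance inequality
----------------------------
Omitting covariates pays in MSE terms exactly when

    bias_omit^2 < var_full - var_omit,

the same criterion the closed-form linear analysis (:mod:`confsel.theory`)
yields.  :func:`inequality_check` evaluates it from Monte-Carlo performance
of a strategy pair; :func:`run_experiment1` applies it to the single-
covariate proof-of-concept grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import dgm, firth as _firth
from .estimators import (
    EXPOSURE_COL,
    build_design,
    effects_from_fit,
    fit_strategy,
)

__all__ = [
    "ScenarioPerformance",
    "run_scenario",
    "inequality_check",
    "run_experiment1",
    "experiment1_inequality_proportions",
    "run_grid",
    "results_to_frame",
    "aggregate",
]

ESTIMANDS = ("log_cor", "log_mrr", "log_mor", "mrd")
STRATEGIES = ("full", "backward", "unadjusted")


@dataclass
class ScenarioPerformance:
    """Monte-Carlo performance of every strategy x estimand cell for one scenario.

    ``stats[(strategy, estimand)]`` holds ``bias``, ``variance`` (n-1
    denominator), ``mse`` (mean squared deviation from the truth) and
    ``n_eff`` (converged replicates).  With that convention
    ``mse == bias**2 + variance * (n_eff - 1) / n_eff`` exactly, because all
    three are computed from the same replicate vector.
    """

    scenario_id: int
    n: int
    theta: float
    event_fraction: float
    expected_events: int | None
    composition: str | None
    truths: dict
    stats: dict
    n_nonconverged: dict
    n_reps: int
    mean_eliminated_confounders: float | None = None
    coverage: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def relative_efficiency(self, estimand: str, pair=("backward", "full")) -> float:
        num = self.stats[(pair[0], estimand)]["mse"]
        den = self.stats[(pair[1], estimand)]["mse"]
        return num / den


def _summarize(values: np.ndarray, truth: float) -> dict:
    m = values.size
    bias = float(values.mean() - truth)
    var = float(values.var(ddof=1)) if m > 1 else 0.0
    mse = float(np.mean((values - truth) ** 2))
    return {"bias": bias, "variance": var, "mse": mse, "n_eff": int(m)}


def run_scenario(
    scenario,
    n_reps: int,
    strategies=("full", "backward", "unadjusted"),
    root_seed: int = 0,
    *,
    alpha: float = 0.157,
    p_value_method: str = "plr",
    true_effects: dgm.TrueEffects | None = None,
    replicate_seeds=None,
    coverage_methods=(),
    coverage_level: float = 0.95,
    coverage_boot_B: int = 200,
) -> ScenarioPerformance:
    """Monte-Carlo evaluation of one calibrated scenario.

    Non-convergent replicates are dropped from the affected strategy's cells
    and counted.  ``coverage_methods`` may contain ``"wald"`` and ``"ppl"``
    (intervals for the log cOR) and ``"boot_mrr"`` (percentile bootstrap for
    the log mRR); coverage is evaluated for the full-model strategy.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    if scenario.alpha0 is None:
        raise ValueError("scenario must be calibrated (see dgm.calibrated)")
    if true_effects is None:
        true_effects = dgm.true_marginal_effects(scenario)
    truth = {
        "log_cor": scenario.theta,
        "log_mrr": true_effects.log_mrr,
        "log_mor": true_effects.log_mor,
        "mrd": true_effects.mrd,
    }
    estimates = {s: [] for s in strategies}
    nonconv = {s: 0 for s in strategies}
    elim_counts = []
    covered = {m: 0 for m in coverage_methods}
    cov_n = {m: 0 for m in coverage_methods}
    confounders = (
        set(scenario.true_confounder_indices())
        if hasattr(scenario, "true_confounder_indices")
        else set()
    )
    if replicate_seeds is None:
        replicate_seeds = [(root_seed, r) for r in range(n_reps)]
    z = _stats.norm.ppf(0.5 + coverage_level / 2.0)
    for seed in replicate_seeds:
        ds = dgm.generate_dataset(scenario, seed)
        for s in strategies:
            try:
                fit, sel = fit_strategy(
                    ds, s, alpha=alpha, p_value_method=p_value_method
                )
                eff = effects_from_fit(fit, s, selection=sel)
            except (RuntimeError, np.linalg.LinAlgError, ZeroDivisionError):
                nonconv[s] += 1
                continue
            if not eff.converged:
                nonconv[s] += 1
                continue
            estimates[s].append(eff.as_tuple())
            if s == "backward" and sel is not None and confounders:
                elim_counts.append(
                    len(confounders.intersection(sel.eliminated_indices()))
                )
            if s == "full" and coverage_methods:
                _tally_coverage(
                    fit, ds, truth, coverage_methods, covered, cov_n,
                    z, coverage_level, coverage_boot_B, seed,
                )
    stats_out = {}
    for s in strategies:
        vals = np.asarray(estimates[s])
        if vals.size == 0:
            raise RuntimeError(
                f"all {n_reps} replicates non-convergent for strategy {s!r}"
            )
        for k, est_name in enumerate(ESTIMANDS):
            stats_out[(s, est_name)] = _summarize(vals[:, k], truth[est_name])
    coverage = {
        m: (covered[m] / cov_n[m] if cov_n[m] else float("nan"))
        for m in coverage_methods
    }
    return ScenarioPerformance(
        scenario_id=scenario.scenario_id,
        n=scenario.n,
        theta=scenario.theta,
        event_fraction=scenario.event_fraction,
        expected_events=getattr(scenario, "expected_events", None),
        composition=(
            scenario.composition_class()
            if hasattr(scenario, "composition_class")
            else None
        ),
        truths=truth,
        stats=stats_out,
        n_nonconverged=nonconv,
        n_reps=len(replicate_seeds),
        mean_eliminated_confounders=(
            float(np.mean(elim_counts)) if elim_counts else None
        ),
        coverage=coverage,
        extra=_scenario_extra(scenario),
    )


def _scenario_extra(scenario) -> dict:
    if getattr(scenario, "experiment", None) == 1:
        return {"beta_la": scenario.beta_la, "beta_ly": scenario.beta_ly}
    return {}


def _tally_coverage(fit, ds, truth, methods, covered, cov_n, z, level, B, seed):
    from .inference import bootstrap_ci

    if "wald" in methods:
        se = math.sqrt(fit.covariance[EXPOSURE_COL, EXPOSURE_COL])
        b = fit.coefficients[EXPOSURE_COL]
        cov_n["wald"] += 1
        if b - z * se <= truth["log_cor"] <= b + z * se:
            covered["wald"] += 1
    if "ppl" in methods:
        try:
            base = _firth.fit_firth(fit.X, fit.y)
            lo, hi = _firth.profile_penalized_likelihood_ci(
                fit.X, fit.y, EXPOSURE_COL, level, fit=base
            )
        except (RuntimeError, np.linalg.LinAlgError):
            return
        cov_n["ppl"] += 1
        if lo <= truth["log_cor"] <= hi:
            covered["ppl"] += 1
    if "boot_mrr" in methods:
        boot_seed = int(np.random.SeedSequence(list(seed) + [7]).generate_state(1)[0] % (2**31))
        try:
            ci = bootstrap_ci(ds, "log_mrr", mode="full", B=B, level=level, seed=boot_seed)
        except RuntimeError:
            return
        cov_n["boot_mrr"] += 1
        if ci.lower <= truth["log_mrr"] <= ci.upper:
            covered["boot_mrr"] += 1


def inequality_check(
    perf: ScenarioPerformance,
    estimand: str = "log_cor",
    strategy_pair=("full", "unadjusted"),
) -> bool:
    """True iff bias_omit^2 < var_full - var_omit for the requested estimand."""
    keep, omit = strategy_pair
    bias_omit = perf.stats[(omit, estimand)]["bias"]
    var_full = perf.stats[(keep, estimand)]["variance"]
    var_omit = perf.stats[(omit, estimand)]["variance"]
    return bool(bias_omit**2 < var_full - var_omit)


def _batched_firth_flic(Xb, yb, tol=1e-6, max_iter=60, max_halvings=5):
    """Firth fits with FLIC intercepts for a stack of same-shape datasets.

    ``Xb`` is (B, n, p) with the intercept in column 0, ``yb`` is (B, n).
    Returns (coefficients (B, p) with FLIC intercept, converged (B,) bool).
    Numerically equivalent to fitting each replicate with
    :func:`confsel.firth.fit_flic`; used by the single-covariate experiment
    where hundreds of tiny fits per scenario would otherwise be dominated by
    per-call overhead.
    """
    from scipy.special import expit

    B, n, p = Xb.shape
    XbT = np.ascontiguousarray(np.transpose(Xb, (0, 2, 1)))

    def core(idx, beta):
        X = Xb[idx]
        eta = np.einsum("bnp,bp->bn", X, beta)
        pi = expit(eta)
        w = pi * (1.0 - pi)
        info = XbT[idx] @ (X * w[:, :, None])
        chol = np.linalg.cholesky(info)
        logdet = 2.0 * np.log(np.einsum("bii->bi", chol)).sum(axis=1)
        ll = np.einsum("bn,bn->b", yb[idx], eta) - np.logaddexp(0.0, eta).sum(axis=1)
        return ll + 0.5 * logdet, pi, w, info

    beta_out = np.zeros((B, p))
    conv = np.zeros(B, dtype=bool)
    active = np.arange(B)
    beta = np.zeros((B, p))
    pll, pi, w, info = core(active, beta)
    for _ in range(max_iter):
        X = Xb[active]
        T = np.linalg.solve(info, XbT[active])
        h = np.einsum("bnp,bpn->bn", X, T) * w
        resid = yb[active] - pi + h * (0.5 - pi)
        score = np.einsum("bnp,bn->bp", X, resid)
        done = np.abs(score).max(axis=1) < tol
        if done.any():
            beta_out[active[done]] = beta[done]
            conv[active[done]] = True
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            beta, score = beta[keep], score[keep]
            pll, pi, w, info = pll[keep], pi[keep], w[keep], info[keep]
        delta = np.linalg.solve(info, score[..., None])[..., 0]
        step = np.ones(active.size)
        for _ in range(max_halvings + 1):
            trial = beta + step[:, None] * delta
            pll_new, pi_new, w_new, info_new = core(active, trial)
            worse = pll_new < pll - 1e-10
            if not worse.any():
                break
            step[worse] *= 0.5
        beta, pll, pi, w, info = trial, pll_new, pi_new, w_new, info_new
    if active.size:
        beta_out[active] = beta  # unconverged; flagged via `conv`

    # FLIC intercept: plain-ML 1-D Newton per replicate with slope offset
    offset = np.einsum("bnp,bp->bn", Xb[:, :, 1:], beta_out[:, 1:])
    b0 = beta_out[:, 0].copy()
    ybar_tot = yb.sum(axis=1)
    flic_ok = np.zeros(B, dtype=bool)
    for _ in range(60):
        pi0 = expit(b0[:, None] + offset)
        g = ybar_tot - pi0.sum(axis=1)
        flic_ok = np.abs(g) < 1e-8 * n
        if flic_ok.all():
            break
        wsum = (pi0 * (1.0 - pi0)).sum(axis=1)
        upd = ~flic_ok
        b0[upd] += g[upd] / wsum[upd]
    beta_out[:, 0] = b0
    return beta_out, conv & flic_ok


def _experiment1_estimates(scenario, n_reps, root_seed):
    """(B, 2) arrays of (log cOR, log mRR) for the full and omit strategies."""
    datasets = [
        dgm.generate_dataset(scenario, (root_seed, r)) for r in range(n_reps)
    ]
    n = scenario.n
    A = np.stack([d.A for d in datasets])
    Y = np.stack([d.Y for d in datasets])
    L = np.stack([d.L[:, 0] for d in datasets])
    ones = np.ones((n_reps, n))
    out = {}
    for tag, Xb in (
        ("full", np.stack([ones, A, L], axis=2)),
        ("unadjusted", np.stack([ones, A], axis=2)),
    ):
        beta, conv = _batched_firth_flic(Xb, Y)
        eta_base = np.einsum("bnp,bp->bn", Xb, beta) - beta[:, 1][:, None] * A
        from scipy.special import expit as _expit

        p1 = _expit(eta_base + beta[:, 1][:, None]).mean(axis=1)
        p0 = _expit(eta_base).mean(axis=1)
        log_mrr = np.log(p1 / p0)
        out[tag] = {
            "log_cor": beta[:, 1],
            "log_mrr": log_mrr,
            "converged": conv,
        }
    return out


def run_experiment1(
    scenarios=None,
    n_reps: int = 500,
    root_seed: int = 0,
    *,
    calib_n_mc: int = 1_000_000,
    batched: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Single-covariate experiment: include-vs-omit inequality per scenario.

    Runs the ``full`` (adjusting for L) and ``unadjusted`` (omitting L)
    strategies on every scenario and records whether the squared omit-bias is
    below the variance difference for the conditional log OR and the marginal
    log RR.  Returns one row per scenario.
    """
    if scenarios is None:
        scenarios = dgm.enumerate_scenarios_exp1()
    rows = []
    for i, sc in enumerate(scenarios):
        if sc.alpha0 is None:
            sc = dgm.calibrated(sc, n_mc=calib_n_mc)
        if batched:
            cells = {}
            ests = _experiment1_estimates(sc, n_reps, root_seed)
            for strat in ("full", "unadjusted"):
                ok = ests[strat]["converged"]
                for est in ("log_cor", "log_mrr"):
                    cells[(strat, est)] = _summarize(
                        ests[strat][est][ok], 0.0  # theta = 0 throughout
                    )
        else:
            perf = run_scenario(
                sc, n_reps, strategies=("full", "unadjusted"), root_seed=root_seed
            )
            cells = perf.stats
        row = {
            "scenario_id": sc.scenario_id,
            "n": sc.n,
            "event_fraction": sc.event_fraction,
            "beta_la": sc.beta_la,
            "beta_ly": sc.beta_ly,
        }
        for est in ("log_cor", "log_mrr"):
            bias_o = cells[("unadjusted", est)]["bias"]
            var_f = cells[("full", est)]["variance"]
            var_o = cells[("unadjusted", est)]["variance"]
            m = cells[("unadjusted", est)]["n_eff"]
            # debiased squared-bias estimate: E[mean^2] = bias^2 + var / reps
            row[f"holds_{est}"] = bool(bias_o**2 - var_o / m < var_f - var_o)
            tag_cells = (("full", "full"), ("unadjusted", "omit"))
            for strat, tag in tag_cells:
                row[f"bias_{tag}_{est}"] = cells[(strat, est)]["bias"]
                row[f"var_{tag}_{est}"] = cells[(strat, est)]["variance"]
        rows.append(row)
        if progress and (i + 1) % 12 == 0:
            print(f"  experiment 1: {i + 1}/{len(scenarios)} scenarios done")
    return pd.DataFrame(rows)


def experiment1_inequality_proportions(frame: pd.DataFrame) -> dict:
    """Percentage of scenarios in which the inequality holds, per estimand."""
    return {
        "log_cor": 100.0 * frame["holds_log_cor"].mean(),
        "log_mrr": 100.0 * frame["holds_log_mrr"].mean(),
    }


# ---------------------------------------------------------------------------
# grid running, persistence, aggregation


def results_to_frame(results) -> pd.DataFrame:
    """One row per scenario x strategy x estimand."""
    rows = []
    for perf in results:
        for (strategy, estimand), cell in perf.stats.items():
            rows.append(
                {
                    "scenario_id": perf.scenario_id,
                    "n": perf.n,
                    "theta": perf.theta,
                    "event_fraction": perf.event_fraction,
                    "expected_events": perf.expected_events,
                    "composition": perf.composition,
                    "strategy": strategy,
                    "estimand": estimand,
                    "truth": perf.truths[estimand],
                    "bias": cell["bias"],
                    "variance": cell["variance"],
                    "mse": cell["mse"],
                    "n_eff": cell["n_eff"],
                    "n_nonconverged": perf.n_nonconverged[strategy],
                    "mean_eliminated_confounders": perf.mean_eliminated_confounders,
                }
            )
    return pd.DataFrame(rows)


def run_grid(
    scenarios,
    n_reps: int,
    root_seed: int = 0,
    *,
    strategies=("full", "backward", "unadjusted"),
    alpha: float = 0.157,
    out_dir: str | Path | None = None,
    n_jobs: int = 1,
    calib_n_mc: int = 1_000_000,
    progress: bool = False,
) -> pd.DataFrame:
    """Run many scenarios; optionally persist one CSV per scenario and resume.

    With ``out_dir`` set, a scenario whose CSV already exists is loaded
    instead of re-run; completed per-scenario outputs are bitwise identical
    across resumed runs because replicate seed streams depend only on
    (root_seed, replicate, scenario_id).
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    def one(sc):
        if out_path is not None:
            f = out_path / f"scenario_{sc.scenario_id:05d}.csv"
            if f.exists():
                return pd.read_csv(f)
        if sc.alpha0 is None:
            sc = dgm.calibrated(sc, n_mc=calib_n_mc)
        perf = run_scenario(
            sc, n_reps, strategies=strategies, root_seed=root_seed, alpha=alpha
        )
        frame = results_to_frame([perf])
        if out_path is not None:
            frame.to_csv(out_path / f"scenario_{sc.scenario_id:05d}.csv", index=False)
        return frame

    if n_jobs != 1:
        from joblib import Parallel, delayed

        frames = Parallel(n_jobs=n_jobs)(delayed(one)(sc) for sc in scenarios)
    else:
        frames = []
        for i, sc in enumerate(scenarios):
            frames.append(one(sc))
            if progress and (i + 1) % 10 == 0:
                print(f"  grid: {i + 1}/{len(scenarios)} scenarios done")
    return pd.concat(frames, ignore_index=True)


def aggregate(
    frame: pd.DataFrame,
    estimand: str = "log_cor",
    *,
    expected_per_group: int | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Summary-table rows per (theta, event fraction, number of events) arm.

    For the chosen estimand: mean bias under the full and backward-eliminated
    model, the median/min/max relative efficiency MSE(BE)/MSE(full), the
    number of scenarios where backward elimination has the lower MSE, and how
    many of those fall in each DGM-composition class (at least three full
    instruments; at least three noise covariates; neither).  A final
    "overall" row pools every scenario.  When ``expected_per_group`` is
    given, groups missing scenarios raise an error naming the gaps.
    """
    sub = frame[frame["estimand"] == estimand]
    wide = sub.pivot_table(
        index=["scenario_id", "theta", "event_fraction", "expected_events",
               "composition"],
        columns="strategy", values=["bias", "mse"],
    )
    if ("mse", "backward") not in wide.columns or ("mse", "full") not in wide.columns:
        raise ValueError("aggregate needs both 'full' and 'backward' strategies")
    wide = wide.reset_index()
    wide["rel_eff"] = wide[("mse", "backward")] / wide[("mse", "full")]

    def summarize(g):
        better = g[g["rel_eff"] < 1.0]
        comp = better["composition"].astype(str)
        return pd.Series(
            {
                "n_scenarios": len(g),
                "mean_bias_full": g[("bias", "full")].mean(),
                "mean_bias_be": g[("bias", "backward")].mean(),
                "median_rel_eff": g["rel_eff"].median(),
                "min_rel_eff": g["rel_eff"].min(),
                "max_rel_eff": g["rel_eff"].max(),
                "n_be_better": len(better),
                "n_ge3_instruments": int(comp.str.contains("instruments").sum()),
                "n_ge3_noise": int(comp.str.contains("noise").sum()),
                "n_neither": int((comp == "neither").sum()),
            }
        )

    keys = ["theta", "event_fraction", "expected_events"]
    grouped = (
        wide.groupby(keys, dropna=False, sort=True)
        .apply(summarize, include_groups=False)
        .reset_index()
    )
    if expected_per_group is not None:
        gaps = grouped[grouped["n_scenarios"] != expected_per_group]
        if len(gaps):
            raise ValueError(
                "incomplete scenario groups: "
                + "; ".join(
                    f"theta={r.theta}, ef={r.event_fraction}, "
                    f"events={r.expected_events}: {int(r.n_scenarios)} scenarios"
                    for r in gaps.itertuples()
                )
            )
    overall = summarize(wide)
    overall_row = pd.DataFrame([{k: "overall" for k in keys} | overall.to_dict()])
    out = pd.concat([grouped, overall_row], ignore_index=True)
    for col in ("n_scenarios", "n_be_better", "n_ge3_instruments", "n_ge3_noise",
                "n_neither"):
        out[col] = out[col].astype(int)
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out
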