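"""Scenario enumeration, intercept calibration and true-estimand checks."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit

from confsel import dgm

# ---------------------------------------------------------------------------
# enumeration


def test_experiment1_enumeration():
    scenarios = dgm.enumerate_scenarios_exp1()
    assert len(scenarios) == 144
    assert all(s.theta == 0.0 for s in scenarios)
    assert {s.n for s in scenarios} == {60, 120}
    assert {s.event_fraction for s in scenarios} == {0.5, 0.2}
    assert all(0.0 <= s.beta_la <= 0.5 and 0.0 <= s.beta_ly <= 0.5 for s in scenarios)
    assert any(s.beta_la == 0.0 and s.beta_ly == 0.0 for s in scenarios)
    ids = [s.scenario_id for s in scenarios]
    assert ids == sorted(set(ids))


def test_experiment2_enumeration():
    scenarios = dgm.enumerate_scenarios_exp2()
    assert len(scenarios) == 3960
    assert all(s.n in (250, 1000, 1667, 6667) for s in scenarios)
    assert all(len(s.covariates) == 24 for s in scenarios)
    # 495 distinct mixture assignments per arm: multiset coefficient C(12, 4)
    assert len(dgm._mixture_assignments()) == math.comb(9 + 4 - 1, 4) == 495
    per_arm = {}
    for s in scenarios:
        per_arm.setdefault((s.theta, s.expected_events, s.event_fraction), set()).add(
            tuple((c.beta_la, c.beta_ly) for c in s.covariates[12:])
        )
    assert len(per_arm) == 8
    assert all(len(v) == 495 for v in per_arm.values())


def test_enumeration_is_stable():
    a = dgm.enumerate_scenarios_exp2()
    b = dgm.enumerate_scenarios_exp2()
    assert [s.scenario_id for s in a] == [s.scenario_id for s in b]
    assert all(x.covariates == y.covariates for x, y in zip(a[:50], b[:50]))


def test_role_labels():
    assert dgm.CovariateEffect(0.0, 0.0).role_label == "noise"
    assert dgm.CovariateEffect(dgm.LOG105, 0.0).role_label == "instrument-class"
    assert dgm.CovariateEffect(0.0, dgm.LOG12).role_label == "predictor-class"
    assert dgm.CovariateEffect(dgm.LOG12, dgm.LOG105).role_label == "confounder"


def test_composition_classification_recoverable():
    scenarios = dgm.enumerate_scenarios_exp2()
    comps = {s.composition_class() for s in scenarios[:495]}
    assert "neither" in comps
    assert any("instruments" in c for c in comps)
    assert any("noise" in c for c in comps)
    # fixed confounders guarantee at least 12 in every scenario
    assert all(s.role_counts()["confounder"] >= 12 for s in scenarios[:495])


# ---------------------------------------------------------------------------
# calibration


def test_calibration_closed_forms():
    sc = dgm.ScenarioExp1(0, 0.0, 0.0, 60, 0.5)
    a0, g0 = dgm.calibrate_intercepts(sc, n_mc=100_000)
    assert a0 == pytest.approx(0.0, abs=1e-6)
    assert g0 == pytest.approx(0.0, abs=1e-6)
    sc = dgm.ScenarioExp1(0, 0.0, 0.0, 60, 0.2)
    _, g0 = dgm.calibrate_intercepts(sc, n_mc=100_000)
    assert g0 == pytest.approx(logit(0.2), abs=1e-6)


def test_calibration_independent_verification(exp2_scenario):
    """Achieved prevalence/event fraction verified on an independent MC sample."""
    sc = exp2_scenario
    rng = np.random.default_rng(555)
    ta, ty = dgm._draw_projections(sc, 1_000_000, rng)
    p_a = expit(sc.alpha0 + ta)
    assert p_a.mean() == pytest.approx(0.5, abs=0.005)
    p_y = p_a * expit(sc.gamma0 + sc.theta + ty) + (1 - p_a) * expit(sc.gamma0 + ty)
    # 0.2 target, MC noise ~ 4e-4 on each sample
    assert p_y.mean() == pytest.approx(sc.event_fraction, abs=0.005)


def test_calibration_rare_events_target():
    all2 = dgm.enumerate_scenarios_exp2()
    sc = next(s for s in all2 if s.event_fraction == 0.03 and s.theta > 0)
    sc = dgm.calibrated(sc, n_mc=400_000)
    rng = np.random.default_rng(918)
    ta, ty = dgm._draw_projections(sc, 1_000_000, rng)
    p_a = expit(sc.alpha0 + ta)
    p_y = p_a * expit(sc.gamma0 + sc.theta + ty) + (1 - p_a) * expit(sc.gamma0 + ty)
    assert p_y.mean() == pytest.approx(0.03, abs=0.002)


def test_calibration_rejects_bad_tol(exp1_scenario):
    with pytest.raises(ValueError):
        dgm.calibrate_intercepts(exp1_scenario, tol=0.0)


# ---------------------------------------------------------------------------
# dataset generation


def test_generate_dataset_deterministic(exp1_scenario):
    d1 = dgm.generate_dataset(exp1_scenario, seed=5)
    d2 = dgm.generate_dataset(exp1_scenario, seed=5)
    np.testing.assert_array_equal(d1.L, d2.L)
    np.testing.assert_array_equal(d1.A, d2.A)
    np.testing.assert_array_equal(d1.Y, d2.Y)
    d3 = dgm.generate_dataset(exp1_scenario, seed=6)
    assert not np.array_equal(d1.L, d3.L)


def test_generate_dataset_binary_and_aligned(small_dataset):
    assert set(np.unique(small_dataset.A)) <= {0.0, 1.0}
    assert set(np.unique(small_dataset.Y)) <= {0.0, 1.0}
    assert np.all(np.isfinite(small_dataset.L))
    assert small_dataset.L.shape[0] == small_dataset.A.shape[0]


def test_covariate_correlation_matches_target(exp2_scenario):
    """Empirical pairwise correlation of the equicorrelated draw is 0.3."""
    big = dgm.ScenarioExp2(
        scenario_id=exp2_scenario.scenario_id,
        theta=exp2_scenario.theta,
        covariates=exp2_scenario.covariates,
        expected_events=200_000,
        event_fraction=0.2,
        alpha0=exp2_scenario.alpha0,
        gamma0=exp2_scenario.gamma0,
    )
    ds = dgm.generate_dataset(big, seed=3)
    C = np.corrcoef(ds.L[:, :6], rowvar=False)
    off = C[np.triu_indices(6, 1)]
    assert np.allclose(off, 0.3, atol=0.005)
    assert np.allclose(ds.L[:, :6].std(axis=0), 1.0, atol=0.01)


def test_event_fraction_across_replicates(exp2_scenario):
    fracs = [
        dgm.generate_dataset(exp2_scenario, seed=s).Y.mean() for s in range(40)
    ]
    # target 0.2; MC SE of the mean over 40 x 250 draws ~ 0.004
    assert np.mean(fracs) == pytest.approx(0.2, abs=0.02)


# ---------------------------------------------------------------------------
# true marginal effects


def test_true_effects_null_exposure(exp1_scenario):
    te = dgm.true_marginal_effects(exp1_scenario)
    assert te.log_mrr == 0.0 and te.log_mor == 0.0 and te.mrd == 0.0


def test_true_effects_closed_form_no_covariate_effects():
    sc = dgm.ScenarioExp1(
        0, 0.5, 0.0, 60, 0.5, theta=math.log(1.5), alpha0=0.0, gamma0=0.0
    )
    te = dgm.true_marginal_effects(sc, approx_N=10_000)
    assert te.log_mrr == pytest.approx(math.log(1.2), abs=1e-9)
    assert te.log_mor == pytest.approx(math.log(1.5), abs=1e-9)
    assert te.mrd == pytest.approx(0.1, abs=1e-9)


def test_noncollapsibility_of_marginal_or(exp2_scenario):
    te = dgm.true_marginal_effects(exp2_scenario, approx_N=1_000_000)
    assert 0 < abs(te.log_mor) < abs(te.log_cor)
    assert np.sign(te.log_mrr) == np.sign(exp2_scenario.theta)


# ---------------------------------------------------------------------------
# CSV round-trip


def test_scenario_grid_roundtrip(tmp_path, exp2_scenario):
    scen = [exp2_scenario, dgm.calibrated(dgm.enumerate_scenarios_exp1()[0], n_mc=50_000)]
    frame = dgm.scenarios_to_frame(scen)
    path = tmp_path / "grid.csv"
    frame.to_csv(path, index=False)
    import pandas as pd

    back = dgm.scenarios_from_frame(pd.read_csv(path))
    assert back[0].scenario_id == exp2_scenario.scenario_id
    assert back[0].n == exp2_scenario.n
    assert back[0].alpha0 == pytest.approx(exp2_scenario.alpha0)
    np.testing.assert_allclose(
        back[0].beta_la_vector, exp2_scenario.beta_la_vector
    )
    assert back[1].experiment == 1


def test_dataset_to_frame(small_dataset):
    frame = dgm.dataset_to_frame(small_dataset)
    assert list(frame.columns[:2]) == ["Y", "A"]
    assert frame.shape == (small_dataset.n, 2 + small_dataset.L.shape[1])
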