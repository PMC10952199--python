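"""Backward elimination versus the full model on one realistic scenario.

Draws a single dataset from a 24-covariate configuration (12 fixed weak
confounders plus a mixture of stronger confounders, instruments, predictors
and noise), prunes it by backward elimination at p = 0.157, and compares the
conditional odds-ratio and marginal risk-ratio estimates of the two
strategies with the scenario's true values.
"""

import math

from confsel import dgm, estimators, selection

scenarios = dgm.enumerate_scenarios_exp2()
sc = next(
    s for s in scenarios
    if s.theta > 0 and s.n == 1000
    and s.role_counts()["instrument-class"] >= 3
    and s.role_counts()["noise"] >= 3
)
sc = dgm.calibrated(sc, n_mc=400_000)
truth = dgm.true_marginal_effects(sc, approx_N=400_000)
print(f"scenario {sc.scenario_id}: n={sc.n}, event fraction {sc.event_fraction}, "
      f"theta=log(1.5)={sc.theta:.4f}")
print(f"covariate roles: {sc.role_counts()}")

ds = dgm.generate_dataset(sc, seed=7)
res = selection.backward_eliminate(ds, alpha=0.157)
print(f"\nbackward elimination removed {len(res.elimination_trace)} of 24 covariates")
removed_confounders = set(sc.true_confounder_indices()) & set(res.eliminated_indices())
print(f"  among them {len(removed_confounders)} true (mostly weak) confounders")

full = estimators.estimate_effects(ds, "full")
be = estimators.estimate_effects(ds, "backward")
crude = estimators.estimate_effects(ds, "unadjusted")

print(f"\n{'':12s}{'log cOR':>9s}{'log mRR':>9s}")
print(f"{'truth':12s}{truth.log_cor:9.3f}{truth.log_mrr:9.3f}")
for eff in (full, be, crude):
    print(f"{eff.strategy_tag:12s}{eff.log_cor:9.3f}{eff.log_mrr:9.3f}")
print()
print("The crude estimate absorbs the confounding; full and backward-")
print("eliminated fits should both sit near the truth on a single dataset,")
print("with their efficiency difference only visible across many replicates.")
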