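"""Selection-aware confidence intervals and stability diagnostics.

On a dataset where backward elimination is genuinely unstable, compares the
selected-model bootstrap CI (conditions on the chosen covariates; too
narrow) with the global bootstrap CI (re-runs selection in every resample),
and reports the relative conditional bias (RCB) and root mean squared
difference ratio (RMSDR) of the selection-based estimator.
"""

import numpy as np
from scipy.special import expit

from confsel import dgm, inference, selection

rng = np.random.default_rng(0)
n = 150
L = rng.standard_normal((n, 3))
A = (rng.random(n) < expit(0.9 * L[:, 0])).astype(float)   # L1: near-instrument
Y = (rng.random(n) < expit(-0.6 + 0.8 * A + 0.35 * L[:, 0] + 0.30 * L[:, 1])).astype(float)
ds = dgm.Dataset(L=L, A=A, Y=Y, seed_record=(0,))

res = selection.backward_eliminate(ds)
print("elimination trace (covariate, p at removal):", [
    (j, round(p, 3)) for j, p in res.elimination_trace
])

rows = []
for mode in ("boot_selected", "boot_global"):
    ci = inference.bootstrap_ci(ds, "log_cor", mode=mode, B=500, seed=1)
    rows.append((mode, ci))
    print(f"{mode:14s}: log cOR 95% CI [{ci.lower:.3f}, {ci.upper:.3f}] "
          f"width {ci.width:.3f}")

m = inference.stability_measures(ds, B=500, seed=1)
print(f"\nRCB  = {m.rcb_percent:+.1f}%   (selection-induced shift of the estimate)")
print(f"RMSDR = {m.rmsdr:.2f}    (>1: selection inflates variance beyond the full model)")
print()
print("The global interval is wider because it propagates the uncertainty of")
print("which covariates get selected - the selected-model interval ignores it.")
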