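"""Train the clinical-only survival transformer and read survival curves.

A discrete-time head over five percentile-derived time bins (plus a
beyond-horizon cell) turns one softmax vector per subject into a full
individual survival function, interpolated to months.  Training minimizes
the two-part objective: a right-censoring-aware likelihood plus a pairwise
ranking penalty.
"""

import numpy as np

from gliosurv import discrete_survival as ds
from gliosurv import pipeline as P
from gliosurv.fusion import FusionConfig, SurvivalTransformer
from gliosurv.synthetic import DEFAULT_CUT_POINTS, generate_tabular, sample_survival

rng = np.random.default_rng(0)
X, lp = generate_tabular(300, [1.0, -1.0], rng)
gen_grid = ds.TimeGrid(DEFAULT_CUT_POINTS)
t, e, _ = sample_survival(lp, gen_grid, 0.3, rng)

grid = ds.build_time_grid(t[:200])
print("time grid from training percentiles (days):",
      np.round(grid.cut_points, 1))

cfg = FusionConfig(embed_dim=16, n_heads=2, clin_tokens=4, img_dim=16,
                   n_img_tokens=0, n_bins=grid.n_bins, modality="clinical",
                   hidden=16)
model = SurvivalTransformer(cfg, d_clin=2, seed=0)
P.train_survival(model, None, X, t, e, grid, np.arange(160), np.arange(160, 200),
                 epochs=120, batch_size=64, lr=3e-3, seed=0)

out = P.predict_survival(model, None, X, grid, np.arange(200, 300))
curve = ds.survival_function(out)
report = P.evaluate_predictions(out, t[200:], e[200:])

hi, lo = np.argmax(lp[200:]), np.argmin(lp[200:])
print(f"\nheld-out Ctd {report.ctd:.3f}, IBS {report.ibs:.3f}")
print("highest-risk subject, S at cut points:", np.round(curve.grid_survival[hi], 2))
print("lowest-risk subject,  S at cut points:", np.round(curve.grid_survival[lo], 2))
print("The model orders the two correctly and outputs a full nonproportional "
      "survival curve for each, not just a relative risk score.")
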