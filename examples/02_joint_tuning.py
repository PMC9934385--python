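"""Tune (tau, lambda) jointly by cross-validation and inspect the choice.

tau and lambda are tuned together the same way (gamma, lambda) are tuned
for the adaptive lasso; the CV table lets you see the error surface.
"""

import numpy as np

from lqsso import (TuningGrid, cross_validate, fit_with_params, loocv_error,
                   standardize)

rng = np.random.default_rng(1)
n, p = 80, 8
X = rng.standard_normal((n, p))
beta_true = np.concatenate([np.array([1.5, 1.0, 0.8]), np.zeros(p - 3)])
y = X @ beta_true + 0.7 * rng.standard_normal(n)

grid = TuningGrid().coarsen_tau(0.1)  # tau in {0, 0.1, ..., 1}
best, table = cross_validate(X, y, "lqsso", grid, seed=7)
print("selected parameters:", best)

surface = table.groupby(["tau_or_gamma", "lambda"])["mse"].mean()
print("best five grid points by CV error:")
print(surface.sort_values().head(5).round(4).to_string())

fit = fit_with_params(standardize(X, y), "lqsso", best)
print("active set at the selected parameters:", fit.active_set.tolist())
cverr = loocv_error(X, y, "lqsso", best)
print(f"leave-one-out CVErr at the selected parameters: {cverr:.4f}")
# CVErr is the irreducible noise variance (0.49 here) plus the estimation
# error of the fitted model; the gap between them is what tuning minimizes.
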