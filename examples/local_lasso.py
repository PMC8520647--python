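"""Locally weighted LASSO versus a single global fit.

The solver minimizes (1/2m) sum_i w_i (y_i - b0 - x_i'b)^2 + (lam/m)||b||_1
by coordinate descent; in local mode the weights w_i come from a Gaussian
kernel centred at each query, so the model is refitted around the query and
can track structure a single straight line cannot.
"""

import numpy as np

from emrcost import LocallyWeightedLasso

rng = np.random.default_rng(0)
x = np.linspace(-1, 1, 40)
y = 2.0 * x**2 + rng.normal(scale=0.05, size=40)   # curved ground truth
X = x[:, None]

model = LocallyWeightedLasso(lam=0.001, tau=0.3).fit(X, y)
pred_local = model.predict(X, local=True)
pred_global = model.predict(X, local=False)

mse_local = np.mean((pred_local - y) ** 2)
mse_global = np.mean((pred_global - y) ** 2)
print(f"global linear LASSO  MSE: {mse_global:.4f}")
print(f"locally weighted fit MSE: {mse_local:.4f}")
print("\nthe quadratic has no global linear fit, so the straight line's error")
print("is dominated by bias; the kernel-weighted refits (bandwidth tau=0.3)")
print("follow the curvature and cut the error by an order of magnitude.")

sparse_rng = np.random.default_rng(1)
Xs = sparse_rng.normal(size=(200, 10))
beta = np.zeros(10)
beta[:3] = [3.0, -2.0, 1.0]
ys = Xs @ beta + sparse_rng.normal(size=200)
m = LocallyWeightedLasso(lam="cv").fit(Xs, ys)
print(f"\nsparse recovery: CV-chosen penalty lam={m.lam_:.2f}, "
      f"fitted support {np.flatnonzero(m.global_model_.beta).tolist()} "
      f"(true support [0, 1, 2])")
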