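"""Goodness-of-fit of the TR weight model on its own generative terms.

Simulates log-weights that truly are linear in squared chemical
distances plus Gaussian noise, fits the stacked univariate regression,
and reports (a) the training R-squared of the fit and (b) the empirical
coverage of 95% prediction intervals for held-out weight targets.  On
correctly specified data the coverage should sit at the nominal 95%.
"""

import numpy as np

import topreg as tg
from topreg.univariate import StackedDesign

N, K = 500, 10
B = tg.random_coefficients(K, seed=0)
sim = tg.simulate_tr_data(tg.GenerativeSpec(N=N, K=K, B_true=B, sigma=0.5, seed=1))

rng = np.random.default_rng(2)
perm = rng.permutation(N)
train, test = perm[:400], perm[400:]

model = tg.fit_univariate(StackedDesign.from_weight_matrix(sim.W_tilde[train], sim.D_X[train]))
print(f"training R^2 of the stacked weight regression: {tg.training_r2(model):.4f}")

x_rows = np.repeat(sim.D_X[test], K, axis=0)
cols = np.tile(np.arange(K), len(test))
targets = sim.W_tilde[test].ravel()
cov = tg.pi_coverage(model, x_rows, cols, targets, level=0.95)
print(f"coverage of 95% prediction intervals on {len(targets)} held-out "
      f"weight targets: {100 * cov:.1f}%")
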