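"""Fit a Cox model by threshold gradient directed regularization.

Survival is simulated from the R2 features (so the truth contains products);
the modified TGDR enforces heredity: a selected interaction always brings in
its two parent first-order features.  (tau, K) are tuned by 5-fold CV.
"""

import numpy as np

from coexsurv import (SimConfig, build_features, build_network, draw_true_model,
                      fit_tuned, gen_expression, gen_survival, module_pca)

cfg = SimConfig(n_samples=100, n_genes=90, n_modules=3, module_sizes=(25, 25, 25),
                min_module_size=14, n_true_features=4, seed=1)
x = gen_expression(cfg, seed=1)
_, modules = build_network(x, b=6, min_module_size=14)
pcas = module_pca(x, modules)
feats = build_features(pcas, "R2")
true_idx, beta_true = draw_true_model(feats, cfg, seed=2)
surv = gen_survival(feats, beta_true, cfg, seed=3)
print("true features:", [feats.index[i] for i in true_idx])

fit = fit_tuned(feats.Z, surv, V=5, tau_grid=(1.0, 0.75, 0.5, 0.25), K_max=400,
                variant="modified", index=feats.index, seed=4)
sel = np.flatnonzero(fit.selected)
print(f"tuned tau = {fit.tau}, K = {fit.n_steps}; "
      f"{len(sel)} of {feats.n_features} features selected")
print("selected:", [feats.index[i] for i in sel])
# every selected (i, j) product has its parents (0, i) and (0, j) selected
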