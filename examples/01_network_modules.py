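"""Build a weighted coexpression network and detect its modules.

Generates a small module-structured expression matrix (3 planted modules of
25 genes plus 15 background genes), builds the |correlation|^6 network, and
clusters the topological-overlap dissimilarity into modules.
"""

import numpy as np

from coexsurv import SimConfig, build_network, gen_expression, pick_power, similarity

cfg = SimConfig(n_samples=60, n_genes=90, n_modules=3, module_sizes=(25, 25, 25),
                min_module_size=14, seed=0)
x = gen_expression(cfg, seed=0)

# scale-free topology fit for candidate soft-threshold powers
net = similarity(x)
b, fits = pick_power(net, candidate_powers=(2, 4, 6, 8), fallback_power=6.0)
print(fits.to_string(index=False))
print(f"chosen power b = {b}")

net, modules = build_network(x, b=6, min_module_size=14)
sizes = np.bincount(modules.labels)
print(f"{modules.n_modules} modules; sizes {sizes[1:].tolist()}, "
      f"{sizes[0]} unassigned genes")
# each detected module should correspond to one planted block of 25 genes
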