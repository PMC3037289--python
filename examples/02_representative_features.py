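"""Module PCs and the four representative-feature sets R1-R4.

R1 keeps each module's first PC ("eigengene"); R3 keeps enough PCs per
module to explain 80% of its variance; R2/R4 add quadratics and pairwise
interactions of those columns.
"""

from coexsurv import (SimConfig, build_features, build_network, gen_expression,
                      module_pca, select_pcs_by_variance)

cfg = SimConfig(n_samples=60, n_genes=90, n_modules=3, module_sizes=(25, 25, 25),
                min_module_size=14, seed=0)
x = gen_expression(cfg, seed=0)
_, modules = build_network(x, b=6, min_module_size=14)
pcas = module_pca(x, modules)

for pca in pcas:
    m_star = select_pcs_by_variance(pca, xi=80.0)
    print(f"module {pca.module_id}: {len(pca.member_gene_ids)} genes, "
          f"first PC explains {pca.variance_fraction[0]:.0%}, "
          f"m* = {m_star} PCs reach 80%")

for kind in ("R1", "R2", "R3", "R4"):
    f = build_features(pcas, kind, xi=80.0)
    print(f"{kind}: {f.n_first_order} first-order + "
          f"{f.n_features - f.n_first_order} product columns")
# R2 has M(M+3)/2 columns and R4 has P(P+3)/2, where P = sum of the m*
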