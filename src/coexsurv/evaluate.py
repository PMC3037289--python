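"""Cross-validated prediction evaluation and gene-level model rewriting.

Out-of-fold risk scores are summarized two ways: (1) the two-group logrank
chi-square statistic (df 1) after dichotomizing the scores at their median,
and (2) Harrell's concordance index over usable pairs (0.5 = random ranking).

Because every representative feature is a (product of) linear combination(s)
of module genes, a sparse feature-level Cox model can be rewritten at the
gene level as a linear term plus a quadratic form in centered expressions;
:func:`gene_level_coefficients` performs that expansion and ranks the largest
coefficients.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank

from .coxtgdr import SurvivalData, TgdrFit, _stratified_folds, fit_tuned, DEFAULT_TAU_GRID
from .features import FeatureSet, ModulePCA, build_features, module_pca, project_features
from .network import build_network
from .preprocess import ExpressionMatrix

__all__ = [
    "EvaluationResult",
    "GeneLevelModel",
    "concordance_index",
    "logrank_median_split",
    "cv_predict",
    "gene_level_coefficients",
]


def concordance_index(scores: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's C: fraction of usable pairs where higher risk = shorter survival.

    A pair (i, j) is usable when the earlier observed time is an event and the
    times differ; tied scores count 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    t, d = surv.time, surv.status
    earlier = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_usable = int(earlier.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs for the concordance index")
    higher = scores[:, None] > scores[None, :]
    tied = scores[:, None] == scores[None, :]
    concordant = float((earlier & higher).sum())
    half = float((earlier & tied).sum())
    return (concordant + 0.5 * half) / n_usable


def logrank_median_split(
    scores: np.ndarray, surv: SurvivalData
) -> tuple[float, float]:
    """Two-group logrank chi-square after splitting scores at their median.

    Scores equal to the median go to the low-risk group.  Returns
    (statistic, p-value); the statistic is chi-square with 1 df under the
    null of no predictive power.
    """
    scores = np.asarray(scores, dtype=float)
    med = np.median(scores)
    high = scores > med
    if high.all() or not high.any():
        raise ValueError("degenerate median split (all scores on one side)")
    res = _lifelines_logrank(
        surv.time[~high], surv.time[high],
        event_observed_A=surv.status[~high], event_observed_B=surv.status[high],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclasses.dataclass
class EvaluationResult:
    risk_scores: np.ndarray
    logrank_stat: float
    logrank_p: float
    concordance: float
    fold_assignment: np.ndarray
    per_fold_fits: list[TgdrFit]
    kind: str

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "logrank_stat": self.logrank_stat,
            "logrank_p": self.logrank_p,
            "concordance": self.concordance,
            "per_fold": [
                {"tau": f.tau, "K": f.n_steps, "n_selected": int(f.selected.sum())}
                for f in self.per_fold_fits
            ],
        }


def cv_predict(
    x: ExpressionMatrix,
    surv: SurvivalData,
    kind: str = "R1",
    V: int = 5,
    seed: int = 0,
    xi: float = 80.0,
    b: float | None = 6.0,
    min_module_size: int = 25,
    cut_height: float | None = None,
    inner_V: int = 5,
    tau_grid=DEFAULT_TAU_GRID,
    K_max: int = 2500,
    delta_nu: float = 1e-3,
    rebuild_per_fold: bool = False,
) -> EvaluationResult:
    """V-fold cross-validated prediction with inner (tau, K) tuning per fold.

    By default the network, modules and features are built once on the full
    data (they are unsupervised) and only the regularized estimation is
    re-run on each reduced dataset; ``rebuild_per_fold=True`` instead rebuilds
    everything from the training samples of each fold and projects the
    held-out samples with the training loadings (strict, leakage-free mode).
    """
    variant = "modified" if kind in ("R2", "R4") else "plain"
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(surv.status, V, rng)
    scores = np.empty(surv.n)
    fits: list[TgdrFit] = []

    if not rebuild_per_fold:
        _, modules = build_network(x, b=b, min_module_size=min_module_size, cut_height=cut_height)
        pcas = module_pca(x, modules)
        feats = build_features(pcas, kind, xi=xi)

    for v in range(V):
        tr = np.flatnonzero(folds != v)
        te = np.flatnonzero(folds == v)
        if rebuild_per_fold:
            x_tr = x.subset_samples(tr)
            _, modules = build_network(
                x_tr, b=b, min_module_size=min_module_size, cut_height=cut_height
            )
            pcas = module_pca(x_tr, modules)
            feats_tr = build_features(pcas, kind, xi=xi)
            Z_tr = feats_tr.Z
            Z_te = project_features(x.subset_samples(te), pcas, feats_tr).Z
        else:
            Z_tr, Z_te = feats.Z[tr], feats.Z[te]
        fit = fit_tuned(
            Z_tr, surv.subset(tr), V=inner_V, tau_grid=tau_grid, K_max=K_max,
            delta_nu=delta_nu, variant=variant,
            index=(feats_tr.index if rebuild_per_fold else feats.index),
            seed=int(rng.integers(2**31 - 1)),
        )
        scores[te] = fit.risk_scores(Z_te)
        fits.append(fit)

    stat, p = logrank_median_split(scores, surv)
    return EvaluationResult(
        risk_scores=scores,
        logrank_stat=stat,
        logrank_p=p,
        concordance=concordance_index(scores, surv),
        fold_assignment=folds,
        per_fold_fits=fits,
        kind=kind,
    )


@dataclasses.dataclass
class GeneLevelModel:
    """Feature-level Cox model rewritten over (centered) gene expressions.

    risk(u) = c' (u - mu) + (u - mu)' Q (u - mu), with c the linear part,
    Q the symmetric quadratic form; per-pair interaction coefficients are
    2 Q_gh (g != h) and per-gene quadratics Q_gg.
    """

    gene_ids: list[str]
    mean: np.ndarray
    linear: np.ndarray
    first_order_weights: np.ndarray        # genes x P, column i = w_i
    second_order_terms: list[tuple[int, int, float]]  # (i, j, beta_ij), 1-based
    ranked: pd.DataFrame

    def risk_scores(self, x: ExpressionMatrix) -> np.ndarray:
        pos = {g: i for i, g in enumerate(x.gene_ids)}
        rows = [pos[g] for g in self.gene_ids]
        U = x.values[rows].T - self.mean  # samples x genes, centered
        score = U @ self.linear
        if self.second_order_terms:
            F = U @ self.first_order_weights  # samples x P
            for i, j, bij in self.second_order_terms:
                score = score + bij * F[:, i - 1] * F[:, j - 1]
        return score


def gene_level_coefficients(
    fit: TgdrFit,
    features: FeatureSet,
    pcas: list[ModulePCA],
    top_n: int = 20,
) -> GeneLevelModel:
    """Expand a sparse feature-level fit into gene-level coefficients.

    Each first-order feature i is w_i' (u - mu) with w_i supported on its
    module's genes; the linear part is sum beta_{0,i} w_i and each selected
    second-order (i, j) contributes the rank-one quadratic
    beta_{i,j} (w_i w_j' + w_j w_i') / 2.  The ranked table merges |c_g|,
    |Q_gg| and |2 Q_gh| and keeps the ``top_n`` largest.
    """
    by_module = {p.module_id: p for p in pcas}
    gene_ids: list[str] = []
    gene_pos: dict[str, int] = {}
    means: list[float] = []
    for p in pcas:
        for r, g in enumerate(p.member_gene_ids):
            if g not in gene_pos:
                gene_pos[g] = len(gene_ids)
                gene_ids.append(g)
                means.append(float(p.mean[r]))
    G = len(gene_ids)
    P = features.n_first_order

    W_full = np.zeros((G, P))
    for i in range(1, P + 1):
        module_id, pc_rank = features.provenance[i]
        pca = by_module[module_id]
        w = pca.loading_weights()[:, pc_rank - 1]
        for r, g in enumerate(pca.member_gene_ids):
            W_full[gene_pos[g], i - 1] = w[r]

    col = {pair: c for c, pair in enumerate(features.index)}
    linear = np.zeros(G)
    second: list[tuple[int, int, float]] = []
    for i in range(1, P + 1):
        bi = fit.beta[col[(0, i)]]
        if bi != 0:
            linear += bi * W_full[:, i - 1]
    for (i, j), c in col.items():
        if i >= 1 and fit.beta[c] != 0:
            second.append((i, j, float(fit.beta[c])))

    # quadratic form restricted to genes in modules touched by second-order terms
    rows = []
    for g in range(G):
        if linear[g] != 0:
            rows.append(("gene", gene_ids[g], "", float(linear[g])))
    if second:
        touched = sorted(
            {g for i, j, _ in second for g in np.flatnonzero(
                np.abs(W_full[:, i - 1]) + np.abs(W_full[:, j - 1]) > 0
            )}
        )
        tpos = {g: t for t, g in enumerate(touched)}
        Q = np.zeros((len(touched), len(touched)))
        Wt = W_full[touched]
        for i, j, bij in second:
            wi, wj = Wt[:, i - 1], Wt[:, j - 1]
            Q += bij * (np.outer(wi, wj) + np.outer(wj, wi)) / 2.0
        for a, g in enumerate(touched):
            if Q[a, a] != 0:
                rows.append(("quadratic", gene_ids[g], gene_ids[g], float(Q[a, a])))
            for bidx in range(a + 1, len(touched)):
                if Q[a, bidx] != 0:
                    rows.append(
                        (
                            "interaction",
                            gene_ids[g],
                            gene_ids[touched[bidx]],
                            float(2.0 * Q[a, bidx]),
                        )
                    )
    ranked = pd.DataFrame(rows, columns=["type", "gene_a", "gene_b", "coefficient"])
    ranked["magnitude"] = ranked.coefficient.abs()
    ranked = (
        ranked.sort_values("magnitude", ascending=False, kind="stable")
        .head(top_n)
        .reset_index(drop=True)
    )
    return GeneLevelModel(
        gene_ids=gene_ids,
        mean=np.asarray(means),
        linear=linear,
        first_order_weights=W_full,
        second_order_terms=second,
        ranked=ranked,
    )
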