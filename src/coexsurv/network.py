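"""Weighted gene-coexpression network and module detection.

The network is built in five steps: absolute Pearson correlation similarity
``S``, soft-threshold adjacency ``a = S^b`` (the power ``b`` picked by the
scale-free topology criterion), connectivity ``C_k = sum_u a_{k,u}``, the
topological-overlap dissimilarity

    d_{k,j} = 1 - (l_{k,j} + a_{k,j}) / (min(C_k, C_j) + 1 - a_{k,j}),
    l_{k,j} = sum_u a_{k,u} a_{j,u},

and average-linkage hierarchical clustering of ``D = (d_{k,j})`` with a
height cut and a minimum module size.

Self-terms: by default the adjacency diagonal is treated as zero, so the sums
for ``C_k`` and ``l_{k,j}`` exclude ``u = k`` (and ``u = j``).  This is the
convention under which ``omega`` is guaranteed to stay in [0, 1].  Passing
``literal_sums=True`` evaluates the sums with ``a_{k,k} = 1`` included, in
which case entries are clipped back into [0, 1].
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = [
    "GeneNetwork",
    "ModuleAssignment",
    "similarity",
    "adjacency",
    "pick_power",
    "connectivity",
    "tom_dissimilarity",
    "detect_modules",
    "build_network",
]


@dataclasses.dataclass
class GeneNetwork:
    gene_ids: list[str]
    similarity: np.ndarray
    power: float | None = None
    adjacency: np.ndarray | None = None
    connectivity: np.ndarray | None = None
    tom_dissimilarity: np.ndarray | None = None


@dataclasses.dataclass
class ModuleAssignment:
    """Gene -> module labels; 0 means unassigned, 1..n_modules are modules
    ordered by decreasing size (ties by smallest member index)."""

    gene_ids: list[str]
    labels: np.ndarray
    n_modules: int
    min_module_size: int

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "module": self.labels})


def similarity(x: ExpressionMatrix) -> GeneNetwork:
    """Absolute Pearson correlation S(k, j) = |cor(k, j)| between gene rows."""
    if x.n_samples < 3:
        raise ValueError("similarity needs at least 3 samples")
    sd = x.values.std(axis=1)
    if np.any(sd == 0):
        bad = [x.gene_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant gene(s), correlation undefined: {bad[:5]}")
    S = np.abs(np.corrcoef(x.values))
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    return GeneNetwork(gene_ids=list(x.gene_ids), similarity=S)


def adjacency(net: GeneNetwork, b: float) -> GeneNetwork:
    """Soft-threshold adjacency a = S^b elementwise; returns a populated copy."""
    if b <= 0:
        raise ValueError("power b must be positive")
    A = net.similarity**b
    np.fill_diagonal(A, 1.0)
    return dataclasses.replace(net, power=float(b), adjacency=A)


def connectivity(net: GeneNetwork, literal_sums: bool = False) -> np.ndarray:
    """Row sums of the adjacency; the self term a_{k,k}=1 is excluded unless
    ``literal_sums`` is set."""
    if net.adjacency is None:
        raise ValueError("adjacency not populated")
    A = net.adjacency.copy()
    if not literal_sums:
        np.fill_diagonal(A, 0.0)
    return A.sum(axis=1)


def _scale_free_fit(C: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) on log10(mean connectivity), equal-width bins.

    Equal-width binning of the connectivity (empty bins dropped) is the
    standard form of the scale-free topology fit; equal-count bins would make
    the frequencies constant by construction.
    """
    C = np.asarray(C, dtype=float)
    C = C[C > 0]
    if C.size < 2:
        raise ValueError("all connectivities zero")
    edges = np.linspace(C.min(), C.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        return 0.0
    which = np.clip(np.searchsorted(edges, C, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for bin_idx in range(n_bins):
        mask = which == bin_idx
        if mask.sum() == 0:
            continue
        xs.append(np.log10(C[mask].mean()))
        ys.append(np.log10(mask.sum() / C.size))
    if len(xs) < 3 or len(set(ys)) < 2:
        return 0.0
    res = stats.linregress(xs, ys)
    return float(res.rvalue**2)


def pick_power(
    net: GeneNetwork,
    candidate_powers: tuple[float, ...] = tuple(range(1, 11)),
    r2_target: float = 0.8,
    n_bins: int = 10,
    fallback_power: float | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power the connectivity distribution is binned
    (``n_bins`` equal-count bins) and log10(frequency) is regressed on
    log10(mean bin connectivity).  Returns the smallest power with
    R^2 >= ``r2_target``; otherwise the power maximizing R^2, or
    ``fallback_power`` if given (6 is the conventional default for this kind
    of network).  The full (power, R^2) table is returned alongside.
    """
    if not candidate_powers:
        raise ValueError("candidate_powers must be nonempty")
    rows = []
    for b in candidate_powers:
        C = connectivity(adjacency(net, b))
        rows.append({"power": float(b), "r_squared": _scale_free_fit(C, n_bins=n_bins)})
    fits = pd.DataFrame(rows)
    ok = fits[fits.r_squared >= r2_target]
    if len(ok):
        chosen = float(ok.power.iloc[0])
    elif fallback_power is not None:
        chosen = float(fallback_power)
    else:
        chosen = float(fits.power.iloc[int(fits.r_squared.to_numpy().argmax())])
    return chosen, fits


def tom_dissimilarity(net: GeneNetwork, literal_sums: bool = False) -> np.ndarray:
    """Topological-overlap dissimilarity D; symmetric, zero diagonal, in [0,1]."""
    if net.adjacency is None:
        raise ValueError("adjacency not populated")
    A = net.adjacency.copy()
    np.fill_diagonal(A, 1.0 if literal_sums else 0.0)
    # with a zero diagonal, (A @ A)[k, j] automatically excludes u in {k, j}
    L = A @ A
    C = A.sum(axis=1)
    Amat = net.adjacency.copy()
    np.fill_diagonal(Amat, 0.0)
    denom = np.minimum.outer(C, C) + 1.0 - Amat
    if np.any(denom <= 0):
        raise ValueError("nonpositive TOM denominator")
    omega = (L + Amat) / denom
    D = 1.0 - omega
    D = np.clip(D, 0.0, 1.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def _adaptive_cut_height(link: np.ndarray, min_module_size: int) -> float:
    """Height just below the lowest merge of two module-sized branches."""
    n = link.shape[0] + 1
    if n < 2:
        return 0.0
    sizes = np.ones(2 * n - 1)
    sizes[n:] = link[:, 3]
    candidates = [float(link[-1, 2])]  # the final merge is always severed
    for a, b, h, _ in link:
        if sizes[int(a)] >= min_module_size and sizes[int(b)] >= min_module_size:
            candidates.append(float(h))
    return float(np.nextafter(min(candidates), -np.inf))


def detect_modules(
    D: np.ndarray,
    min_module_size: int = 25,
    cut_height: float | None = None,
    gene_ids: list[str] | None = None,
) -> ModuleAssignment:
    """Average-linkage clustering of the dissimilarity, cut at a height.

    Branches below the cut with at least ``min_module_size`` members become
    modules, labeled 1..n_modules in decreasing size order; everything else
    is labeled 0.  When ``cut_height`` is None an adaptive cut is used, in
    the spirit of the dynamic tree-cut procedure: the tree is cut just below
    the lowest merge that joins two branches each already holding at least
    ``min_module_size`` leaves (just below the final merge if no such join
    exists), so module-sized branches are kept intact while the joins between
    them are severed.  TOM heights concentrate near 1 for soft-thresholded
    networks, which makes any fixed fraction of the maximum height unreliable
    as a default.  The rule assumes modules are smaller than twice the
    minimum module size would allow them to split; explicit ``cut_height``
    overrides it.
    """
    D = np.asarray(D, dtype=float)
    d = D.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(d)]
    if d < min_module_size:
        warnings.warn("fewer genes than min_module_size; no modules detected")
        return ModuleAssignment(list(gene_ids), np.zeros(d, dtype=int), 0, min_module_size)
    link = sch.linkage(squareform(D, checks=False), method="average")
    if cut_height is None:
        cut_height = _adaptive_cut_height(link, min_module_size)
    raw = sch.fcluster(link, t=cut_height, criterion="distance")
    labels = np.zeros(d, dtype=int)
    clusters = []
    for c in np.unique(raw):
        idx = np.flatnonzero(raw == c)
        if idx.size >= min_module_size:
            clusters.append(idx)
    clusters.sort(key=lambda idx: (-idx.size, idx.min()))
    for m, idx in enumerate(clusters, start=1):
        labels[idx] = m
    return ModuleAssignment(list(gene_ids), labels, len(clusters), min_module_size)


def build_network(
    x: ExpressionMatrix,
    b: float | None = None,
    r2_target: float = 0.8,
    min_module_size: int = 25,
    cut_height: float | None = None,
    literal_sums: bool = False,
) -> tuple[GeneNetwork, ModuleAssignment]:
    """Convenience: similarity -> (auto) power -> adjacency -> TOM -> modules."""
    net = similarity(x)
    if b is None:
        b, _ = pick_power(net, r2_target=r2_target, fallback_power=6.0)
    net = adjacency(net, b)
    net.connectivity = connectivity(net, literal_sums=literal_sums)
    net.tom_dissimilarity = tom_dissimilarity(net, literal_sums=literal_sums)
    modules = detect_modules(
        net.tom_dissimilarity,
        min_module_size=min_module_size,
        cut_height=cut_height,
        gene_ids=list(x.gene_ids),
    )
    return net, modules
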