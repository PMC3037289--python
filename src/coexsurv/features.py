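"""Module-level representative features.

Principal component analysis is run within each network module separately.
Score columns (samples x components) are unit-norm and pairwise orthogonal;
variance fractions are nonincreasing.  Four feature sets are built from the
module PCs:

* ``R1`` — the first PC of every module (the classical "eigengene" set);
* ``R2`` — R1 plus all pairwise products of its columns (quadratics i = j and
  interactions i < j);
* ``R3`` — per module, the top ``m*`` PCs jointly explaining at least ``xi``
  percent of that module's variance, concatenated (P columns in total);
* ``R4`` — R3 plus all pairwise products of its columns.

Features are indexed by pairs: ``(0, i)`` is the i-th first-order column
(1-based) and ``(i, j)`` with ``1 <= i <= j`` is the elementwise product of
first-order columns i and j.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .network import ModuleAssignment
from .preprocess import ExpressionMatrix

__all__ = [
    "ModulePCA",
    "FeatureSet",
    "KINDS",
    "module_pca",
    "select_pcs_by_variance",
    "build_features",
    "project_features",
]

KINDS = ("R1", "R2", "R3", "R4")


@dataclasses.dataclass
class ModulePCA:
    """PCA of one module's expression submatrix (samples as observations).

    ``scores = (data - mean) @ components / singular_values`` has unit-norm,
    pairwise-orthogonal columns; ``variance_fraction`` are the normalized
    squared singular values.  A deterministic sign convention is applied: each
    score column is flipped so it correlates non-negatively with the module's
    mean expression profile (largest-magnitude loading forced positive when
    that correlation is exactly zero).
    """

    module_id: int
    member_gene_ids: list[str]
    mean: np.ndarray                 # per-gene training mean, length g
    components: np.ndarray           # g x rank, orthonormal columns (right singular vectors)
    singular_values: np.ndarray      # length rank, positive, nonincreasing
    scores: np.ndarray               # n x rank, unit-norm columns
    variance_fraction: np.ndarray    # length rank, sums to 1, nonincreasing

    @property
    def rank(self) -> int:
        return int(self.singular_values.size)

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Project new data (samples x member genes) onto the stored axes."""
        centered = np.asarray(data, dtype=float) - self.mean
        return centered @ self.components / self.singular_values

    def loading_weights(self) -> np.ndarray:
        """Gene-space weights w such that score = w' (u - mean): components / s."""
        return self.components / self.singular_values


def module_pca(x: ExpressionMatrix, modules: ModuleAssignment) -> list[ModulePCA]:
    """Run PCA within each module (label >= 1); unassigned genes are ignored."""
    if modules.n_modules < 1:
        raise ValueError("no modules to decompose")
    out: list[ModulePCA] = []
    for m in range(1, modules.n_modules + 1):
        idx = modules.members(m)
        if idx.size < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        data = x.values[idx].T  # samples x genes
        mean = data.mean(axis=0)
        centered = data - mean
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        tol = s[0] * max(centered.shape) * np.finfo(float).eps if s.size else 0.0
        rank = int((s > tol).sum())
        U, s, V = U[:, :rank], s[:rank], Vt[:rank].T
        # deterministic sign: score column correlates >= 0 with the mean profile
        profile = centered.mean(axis=1)
        for j in range(rank):
            c = float(profile @ U[:, j])
            if c < 0 or (c == 0 and V[np.argmax(np.abs(V[:, j])), j] < 0):
                U[:, j] *= -1
                V[:, j] *= -1
        out.append(
            ModulePCA(
                module_id=m,
                member_gene_ids=[x.gene_ids[i] for i in idx],
                mean=mean,
                components=V,
                singular_values=s,
                scores=U,
                variance_fraction=s**2 / (s**2).sum(),
            )
        )
    return out


def select_pcs_by_variance(pca: ModulePCA, xi: float = 80.0) -> int:
    """Smallest m* whose leading PCs jointly explain at least xi percent."""
    if not 0 < xi <= 100:
        raise ValueError("xi must be in (0, 100]")
    cum = np.cumsum(pca.variance_fraction)
    target = xi / 100.0 - 1e-12
    return int(np.searchsorted(cum, target) + 1)


@dataclasses.dataclass
class FeatureSet:
    """Representative-feature matrix Z (samples x p) with structured indices.

    ``index[c]`` is ``(0, i)`` for the i-th first-order column and ``(i, j)``
    (1 <= i <= j) for the product of first-order columns i and j.
    ``provenance[i] = (module_id, pc_rank)`` maps first-order feature i
    (1-based) to its module and PC number (1 = leading PC).
    """

    kind: str
    Z: np.ndarray
    index: list[tuple[int, int]]
    provenance: dict[int, tuple[int, int]]
    xi: float | None = None

    @property
    def n_first_order(self) -> int:
        return sum(1 for i, _ in self.index if i == 0)

    @property
    def n_features(self) -> int:
        return self.Z.shape[1]

    def first_order_columns(self) -> np.ndarray:
        return self.Z[:, : self.n_first_order]


def _first_order_ranks(pcas: list[ModulePCA], kind: str, xi: float) -> list[tuple[int, int]]:
    """(module position, pc column) pairs defining the first-order features."""
    pairs: list[tuple[int, int]] = []
    for pos, pca in enumerate(pcas):
        top = 1 if kind in ("R1", "R2") else select_pcs_by_variance(pca, xi)
        pairs.extend((pos, r) for r in range(top))
    return pairs


def _assemble(first: np.ndarray, kind: str, provenance: dict, xi: float | None) -> FeatureSet:
    n, P = first.shape
    index: list[tuple[int, int]] = [(0, i) for i in range(1, P + 1)]
    cols = [first]
    if kind in ("R2", "R4"):
        prods = []
        for i in range(1, P + 1):
            for j in range(i, P + 1):
                index.append((i, j))
                prods.append(first[:, i - 1] * first[:, j - 1])
        cols.append(np.column_stack(prods))
    Z = np.column_stack(cols) if len(cols) > 1 else first.copy()
    return FeatureSet(kind=kind, Z=Z, index=index, provenance=provenance, xi=xi)


def build_features(
    pcas: list[ModulePCA], kind: str, xi: float = 80.0
) -> FeatureSet:
    """Build one of the four representative-feature sets from module PCAs."""
    if kind not in KINDS:
        raise ValueError(f"unknown feature kind {kind!r}")
    if not pcas:
        raise ValueError("pcas must be nonempty")
    pairs = _first_order_ranks(pcas, kind, xi)
    first = np.column_stack([pcas[pos].scores[:, r] for pos, r in pairs])
    provenance = {
        i + 1: (pcas[pos].module_id, r + 1) for i, (pos, r) in enumerate(pairs)
    }
    return _assemble(first, kind, provenance, xi if kind in ("R3", "R4") else None)


def project_features(
    x_new: ExpressionMatrix, pcas: list[ModulePCA], template: FeatureSet
) -> FeatureSet:
    """Features for new samples using the *training* loadings and centering.

    The first-order columns are computed by projecting the new samples onto
    each module's stored axes; product columns follow the template's index.
    """
    gene_pos = {g: i for i, g in enumerate(x_new.gene_ids)}
    by_module = {p.module_id: p for p in pcas}
    P = template.n_first_order
    first = np.empty((x_new.n_samples, P))
    proj_cache: dict[int, np.ndarray] = {}
    for i in range(1, P + 1):
        module_id, pc_rank = template.provenance[i]
        pca = by_module[module_id]
        if module_id not in proj_cache:
            try:
                rows = [gene_pos[g] for g in pca.member_gene_ids]
            except KeyError as exc:
                raise ValueError(f"gene {exc.args[0]!r} missing from new data") from exc
            proj_cache[module_id] = pca.transform(x_new.values[rows].T)
        first[:, i - 1] = proj_cache[module_id][:, pc_rank - 1]
    cols = [first]
    second = [(i, j) for i, j in template.index if i >= 1]
    if second:
        cols.append(
            np.column_stack([first[:, i - 1] * first[:, j - 1] for i, j in second])
        )
    Z = np.column_stack(cols) if len(cols) > 1 else first.copy()
    return FeatureSet(
        kind=template.kind,
        Z=Z,
        index=list(template.index),
        provenance=dict(template.provenance),
        xi=template.xi,
    )
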