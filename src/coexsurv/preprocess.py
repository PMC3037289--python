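"""Expression-matrix ingestion and preprocessing.

The standard pipeline for a microarray prognosis dataset is

    read -> KNN-impute missing values -> keep the ``d_keep`` highest-variance
    genes -> rescale every gene to zero median and unit variance.

Screening happens on raw (imputed) values, *before* rescaling: after rescaling
every gene has variance one and a variance screen would be meaningless.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "read_survival",
    "impute_knn",
    "screen_by_variance",
    "rescale",
    "preprocess_pipeline",
]

#: tokens treated as missing in delimited input (empty cells are always missing)
MISSING_TOKENS: tuple[str, ...] = ("NA", "NaN", "nan", "")


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with identifiers.

    ``values[g, s]`` is the expression of gene ``gene_ids[g]`` in sample
    ``sample_ids[s]``; missing entries are ``NaN`` until imputation.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} identifiers: {dup[:5]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.gene_ids), list(self.sample_ids), self.values.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            list(self.gene_ids), [self.sample_ids[i] for i in idx], self.values[:, idx]
        )


def _read_table(path: str | Path, missing_tokens: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=list(missing_tokens),
        keep_default_na=False,
    )
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in column {col!r}: {exc}") from exc
    return df


def read_expression(
    path: str | Path,
    orientation: str = "genes-in-rows",
    missing_tokens: Iterable[str] = MISSING_TOKENS,
) -> ExpressionMatrix:
    """Read a delimited expression matrix (CSV, or TSV for .tsv/.txt/.tab).

    Parameters
    ----------
    orientation:
        ``"genes-in-rows"`` (default) or ``"samples-in-rows"`` (transposed on
        read so the result is always genes x samples).
    missing_tokens:
        Cell values treated as missing, in addition to empty cells.
    """
    if orientation not in {"genes-in-rows", "samples-in-rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, missing_tokens)
    if orientation == "samples-in-rows":
        df = df.T
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def read_survival(path: str | Path):
    """Read right-censored outcomes: CSV with sample id index and (time, status) columns.

    ``status`` is 1 for an observed event and 0 for censoring.  Returns a
    :class:`coexsurv.coxtgdr.SurvivalData`.
    """
    from .coxtgdr import SurvivalData

    df = _read_table(path, MISSING_TOKENS)
    if df.shape[1] < 2:
        raise ValueError("survival file needs two columns: time, status")
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("time", df.columns[0])
    scol = cols.get("status", df.columns[1])
    return SurvivalData(
        time=df[tcol].to_numpy(dtype=float),
        status=df[scol].to_numpy(dtype=int),
        sample_ids=[str(i) for i in df.index],
    )


def impute_knn(x: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Replace each missing entry by the mean of its k nearest gene rows.

    Distance between two gene rows is the root-mean-square difference over the
    samples where both are observed; a neighbor is usable for entry (g, s) only
    if it is observed at sample s.  Observed entries are never changed.  Fewer
    than ``k`` usable neighbors fall back to however many exist.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= x.n_genes:
        raise ValueError("k must be smaller than the number of genes")
    V = x.values.copy()
    obs = ~np.isnan(V)
    if obs.all():
        return ExpressionMatrix(list(x.gene_ids), list(x.sample_ids), V)
    empty = ~obs.any(axis=1)
    if empty.any():
        bad = [x.gene_ids[i] for i in np.flatnonzero(empty)]
        raise ValueError(f"gene(s) with all values missing: {bad[:5]}")

    # pairwise mean squared difference over co-observed samples
    X0 = np.where(obs, V, 0.0)
    M = obs.astype(float)
    cnt = M @ M.T
    sq = X0 * X0
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (sq @ M.T + M @ sq.T - 2.0 * (X0 @ X0.T)) / cnt
    d2[cnt == 0] = np.inf
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)  # guard tiny negative round-off

    out = V.copy()
    for g in np.flatnonzero(~obs.all(axis=1)):
        order = np.argsort(d2[g], kind="stable")
        for s in np.flatnonzero(~obs[g]):
            usable = order[(obs[order, s]) & np.isfinite(d2[g, order])]
            if usable.size == 0:
                raise ValueError(
                    f"no usable neighbor for gene {x.gene_ids[g]!r} at sample "
                    f"{x.sample_ids[s]!r}"
                )
            out[g, s] = V[usable[:k], s].mean()
    return ExpressionMatrix(list(x.gene_ids), list(x.sample_ids), out)


def screen_by_variance(x: ExpressionMatrix, d_keep: int) -> ExpressionMatrix:
    """Keep the ``d_keep`` genes with largest sample variance (ddof=1).

    Ties are broken by input order (first occurrence wins) and the surviving
    genes keep their original relative order.
    """
    if d_keep <= 0:
        raise ValueError("d_keep must be positive")
    if d_keep > x.n_genes:
        raise ValueError("d_keep exceeds the number of genes")
    if np.isnan(x.values).any():
        raise ValueError("screen_by_variance requires a complete matrix; impute first")
    var = x.values.var(axis=1, ddof=1)
    top = np.sort(np.argsort(-var, kind="stable")[:d_keep])
    return ExpressionMatrix(
        [x.gene_ids[i] for i in top], list(x.sample_ids), x.values[top]
    )


def rescale(x: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every gene to zero median and unit (ddof=1) variance."""
    if np.isnan(x.values).any():
        raise ValueError("rescale requires a complete matrix; impute first")
    med = np.median(x.values, axis=1, keepdims=True)
    sd = x.values.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = [x.gene_ids[i] for i in np.flatnonzero(sd.ravel() == 0)]
        raise ValueError(f"constant gene row(s): {bad[:5]}")
    return ExpressionMatrix(
        list(x.gene_ids), list(x.sample_ids), (x.values - med) / sd
    )


def preprocess_pipeline(
    x: ExpressionMatrix, k_impute: int = 10, d_keep: int = 2000
) -> ExpressionMatrix:
    """Impute, screen by variance, then rescale — in that order."""
    x = impute_knn(x, k=k_impute)
    x = screen_by_variance(x, d_keep=min(d_keep, x.n_genes))
    return rescale(x)
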