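"""Synthetic module-structured expression and Cox-model survival.

The generator emulates a microarray prognosis study: genes fall into
coexpression modules driven by per-module latent factors,

    U_g = rho_g F_m + sqrt(1 - rho_g^2) eps,   rho_g ~ Uniform(loading range),

background genes are independent noise, and the matrix is rescaled to zero
median / unit variance per gene.  Survival times follow a Cox model with
constant baseline hazard lambda0 (exponential times) whose linear predictor
uses 10 randomly chosen representative features with Uniform(-0.5, 0.5)
coefficients applied to variance-standardized feature columns; censoring
times are independent exponentials whose rate is calibrated by root-finding
so the expected censoring fraction hits the target (~40%).

:func:`run_study` runs the full cross-specification experiment: per
replicate, generate expression, split train/test, build the network, modules
and all four feature sets on the training half only, draw the truth under a
chosen generating kind, simulate survival for everyone, fit every kind on the
training half and score the test half by logrank statistic and concordance.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import features as feat
from .coxtgdr import SurvivalData, fit_tuned
from .evaluate import concordance_index, logrank_median_split
from .network import build_network
from .preprocess import ExpressionMatrix, rescale

__all__ = [
    "SimConfig",
    "SimResult",
    "gen_expression",
    "draw_true_model",
    "calibrate_censoring",
    "gen_survival",
    "run_study",
]


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the simulator; defaults are desk-scale."""

    n_samples: int = 200                 # split in half into train/test
    n_genes: int = 500
    n_modules: int = 10
    module_sizes: tuple[int, ...] | None = None   # default: 40 genes each
    factor_loading_range: tuple[float, float] = (0.3, 0.9)
    generating_kind: str = "R1"
    n_true_features: int = 10
    coef_range: tuple[float, float] = (-0.5, 0.5)
    baseline_hazard: float = 0.5
    target_censoring: float = 0.40
    n_replicates: int = 500
    xi: float = 80.0
    power_b: float = 6.0
    min_module_size: int = 25
    cut_height: float | None = None
    fitted_kinds: tuple[str, ...] = ("R1", "R2", "R3", "R4")
    V: int = 5
    tau_grid: Sequence[float] = (1.0, 0.75, 0.5, 0.25, 0.0)
    K_max: int = 500
    delta_nu: float = 1e-3
    patience: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = tuple([40] * self.n_modules)
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the gene count")
        if not 0 < self.target_censoring < 1:
            raise ValueError("target_censoring must be in (0, 1)")
        if self.generating_kind not in feat.KINDS:
            raise ValueError(f"unknown generating_kind {self.generating_kind!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["tau_grid"] = list(self.tau_grid)
        d["fitted_kinds"] = list(self.fitted_kinds)
        return d


def gen_expression(cfg: SimConfig, seed: int | None = None) -> ExpressionMatrix:
    """Block latent-factor expression matrix, rescaled per gene."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, d = cfg.n_samples, cfg.n_genes
    V = np.empty((d, n))
    g0 = 0
    lo, hi = cfg.factor_loading_range
    for size in cfg.module_sizes:
        F = rng.standard_normal(n)
        rho = rng.uniform(lo, hi, size=size)
        eps = rng.standard_normal((size, n))
        V[g0 : g0 + size] = rho[:, None] * F[None, :] + np.sqrt(1 - rho**2)[:, None] * eps
        g0 += size
    if g0 < d:
        V[g0:] = rng.standard_normal((d - g0, n))
    x = ExpressionMatrix(
        [f"gene{i:04d}" for i in range(d)],
        [f"s{i:04d}" for i in range(n)],
        V,
    )
    return rescale(x)


def draw_true_model(
    features: feat.FeatureSet, cfg: SimConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pick ``n_true_features`` features uniformly at random and give them
    i.i.d. Uniform(coef_range) coefficients; everything else is noise."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    p = features.n_features
    if p < cfg.n_true_features:
        raise ValueError("fewer features than n_true_features")
    true_idx = np.sort(rng.choice(p, size=cfg.n_true_features, replace=False))
    beta = np.zeros(p)
    beta[true_idx] = rng.uniform(*cfg.coef_range, size=cfg.n_true_features)
    return true_idx, beta


def calibrate_censoring(
    linpred: np.ndarray, lam0: float, target: float, tol: float = 1e-3
) -> float:
    """Exponential censoring rate giving the target expected censoring fraction.

    With T ~ Exp(lam0 * exp(lp)) and C ~ Exp(lam_c) independent,
    P(C < T | lp) = lam_c / (lam_c + lam0 * exp(lp)); the mean over the
    sample's linear predictors is driven to ``target`` by root-finding.
    """
    lp = np.asarray(linpred, dtype=float)
    if not np.isfinite(lp).all():
        raise ValueError("linear predictor must be finite")
    if not 0 < target < 1:
        raise ValueError("target must be in (0, 1)")
    rates = lam0 * np.exp(lp)

    def frac(log_lc: float) -> float:
        lc = np.exp(log_lc)
        return float(np.mean(lc / (lc + rates))) - target

    lo, hi = np.log(lam0) - 30, np.log(lam0) + 30
    if frac(lo) > 0 or frac(hi) < 0:
        raise ValueError("target censoring unreachable for this linear predictor")
    return float(np.exp(brentq(frac, lo, hi, xtol=tol)))


def _standardized_linpred(features: feat.FeatureSet, beta_true: np.ndarray) -> np.ndarray:
    """beta' Z with columns scaled to unit sample variance, so Uniform(-0.5,0.5)
    coefficients represent comparable effect sizes regardless of n."""
    Z = features.Z
    sd = Z.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (Z / sd) @ beta_true


def gen_survival(
    features: feat.FeatureSet,
    beta_true: np.ndarray,
    cfg: SimConfig,
    seed: int | None = None,
) -> SurvivalData:
    """Exponential event times from the Cox model, independent calibrated
    exponential censoring; Y = min(T, C), status = I(T <= C)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lp = _standardized_linpred(features, beta_true)
    rate = cfg.baseline_hazard * np.exp(lp)
    T = rng.exponential(1.0 / rate)
    lam_c = calibrate_censoring(lp, cfg.baseline_hazard, cfg.target_censoring)
    C = rng.exponential(1.0 / lam_c, size=lp.size)
    Y = np.minimum(T, C)
    status = (T <= C).astype(int)
    Y = np.maximum(Y, np.finfo(float).tiny)
    return SurvivalData(time=Y, status=status)


@dataclasses.dataclass
class SimResult:
    table: pd.DataFrame          # replicate, fitted_kind, logrank, concordance
    aggregate: pd.DataFrame      # fitted_kind, mean logrank, mean concordance
    config: SimConfig
    replicate_seeds: list[int]

    def to_dict(self) -> dict:
        return {
            "generating_kind": self.config.generating_kind,
            "n_replicates": int(self.table.replicate.nunique()),
            "aggregate": self.aggregate.to_dict(orient="records"),
        }


def _one_replicate(cfg: SimConfig, seed: int) -> pd.DataFrame:
    ss = np.random.SeedSequence(seed)
    s_expr, s_split, s_truth, s_surv, s_fit = (
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(5)
    )
    x = gen_expression(cfg, seed=s_expr)
    rng = np.random.default_rng(s_split)
    perm = rng.permutation(cfg.n_samples)
    n_train = cfg.n_samples // 2
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    x_tr, x_te = x.subset_samples(tr), x.subset_samples(te)

    _, modules = build_network(
        x_tr, b=cfg.power_b, min_module_size=cfg.min_module_size, cut_height=cfg.cut_height
    )
    if modules.n_modules == 0:
        raise RuntimeError("no modules detected in this replicate")
    pcas = feat.module_pca(x_tr, modules)
    train_sets = {k: feat.build_features(pcas, k, xi=cfg.xi) for k in set(cfg.fitted_kinds) | {cfg.generating_kind}}
    test_sets = {k: feat.project_features(x_te, pcas, train_sets[k]) for k in train_sets}

    gen_tr = train_sets[cfg.generating_kind]
    gen_te = test_sets[cfg.generating_kind]
    _, beta_true = draw_true_model(gen_tr, cfg, seed=s_truth)
    # one combined feature matrix so train and test survival share the truth;
    # test columns are standardized with the same convention
    combined = feat.FeatureSet(
        kind=gen_tr.kind,
        Z=np.vstack([gen_tr.Z, gen_te.Z]),
        index=list(gen_tr.index),
        provenance=dict(gen_tr.provenance),
        xi=gen_tr.xi,
    )
    surv_all = gen_survival(combined, beta_true, cfg, seed=s_surv)
    surv_tr = surv_all.subset(np.arange(len(tr)))
    surv_te = surv_all.subset(np.arange(len(tr), cfg.n_samples))

    rng_fit = np.random.default_rng(s_fit)
    rows = []
    for kind in cfg.fitted_kinds:
        variant = "modified" if kind in ("R2", "R4") else "plain"
        fit = fit_tuned(
            train_sets[kind].Z, surv_tr, V=cfg.V, tau_grid=cfg.tau_grid,
            K_max=cfg.K_max, delta_nu=cfg.delta_nu, variant=variant,
            index=train_sets[kind].index, seed=int(rng_fit.integers(2**31 - 1)),
            patience=cfg.patience,
        )
        scores = fit.risk_scores(test_sets[kind].Z)
        try:
            stat, _ = logrank_median_split(scores, surv_te)
        except ValueError:  # all scores identical (e.g. beta = 0 fit)
            stat = 0.0
        rows.append(
            {
                "fitted_kind": kind,
                "logrank": stat,
                "concordance": concordance_index(scores, surv_te)
                if np.ptp(scores) > 0
                else 0.5,
            }
        )
    return pd.DataFrame(rows)


def run_study(cfg: SimConfig, max_retries: int = 3) -> SimResult:
    """Run the replicate study; failed replicates are resampled (bounded)."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_replicates * (max_retries + 1))
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]
    tables = []
    used_seeds: list[int] = []
    cursor = 0
    for rep in range(cfg.n_replicates):
        last_err: Exception | None = None
        for _ in range(max_retries + 1):
            seed = seeds[cursor]
            cursor += 1
            try:
                t = _one_replicate(cfg, seed)
                t.insert(0, "replicate", rep)
                tables.append(t)
                used_seeds.append(seed)
                last_err = None
                break
            except (RuntimeError, ValueError) as exc:
                last_err = exc
        if last_err is not None:
            raise RuntimeError(f"replicate {rep} failed repeatedly: {last_err}")
    table = pd.concat(tables, ignore_index=True)
    aggregate = (
        table.groupby("fitted_kind", sort=False)[["logrank", "concordance"]]
        .mean()
        .reset_index()
    )
    return SimResult(table=table, aggregate=aggregate, config=cfg, replicate_seeds=used_seeds)
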