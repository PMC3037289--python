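"""Shared fixtures: small synthetic expression matrices and survival data."""

from __future__ import annotations

import numpy as np
import pytest

from coexsurv import ExpressionMatrix, SimConfig, SurvivalData, gen_expression


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expression(rng) -> ExpressionMatrix:
    """12 genes x 10 samples, no structure."""
    return ExpressionMatrix(
        [f"g{i}" for i in range(12)],
        [f"s{i}" for i in range(10)],
        rng.standard_normal((12, 10)),
    )


def planted_expression(
    module_sizes=(30, 30, 30),
    n_background=30,
    n_samples=80,
    loading_range=(0.3, 0.9),
    seed=1,
) -> ExpressionMatrix:
    """Block latent-factor matrix with known module membership."""
    cfg = SimConfig(
        n_samples=n_samples,
        n_genes=sum(module_sizes) + n_background,
        n_modules=len(module_sizes),
        module_sizes=tuple(module_sizes),
        factor_loading_range=loading_range,
        min_module_size=min(module_sizes) // 2,
        seed=seed,
    )
    return gen_expression(cfg, seed=seed)


def planted_labels(module_sizes=(30, 30, 30), n_background=30) -> np.ndarray:
    return np.repeat(
        list(range(1, len(module_sizes) + 1)) + [0], list(module_sizes) + [n_background]
    )


@pytest.fixture
def toy_survival() -> SurvivalData:
    """8 subjects, distinct times, two censored."""
    return SurvivalData(
        time=np.array([2.0, 5.0, 1.0, 8.0, 3.0, 7.0, 4.0, 6.0]),
        status=np.array([1, 1, 1, 0, 1, 1, 0, 1]),
    )


def exponential_survival(n, rng, lam0=0.5, lam_c=0.5) -> SurvivalData:
    """Null survival: Exp(lam0) event times, independent Exp(lam_c) censoring."""
    T = rng.exponential(1.0 / lam0, n)
    C = rng.exponential(1.0 / lam_c, n)
    return SurvivalData(np.minimum(T, C), (T <= C).astype(int))
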