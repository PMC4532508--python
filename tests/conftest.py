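import numpy as np
import pandas as pd
import pytest

from mmisdm import SiteTable, SyntheticConfig, generate_predictor_rasters, sample_sites


def make_site_table(x: np.ndarray, y: np.ndarray,
                    names: list[str] | None = None) -> SiteTable:
    """Site table from a plain design matrix and response."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    names = names or [f"P{i}" for i in range(x.shape[1])]
    df = pd.DataFrame(
        {
            "site_id": [f"S{i}" for i in range(len(y))],
            "x": np.arange(len(y), dtype=float),
            "y": np.zeros(len(y)),
            "presence": np.asarray(y, dtype=int),
        }
    )
    for j, n in enumerate(names):
        df[n] = x[:, j]
    return SiteTable(df, names)


def irls_logistic(design: np.ndarray, y: np.ndarray,
                  tol: float = 1e-12, max_iter: int = 200):
    """Independent Newton–Raphson logistic fit used as the oracle.

    Returns (coefficients, covariance = inverse observed information,
    log-likelihood).
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(design.shape[1])
    for _ in range(max_iter):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        score = design.T @ (y - p)
        info = design.T @ (design * w[:, None])
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = design @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    info = design.T @ (design * (p * (1 - p))[:, None])
    cov = np.linalg.inv(info)
    eps = 1e-12
    pc = np.clip(p, eps, 1 - eps)
    llf = float(np.sum(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
    return beta, cov, llf


@pytest.fixture(scope="session")
def world():
    """Default synthetic study conditions: six correlated climate-like
    predictors on a 100×100 km grid, 204 sites at rare-species
    prevalence."""
    cfg = SyntheticConfig(seed=11)
    rasters = generate_predictor_rasters(cfg)
    sites = sample_sites(rasters, cfg.coefficient_vector(), cfg.n_sites, cfg.seed)
    return cfg, rasters, sites


@pytest.fixture(scope="session")
def trio_sites():
    """204 sites over three independent predictors with a two-predictor
    truth, sized for fast all-subsets enumeration (7 candidates)."""
    rng = np.random.default_rng(7)
    n = 204
    x = rng.standard_normal((n, 3))
    eta = -0.8 - 1.2 * x[:, 0] + 0.6 * x[:, 2]
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    return make_site_table(x, y, ["T1", "T2", "T3"])
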