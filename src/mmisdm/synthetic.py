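"""Synthetic climate surfaces and virtual-species occupancy.

Everything downstream of raw data acquisition is testable against a
known truth generated here: a stack of mutually correlated, spatially
autocorrelated climate-like rasters; a logistic occupancy surface
dominated by a negative temperature-like slope; Bernoulli-sampled
presence/absence sites at rare-species prevalence; a spatially
separated even train/test split; and "future" rasters produced by
additive per-predictor deltas.

Spatial autocorrelation comes from Gaussian-kernel smoothing of white
noise; cross-predictor correlation from an order-preserving empirical
whitening of the raw fields followed by mixing with the Cholesky
factor of the target correlation matrix, so cellwise sample
correlations hit the target essentially exactly while the first
field keeps its dominant north–south gradient (the temperature
analogue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .raster import RasterGrid, check_stack
from .sites import SiteTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_predictor_rasters",
    "true_suitability",
    "sample_sites",
    "split_train_test",
    "make_future_rasters",
]

# Default predictor roster mirrors the retained bioclimatic set of the
# study system: annual mean temperature, diurnal range, isothermality,
# annual precipitation, wettest- and driest-month precipitation.
DEFAULT_PREDICTORS = ("BIO1", "BIO2", "BIO3", "BIO12", "BIO13", "BIO14")

# Rare-species regime: a dominant negative temperature slope, a small
# positive driest-month precipitation slope, and an intercept putting
# prevalence near 0.14 (≈14 presences per 102 sites) on standardized
# predictors.
DEFAULT_COEFFICIENTS = {
    "intercept": -2.8,
    "BIO1": -1.5,
    "BIO2": 0.0,
    "BIO3": 0.0,
    "BIO12": 0.0,
    "BIO13": 0.0,
    "BIO14": 0.5,
}


def _default_correlation(p: int) -> np.ndarray:
    return np.eye(p)


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the virtual-species world.

    Defaults emulate the real study's shape: 1 km² cells, six retained
    predictors, 204 sites split 102/102, rare-species prevalence.
    """

    nrows: int = 100
    ncols: int = 100
    cell_area_km2: float = 1.0
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    correlation: np.ndarray | None = None  # target predictor correlation
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    n_sites: int = 204
    seed: int = 0
    smoothing_sigma: float = 2.0  # cells; spatial autocorrelation range
    gradient_strength: float = 2.0  # dominant N–S gradient of predictor 1
    # additive per-predictor shifts per scenario, on the standardized
    # predictor scale; warming raises the temperature analogue
    future_deltas: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "rcp45_2050": {"BIO1": 1.0},
            "rcp45_2070": {"BIO1": 1.6},
            "rcp85_2050": {"BIO1": 1.4},
            "rcp85_2070": {"BIO1": 2.8},
        }
    )

    def __post_init__(self) -> None:
        if self.nrows < 2 or self.ncols < 2:
            raise ValueError("grid must be at least 2×2")
        if self.n_sites % 2 != 0:
            raise ValueError("n_sites must be even (paired train/test halves)")
        if self.correlation is None:
            self.correlation = _default_correlation(len(self.predictors))
        self.correlation = np.asarray(self.correlation, dtype=float)
        p = len(self.predictors)
        if self.correlation.shape != (p, p):
            raise ValueError("correlation matrix shape must match predictor count")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        eigvals = np.linalg.eigvalsh(self.correlation)
        if eigvals.min() < -1e-10:
            raise ValueError(
                "correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )

    def coefficient_vector(self) -> np.ndarray:
        """(intercept, slope per predictor) in predictor order."""
        beta = [self.coefficients.get("intercept", 0.0)]
        beta += [self.coefficients.get(name, 0.0) for name in self.predictors]
        return np.array(beta, dtype=float)


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    coefficients: np.ndarray  # intercept first, predictor order
    suitability: RasterGrid  # inverse-logit of the true linear predictor
    threshold: float
    range_mask: RasterGrid  # suitability ≥ threshold


def _smooth_field(rng: np.random.Generator, nrows: int, ncols: int,
                  sigma: float) -> np.ndarray:
    z = rng.standard_normal((nrows, ncols))
    if sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
    return z


def generate_predictor_rasters(config: SyntheticConfig) -> dict[str, RasterGrid]:
    """One spatially autocorrelated raster per predictor.

    Cellwise Pearson correlations between layers match
    ``config.correlation`` up to the rank of the target (exactly for a
    full-rank target, by construction). Each layer is standardized to
    zero mean and unit variance over cells.
    """
    p = len(config.predictors)
    rng = np.random.default_rng(config.seed)
    fields = []
    for k in range(p):
        z = _smooth_field(rng, config.nrows, config.ncols, config.smoothing_sigma)
        if k == 0 and config.gradient_strength != 0:
            # temperature analogue: smooth dominant gradient, cold in the
            # north (row 0) — standardization below fixes the scale
            grad = np.linspace(-1.0, 1.0, config.nrows)[:, None]
            grad = np.broadcast_to(grad, z.shape)
            z = config.gradient_strength * grad + (z - z.mean()) / (z.std() + 1e-12)
        fields.append(z.ravel())
    raw = np.column_stack(fields)
    raw -= raw.mean(axis=0)
    # order-preserving empirical whitening: the transformed columns are
    # exactly uncorrelated with unit variance, and column 0 spans the
    # same direction as the raw gradient field
    cov = raw.T @ raw / raw.shape[0]
    lower = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    white = np.linalg.solve(lower, raw.T).T
    # mix to the target correlation; PSD-but-singular targets (e.g. a
    # pair at r = 1) use the symmetric square root instead of Cholesky
    try:
        target_l = np.linalg.cholesky(config.correlation)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(config.correlation)
        target_l = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
    mixed = white @ target_l.T
    stack: dict[str, RasterGrid] = {}
    for k, name in enumerate(config.predictors):
        vals = mixed[:, k].reshape(config.nrows, config.ncols)
        sd = vals.std()
        if sd > 0:
            vals = (vals - vals.mean()) / sd
        stack[name] = RasterGrid(values=vals, cell_area_km2=config.cell_area_km2)
    return stack


def true_suitability(config: SyntheticConfig,
                     rasters: dict[str, RasterGrid],
                     threshold: float = 0.38) -> SyntheticTruth:
    """Inverse-logit occupancy surface implied by the true coefficients."""
    beta = config.coefficient_vector()
    ref = rasters[config.predictors[0]]
    eta = np.full(ref.values.shape, beta[0])
    for k, name in enumerate(config.predictors):
        eta = eta + beta[k + 1] * rasters[name].values
    suit = expit(eta)
    suit_grid = ref.like(suit)
    return SyntheticTruth(
        coefficients=beta,
        suitability=suit_grid,
        threshold=threshold,
        range_mask=ref.like((suit >= threshold).astype(float)),
    )


def sample_sites(rasters: dict[str, RasterGrid],
                 coefficients: np.ndarray,
                 n_sites: int,
                 seed: int,
                 predictors: list[str] | None = None) -> SiteTable:
    """Bernoulli presence/absence at cells drawn without replacement.

    Each site inherits the predictor vector of its cell; presence is a
    Bernoulli draw with probability inverse-logit(beta · (1, x)).
    """
    check_stack(rasters)
    names = list(rasters) if predictors is None else list(predictors)
    ref = rasters[names[0]]
    valid = np.flatnonzero(
        np.all([rasters[n].valid_mask.ravel() for n in names], axis=0)
    )
    if n_sites > valid.size:
        raise ValueError(
            f"n_sites={n_sites} exceeds the {valid.size} valid cells"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(valid, size=n_sites, replace=False))
    rows, cols = np.unravel_index(chosen, ref.values.shape)
    x = np.empty((n_sites, len(names)))
    for k, name in enumerate(names):
        x[:, k] = rasters[name].values[rows, cols]
    beta = np.asarray(coefficients, dtype=float)
    if beta.size != len(names) + 1:
        raise ValueError("coefficient vector must be intercept + one slope per predictor")
    prob = expit(beta[0] + x @ beta[1:])
    presence = rng.binomial(1, prob)
    coords = np.array([ref.cell_center(r, c) for r, c in zip(rows, cols)])
    df = pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(n_sites)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "presence": presence,
        }
    )
    for k, name in enumerate(names):
        df[name] = x[:, k]
    return SiteTable(df, names)


def split_train_test(sites: SiteTable, seed: int = 0) -> tuple[SiteTable, SiteTable]:
    """Spatially interleaved even split into calibration and test halves.

    Sites are ordered along the dominant spatial axis (y, then x, then
    id) and assigned alternately, so near neighbours — including
    co-located sites — land in different halves, damping spatial
    autocorrelation between calibration and evaluation data. The seed
    only chooses which half leads the alternation.
    """
    n = sites.n_sites
    if n % 2 != 0:
        raise ValueError("train/test split requires an even number of sites")
    order = np.lexsort(
        (
            sites.data["site_id"].to_numpy(),
            sites.data["x"].to_numpy(),
            sites.data["y"].to_numpy(),
        )
    )
    start = int(np.random.default_rng(seed).integers(2))
    train_pos = order[start::2]
    test_pos = order[1 - start::2]
    return sites.subset(np.sort(train_pos)), sites.subset(np.sort(test_pos))


def make_future_rasters(rasters: dict[str, RasterGrid],
                        deltas: dict[str, float]) -> dict[str, RasterGrid]:
    """Additive climate-shift scenario: cell + delta, nodata preserved."""
    unknown = set(deltas) - set(rasters)
    if unknown:
        raise ValueError(f"deltas for unknown predictors: {sorted(unknown)}")
    out: dict[str, RasterGrid] = {}
    for name, grid in rasters.items():
        out[name] = grid.like(grid.values + deltas.get(name, 0.0))
    return out
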