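"""Maximum-likelihood logistic regression for candidate occupancy models.

Every candidate in the all-subsets enumeration is a plain binomial GLM
(logit link) fit by maximum likelihood. Fitting is delegated to
statsmodels' IRLS; this module owns the FittedModel contract the
multimodel-inference layer consumes: ordered predictor subset,
coefficients with their covariance (inverse observed information),
maximized log-likelihood, parameter count K and link-scale prediction
variance for the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .sites import SiteTable

__all__ = ["FittedModel", "fit_logistic", "predict_link", "log_likelihood"]

_EPS = 1e-12
# coefficient norms beyond this signal quasi-complete separation
_SEPARATION_NORM = 1e3


@dataclass
class FittedModel:
    """One predictor subset's ML logistic fit."""

    predictors: list[str]  # ordered subset (no intercept)
    coefficients: np.ndarray  # intercept first
    covariance: np.ndarray  # inverse observed information
    log_lik: float
    n: int
    converged: bool
    n_iter: int

    @property
    def K(self) -> int:
        """Number of estimated parameters (intercept + slopes)."""
        return len(self.predictors) + 1

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0, None))

    def design_row(self, values: dict[str, float] | np.ndarray) -> np.ndarray:
        """(1, x_1, …, x_K-1) design vector for one location."""
        if isinstance(values, dict):
            missing = [p for p in self.predictors if p not in values]
            if missing:
                raise KeyError(f"missing predictor value(s): {missing}")
            x = [values[p] for p in self.predictors]
        else:
            x = np.asarray(values, dtype=float)
            if x.shape[-1] != len(self.predictors):
                raise ValueError(
                    f"expected {len(self.predictors)} predictor values, "
                    f"got {x.shape[-1]}"
                )
        return np.concatenate([[1.0], np.asarray(x, dtype=float)])

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": self.coefficients.tolist(),
            "covariance": self.covariance.tolist(),
            "log_lik": self.log_lik,
            "n": self.n,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            predictors=list(d["predictors"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            log_lik=float(d["log_lik"]),
            n=int(d["n"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
        )


def fit_logistic(sites: SiteTable, predictors: list[str],
                 max_iter: int = 50, tol: float = 1e-8) -> FittedModel:
    """Fit a binomial GLM by IRLS on the given predictor subset.

    Perfect or quasi-complete separation (diverging coefficients) and a
    constant response are flagged as non-converged rather than raised:
    with rare species both are live possibilities in an all-subsets
    enumeration, and the candidate set records failures.
    """
    predictors = list(predictors)
    y = sites.presence
    x = sites.predictor_matrix(predictors)
    design = sm.add_constant(x, has_constant="add")
    k = design.shape[1]
    if sites.n_sites < k + 1:
        raise ValueError(
            f"need at least K+1={k + 1} sites to fit {k} parameters"
        )
    if np.linalg.matrix_rank(design) < k:
        raise ValueError(f"rank-deficient design for subset {predictors}")
    converged = True
    if y.min() == y.max():
        # constant response: likelihood is maximized in the limit; report
        # the degenerate fit and flag it
        coef = np.zeros(k)
        coef[0] = 50.0 if y[0] == 1 else -50.0
        return FittedModel(
            predictors=predictors,
            coefficients=coef,
            covariance=np.full((k, k), np.nan),
            log_lik=0.0,
            n=sites.n_sites,
            converged=False,
            n_iter=0,
        )
    model = sm.GLM(y, design, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=max_iter, tol=tol)
    coef = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    n_iter = int(getattr(res, "fit_history", {}).get("iteration", max_iter))
    max_se = np.sqrt(np.clip(np.diag(cov), 0, None)).max() if cov.size else 0.0
    if not np.all(np.isfinite(coef)) or np.linalg.norm(coef) > _SEPARATION_NORM:
        converged = False
    elif not np.all(np.isfinite(cov)) or max_se > _SEPARATION_NORM:
        # the observed information degenerates under (quasi-)separation
        # before the coefficients themselves diverge
        converged = False
    return FittedModel(
        predictors=predictors,
        coefficients=coef,
        covariance=cov,
        log_lik=float(res.llf),
        n=sites.n_sites,
        converged=converged,
        n_iter=n_iter,
    )


def predict_link(model: FittedModel, values) -> tuple[float, float]:
    """Linear predictor and its delta-method variance on the link scale.

    Variance is the quadratic form x' Σ x with Σ the coefficient
    covariance — the within-model ingredient of the averaged
    prediction variance.
    """
    row = model.design_row(values)
    eta = float(row @ model.coefficients)
    var = float(row @ model.covariance @ row)
    return eta, max(var, 0.0)


def log_likelihood(model: FittedModel, sites: SiteTable) -> float:
    """Bernoulli log-likelihood of the fitted model on a site table."""
    x = sites.predictor_matrix(model.predictors)
    eta = model.coefficients[0] + x @ model.coefficients[1:]
    p = np.clip(expit(eta), _EPS, 1 - _EPS)
    y = sites.presence
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
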