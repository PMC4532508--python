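"""Multimodel inference over all-subsets logistic candidates.

The engine implements the information-theoretic workflow of Burnham &
Anderson: fit every non-empty predictor subset, score each candidate
with the small-sample Akaike criterion

    AICc = -2 log L + 2K + 2K(K+1)/(n - K - 1),

convert AICc differences Δ_i to Akaike weights
w_i = exp(-Δ_i/2) / Σ_j exp(-Δ_j/2), take the 95% confidence set (the
shortest AICc-ranked prefix whose cumulative weight reaches the level),
and average coefficients and predictions across it.

Averaged coefficients use zero-substitution by default — a predictor
absent from a model contributes θ_i = 0 — with the unconditional
standard error

    SE_u(θ̄) = sqrt( Σ_i w_i [ SE_i² + (θ_i − θ̄)² ] ),

which folds model-selection uncertainty into the sampling variance.
Averaged predictions carry a total variance S²_T = (weighted mean
within-model variance, delta-method on the response scale) +
(between-model variance of the per-model predictions), and 95%
intervals mean ± 1.96·S_T clipped to [0, 1].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .glm import FittedModel, fit_logistic
from .raster import RasterGrid, check_stack
from .sites import SiteTable

__all__ = [
    "CandidateSet",
    "AveragedModel",
    "AveragedPrediction",
    "aicc",
    "akaike_weights",
    "enumerate_candidates",
    "confidence_set",
    "average_coefficients",
    "predict_averaged",
]

Z95 = 1.96  # the conventional two-sided 95% normal multiplier


def aicc(log_lik: float, K: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n - K - 1 <= 0:
        raise ValueError(
            f"AICc undefined: n - K - 1 = {n - K - 1} must be positive"
        )
    return -2.0 * log_lik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values) -> tuple[np.ndarray, np.ndarray]:
    """ΔAICc and normalized Akaike weights for a set of candidates."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.any(np.isfinite(a)):
        raise ValueError("need at least one finite AICc value")
    delta = a - np.nanmin(a[np.isfinite(a)])
    rel = np.where(np.isfinite(delta), np.exp(-delta / 2.0), 0.0)
    return delta, rel / rel.sum()


@dataclass
class CandidateSet:
    """AICc-ranked candidate models with weights and confidence flags."""

    models: list[FittedModel]  # ranked by AICc, best first
    aicc_values: np.ndarray
    delta: np.ndarray
    weights: np.ndarray
    level: float | None = None
    in_confidence_set: np.ndarray | None = None
    member_weights: np.ndarray | None = None  # renormalized within the set
    failed_subsets: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def member_models(self) -> list[FittedModel]:
        if self.in_confidence_set is None:
            return list(self.models)
        return [m for m, f in zip(self.models, self.in_confidence_set) if f]

    def member_weight_values(self) -> np.ndarray:
        if self.member_weights is None:
            return self.weights
        return self.member_weights[self.in_confidence_set]

    def selection_table(self) -> pd.DataFrame:
        """Model-selection summary (model, K, AICc, ΔAICc, w)."""
        rows = []
        for m, a, d, w in zip(self.models, self.aicc_values, self.delta, self.weights):
            rows.append(
                {
                    "model": " + ".join(m.predictors),
                    "K": m.K,
                    "AICc": a,
                    "delta_AICc": d,
                    "weight": w,
                    "in_confidence_set": bool(self.in_confidence_set[
                        len(rows)]) if self.in_confidence_set is not None else True,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class AveragedModel:
    """Composite model: weight-averaged coefficients over the union."""

    predictors: list[str]  # union, ordered
    estimates: np.ndarray  # intercept first
    unconditional_se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    mode: str = "zero"  # "zero" (zero-substitution) or "natural"

    def coefficient_table(self) -> pd.DataFrame:
        names = ["intercept"] + self.predictors
        return pd.DataFrame(
            {
                "parameter": names,
                "estimate": self.estimates,
                "unconditional_se": self.unconditional_se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self.estimates[0] + x @ self.estimates[1:]


@dataclass
class AveragedPrediction:
    """Model-averaged suitability with its variance decomposition."""

    mean: np.ndarray  # composite-model probability
    within_var: np.ndarray  # weighted delta-method variance, response scale
    between_var: np.ndarray  # weighted spread of per-model predictions
    total_var: np.ndarray  # S²_T = within + between
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    variance_ratio: np.ndarray  # between / within; NaN where within = 0

    @property
    def total_se(self) -> np.ndarray:
        return np.sqrt(self.total_var)

    @property
    def ci_width(self) -> np.ndarray:
        return self.ci_upper - self.ci_lower


def enumerate_candidates(train: SiteTable,
                         predictors: list[str] | None = None,
                         max_predictors: int = 20) -> CandidateSet:
    """Fit every non-empty predictor subset and rank by AICc.

    Subsets that fail to fit (separation, rank deficiency) are recorded
    and excluded from the weight normalization.
    """
    names = train.predictors if predictors is None else list(predictors)
    p = len(names)
    if not 1 <= p <= max_predictors:
        raise ValueError(f"need 1–{max_predictors} predictors, got {p}")
    fitted: list[FittedModel] = []
    failed: list[tuple[str, ...]] = []
    for size in range(1, p + 1):
        for subset in itertools.combinations(names, size):
            try:
                m = fit_logistic(train, list(subset))
            except ValueError:
                failed.append(subset)
                continue
            if not m.converged:
                failed.append(subset)
                continue
            fitted.append(m)
    if failed:
        warnings.warn(
            f"{len(failed)} candidate subset(s) failed to fit and were "
            "excluded from the weights",
            stacklevel=2,
        )
    if not fitted:
        raise ValueError("no candidate model could be fitted")
    scores = np.array([aicc(m.log_lik, m.K, m.n) for m in fitted])
    order = np.argsort(scores, kind="stable")
    models = [fitted[i] for i in order]
    scores = scores[order]
    delta, weights = akaike_weights(scores)
    return CandidateSet(
        models=models,
        aicc_values=scores,
        delta=delta,
        weights=weights,
        failed_subsets=failed,
    )


def confidence_set(cands: CandidateSet, level: float = 0.95) -> CandidateSet:
    """Flag the shortest ranked prefix with cumulative weight ≥ level.

    Member weights are renormalized to sum to 1 within the set (stored
    separately; global weights are untouched).
    """
    if not 0 < level <= 1:
        raise ValueError("confidence level must be in (0, 1]")
    cum = np.cumsum(cands.weights)
    # first index where the cumulative weight reaches the level
    cut = int(np.searchsorted(cum, level - 1e-12)) + 1
    cut = min(cut, cands.n_models)
    flags = np.zeros(cands.n_models, dtype=bool)
    flags[:cut] = True
    member = np.where(flags, cands.weights, 0.0)
    member = member / member.sum()
    cands.level = level
    cands.in_confidence_set = flags
    cands.member_weights = member
    return cands


def _union_predictors(models: list[FittedModel], order_hint: list[str] | None = None) -> list[str]:
    seen: list[str] = []
    for m in models:
        for p in m.predictors:
            if p not in seen:
                seen.append(p)
    if order_hint:
        hinted = [p for p in order_hint if p in seen]
        return hinted + [p for p in seen if p not in hinted]
    return seen


def average_coefficients(cands: CandidateSet,
                         mode: str = "zero",
                         order_hint: list[str] | None = None) -> AveragedModel:
    """Weight-average coefficients across the confidence set.

    mode="zero": absent predictors contribute θ_i = 0 with SE_i = 0
    (shrinks weakly supported effects toward zero). mode="natural":
    averages only over the models containing each predictor, with
    weights renormalized among them.
    """
    if mode not in ("zero", "natural"):
        raise ValueError("mode must be 'zero' or 'natural'")
    models = cands.member_models()
    if not models:
        raise ValueError("empty confidence set")
    w = np.asarray(cands.member_weight_values(), dtype=float)
    w = w / w.sum()
    union = _union_predictors(models, order_hint)
    n_par = len(union) + 1
    theta = np.zeros((len(models), n_par))
    se = np.zeros((len(models), n_par))
    present = np.zeros((len(models), n_par), dtype=bool)
    present[:, 0] = True  # every model has an intercept
    for i, m in enumerate(models):
        ses = m.standard_errors
        theta[i, 0] = m.coefficients[0]
        se[i, 0] = ses[0]
        for j, p in enumerate(m.predictors):
            col = union.index(p) + 1
            theta[i, col] = m.coefficients[j + 1]
            se[i, col] = ses[j + 1]
            present[i, col] = True
    if mode == "zero":
        eff_w = np.repeat(w[:, None], n_par, axis=1)
    else:
        eff_w = np.where(present, w[:, None], 0.0)
        totals = eff_w.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("a union predictor appears in no member model")
        eff_w = eff_w / totals
    est = (eff_w * theta).sum(axis=0)
    unc_var = (eff_w * (se**2 + (theta - est) ** 2)).sum(axis=0)
    unc_se = np.sqrt(unc_var)
    return AveragedModel(
        predictors=union,
        estimates=est,
        unconditional_se=unc_se,
        ci_lower=est - Z95 * unc_se,
        ci_upper=est + Z95 * unc_se,
        mode=mode,
    )


def _predict_matrix(cands: CandidateSet, avg: AveragedModel,
                    x: np.ndarray) -> AveragedPrediction:
    """Averaged prediction for an (n_points × union predictors) matrix."""
    models = cands.member_models()
    w = np.asarray(cands.member_weight_values(), dtype=float)
    w = w / w.sum()
    n_pts = x.shape[0]
    # composite-model mean on the link scale, back-transformed
    mean = expit(avg.linear_predictor(x))
    p_i = np.empty((len(models), n_pts))
    var_i = np.empty((len(models), n_pts))
    for i, m in enumerate(models):
        cols = [avg.predictors.index(p) for p in m.predictors]
        design = np.column_stack([np.ones(n_pts), x[:, cols]])
        eta = design @ m.coefficients
        var_link = np.einsum("ij,jk,ik->i", design, m.covariance, design)
        p = expit(eta)
        p_i[i] = p
        # delta method: response-scale variance via d expit/d eta = p(1-p)
        var_i[i] = np.clip(var_link, 0, None) * (p * (1 - p)) ** 2
    within = w @ var_i
    p_bar = w @ p_i
    between = w @ (p_i - p_bar) ** 2
    total = within + between
    se = np.sqrt(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(within > 0, between / within, np.nan)
    return AveragedPrediction(
        mean=mean,
        within_var=within,
        between_var=between,
        total_var=total,
        ci_lower=np.clip(mean - Z95 * se, 0.0, 1.0),
        ci_upper=np.clip(mean + Z95 * se, 0.0, 1.0),
        variance_ratio=ratio,
    )


def predict_averaged(cands: CandidateSet, avg: AveragedModel,
                     values) -> AveragedPrediction:
    """Model-averaged suitability with S²_T decomposition.

    ``values`` may be a single predictor dict, an (n × p) matrix over
    the averaged model's predictor union, or a raster stack keyed by
    predictor name (NaN cells propagate to NaN outputs).
    """
    if isinstance(values, dict) and values and isinstance(
        next(iter(values.values())), RasterGrid
    ):
        return _predict_stack(cands, avg, values)
    if isinstance(values, dict):
        missing = [p for p in avg.predictors if p not in values]
        if missing:
            raise KeyError(f"missing predictor value(s): {missing}")
        x = np.array([[values[p] for p in avg.predictors]], dtype=float)
        pred = _predict_matrix(cands, avg, x)
        return AveragedPrediction(
            *(np.asarray(getattr(pred, f))[0] for f in (
                "mean", "within_var", "between_var", "total_var",
                "ci_lower", "ci_upper", "variance_ratio",
            ))
        )
    x = np.atleast_2d(np.asarray(values, dtype=float))
    if x.shape[1] != len(avg.predictors):
        raise ValueError(
            f"expected {len(avg.predictors)} predictor columns, got {x.shape[1]}"
        )
    return _predict_matrix(cands, avg, x)


def _predict_stack(cands: CandidateSet, avg: AveragedModel,
                   stack: dict[str, RasterGrid]) -> dict[str, RasterGrid]:
    check_stack(stack)
    missing = [p for p in avg.predictors if p not in stack]
    if missing:
        raise KeyError(f"raster stack missing predictor(s): {missing}")
    ref = stack[avg.predictors[0]]
    shape = ref.values.shape
    flat = np.column_stack([stack[p].values.ravel() for p in avg.predictors])
    valid = ~np.isnan(flat).any(axis=1)
    pred = _predict_matrix(cands, avg, flat[valid])
    out: dict[str, RasterGrid] = {}
    for name in ("mean", "within_var", "between_var", "total_var",
                 "ci_lower", "ci_upper", "variance_ratio"):
        full = np.full(flat.shape[0], np.nan)
        full[valid] = getattr(pred, name)
        out[name] = ref.like(full.reshape(shape))
    out["ci_width"] = ref.like(out["ci_upper"].values - out["ci_lower"].values)
    return out
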