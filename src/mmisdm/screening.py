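"""Collinearity screening of the candidate predictor pool.

Highly correlated predictor pairs (|Pearson r| above a threshold,
default 0.70) are resolved by dropping the member with the weaker
univariate association with presence, measured as the absolute
point-biserial correlation between predictor and the 0/1 response.
Elimination is greedy on the strongest remaining pair, and the whole
decision trail is kept for audit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sites import SiteTable

__all__ = ["ScreeningReport", "pearson_matrix", "screen_predictors"]


@dataclass
class Elimination:
    dropped: str
    kept: str
    r: float  # correlation of the triggering pair
    dropped_strength: float  # |point-biserial| with presence
    kept_strength: float
    note: str = ""


@dataclass
class ScreeningReport:
    correlation: pd.DataFrame  # full matrix over the input pool
    retained: list[str]
    eliminations: list[Elimination] = field(default_factory=list)
    threshold: float = 0.70
    strengths: dict[str, float] = field(default_factory=dict)

    @property
    def eliminated(self) -> list[str]:
        return [e.dropped for e in self.eliminations]

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "retained": self.retained,
                "eliminations": [
                    {
                        "dropped": e.dropped,
                        "kept": e.kept,
                        "r": e.r,
                        "dropped_strength": e.dropped_strength,
                        "kept_strength": e.kept_strength,
                        "note": e.note,
                    }
                    for e in self.eliminations
                ],
                "strengths": self.strengths,
            },
            indent=2,
        )


def pearson_matrix(sites: SiteTable, predictors: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson r over sites; errors on constant predictors."""
    names = sites.predictors if predictors is None else list(predictors)
    if sites.n_sites < 3:
        raise ValueError("need at least 3 sites for a correlation matrix")
    x = sites.predictor_matrix(names)
    sds = x.std(axis=0)
    constant = [n for n, s in zip(names, sds) if s == 0]
    if constant:
        raise ValueError(f"constant predictor(s) with zero variance: {constant}")
    r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names)


def _point_biserial(sites: SiteTable, names: list[str]) -> dict[str, float]:
    y = sites.presence.astype(float)
    if y.std() == 0:
        # response constant: no association signal; all strengths 0
        return {n: 0.0 for n in names}
    x = sites.predictor_matrix(names)
    out = {}
    for k, n in enumerate(names):
        out[n] = float(np.corrcoef(x[:, k], y)[0, 1])
    return out


def screen_predictors(sites: SiteTable,
                      predictors: list[str] | None = None,
                      threshold: float = 0.70) -> ScreeningReport:
    """Greedy elimination of the weaker member of each |r| > threshold pair.

    While any retained pair exceeds the threshold, the highest-|r| pair
    is taken (name-order tie-break) and its member with the smaller
    |point-biserial| correlation with presence is dropped (ties drop
    the later name).
    """
    names = sites.predictors if predictors is None else list(predictors)
    corr = pearson_matrix(sites, names)
    strengths = _point_biserial(sites, names)
    retained = list(names)
    eliminations: list[Elimination] = []
    while len(retained) > 1:
        sub = corr.loc[retained, retained].to_numpy()
        absr = np.abs(sub)
        np.fill_diagonal(absr, 0.0)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= threshold:
            break
        a, b = sorted((retained[i], retained[j]))
        sa, sb = abs(strengths[a]), abs(strengths[b])
        if sa > sb or (sa == sb and a < b):
            kept, dropped = a, b
        else:
            kept, dropped = b, a
        note = "tie broken by name order" if sa == sb else ""
        eliminations.append(
            Elimination(
                dropped=dropped,
                kept=kept,
                r=float(corr.loc[a, b]),
                dropped_strength=abs(strengths[dropped]),
                kept_strength=abs(strengths[kept]),
                note=note,
            )
        )
        retained.remove(dropped)
    if len(retained) == 1 and eliminations:
        warnings.warn(
            "all predictors mutually correlated above the threshold; "
            f"retaining only {retained[0]!r}",
            stacklevel=2,
        )
    return ScreeningReport(
        correlation=corr,
        retained=retained,
        eliminations=eliminations,
        threshold=threshold,
        strengths={n: abs(v) for n, v in strengths.items()},
    )
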