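"""Range projection under current and shifted climate surfaces.

The averaged model is pushed through each scenario's predictor stack,
suitability is classified by a fixed occurrence threshold (cell
suitable iff suitability ≥ threshold), and suitable area per scenario
is compared with the baseline as a percent loss
(baseline − scenario) / baseline × 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mmi import AveragedModel, CandidateSet, predict_averaged
from .raster import RasterGrid, check_stack

__all__ = [
    "ScenarioResult",
    "project_suitability",
    "classify_range",
    "suitable_area",
    "area_and_change",
    "scenario_table",
]


@dataclass
class ScenarioResult:
    scenario: str
    threshold: float
    suitable_cells: int
    suitable_area_km2: float
    baseline_area_km2: float
    percent_change: float  # positive = habitat loss vs baseline

    def as_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "threshold": self.threshold,
            "suitable_cells": self.suitable_cells,
            "suitable_area_km2": self.suitable_area_km2,
            "baseline_area_km2": self.baseline_area_km2,
            "percent_change": round(self.percent_change, 2),
        }


def project_suitability(cands: CandidateSet, avg: AveragedModel,
                        stack: dict[str, RasterGrid]) -> dict[str, RasterGrid]:
    """Per-cell averaged suitability, CI and variance fields for a stack."""
    check_stack(stack)
    return predict_averaged(cands, avg, stack)


def classify_range(suitability: RasterGrid, threshold: float) -> RasterGrid:
    """Binary range raster: 1 where suitability ≥ threshold, NaN preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    vals = suitability.values
    out = np.where(np.isnan(vals), np.nan, (vals >= threshold).astype(float))
    return suitability.like(out)


def suitable_area(binary: RasterGrid) -> tuple[int, float]:
    """(suitable cell count, area in km²) of a binary range raster."""
    count = int(np.nansum(binary.values == 1.0))
    return count, count * binary.cell_area_km2


def area_and_change(baseline: RasterGrid,
                    scenarios: dict[str, RasterGrid],
                    threshold: float,
                    baseline_label: str = "current") -> list[ScenarioResult]:
    """Suitable area per scenario and percent change vs baseline.

    Inputs are binary range rasters sharing the baseline's geometry.
    The baseline row is included with percent change 0.
    """
    for name, grid in scenarios.items():
        if not grid.same_geometry(baseline):
            raise ValueError(f"scenario '{name}' geometry differs from baseline")
    base_count, base_area = suitable_area(baseline)
    results = [
        ScenarioResult(
            scenario=baseline_label,
            threshold=threshold,
            suitable_cells=base_count,
            suitable_area_km2=base_area,
            baseline_area_km2=base_area,
            percent_change=0.0,
        )
    ]
    for name, grid in scenarios.items():
        count, area = suitable_area(grid)
        if base_area == 0:
            change = np.nan  # undefined without baseline habitat
        else:
            change = (base_area - area) / base_area * 100.0
        results.append(
            ScenarioResult(
                scenario=name,
                threshold=threshold,
                suitable_cells=count,
                suitable_area_km2=area,
                baseline_area_km2=base_area,
                percent_change=float(change),
            )
        )
    return results


def scenario_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Areal-change summary with percent change rounded to 2 decimals."""
    return pd.DataFrame([r.as_row() for r in results])
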