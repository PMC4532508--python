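"""Site tables: presence/absence records with predictor values.

A SiteTable is the modelling currency of the pipeline: one row per
survey site carrying an id, planar coordinates, a binary presence flag
for the species group, and one numeric column per climate predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SiteTable", "read_site_table", "write_site_table"]

_CORE_COLUMNS = ["site_id", "x", "y", "presence"]


@dataclass
class SiteTable:
    """Validated table of survey sites.

    ``data`` holds columns ``site_id, x, y, presence`` plus one column
    per name in ``predictors`` (order defines the canonical column
    order). ``presence`` is strictly 0/1.
    """

    data: pd.DataFrame
    predictors: list[str]

    def __post_init__(self) -> None:
        self.predictors = list(self.predictors)
        missing = [c for c in _CORE_COLUMNS + self.predictors if c not in self.data.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        self.data = self.data[_CORE_COLUMNS + self.predictors].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        ids = self.data["site_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate site ids: {dupes[:5]}")
        pres = self.data["presence"]
        bad = ~pres.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"presence must be 0/1; row {row} (site_id="
                f"{ids.iloc[row]!r}) has value {pres.iloc[row]!r}"
            )
        cols = ["x", "y"] + self.predictors
        if self.data[cols].isna().any().any():
            bad_cols = self.data[cols].columns[self.data[cols].isna().any()].tolist()
            raise ValueError(f"missing values in columns: {bad_cols}")

    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def presence(self) -> np.ndarray:
        return self.data["presence"].to_numpy(dtype=int)

    @property
    def prevalence(self) -> float:
        return float(self.data["presence"].mean())

    @property
    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def predictor_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Sites × predictors value matrix (no intercept column)."""
        names = self.predictors if names is None else list(names)
        unknown = [n for n in names if n not in self.predictors]
        if unknown:
            raise KeyError(f"unknown predictors: {unknown}")
        return self.data[names].to_numpy(dtype=float)

    def subset(self, index) -> "SiteTable":
        return SiteTable(self.data.iloc[index].reset_index(drop=True), self.predictors)

    def select_predictors(self, names: list[str]) -> "SiteTable":
        unknown = [n for n in names if n not in self.predictors]
        if unknown:
            raise KeyError(f"unknown predictors: {unknown}")
        return SiteTable(self.data[_CORE_COLUMNS + list(names)], list(names))


def read_site_table(path) -> SiteTable:
    """Read and validate a site CSV; predictor names come from the header."""
    df = pd.read_csv(path)
    predictors = [c for c in df.columns if c not in _CORE_COLUMNS]
    return SiteTable(df, predictors)


def write_site_table(sites: SiteTable, path) -> None:
    sites.data.to_csv(path, index=False)
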