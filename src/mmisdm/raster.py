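"""Regular-grid raster container and ESRI ASCII grid I/O.

Rasters carry one predictor or output field on a regular grid. Missing
cells are represented as NaN in memory and as the declared NODATA value
on disk. All layers of a stack must share geometry (shape, origin,
cell size); :func:`check_stack` enforces this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RasterGrid", "read_ascii_raster", "write_ascii_raster", "check_stack"]


@dataclass
class RasterGrid:
    """One gridded field.

    Parameters
    ----------
    values
        2-D float array (rows × cols), NaN marking nodata. Row 0 is the
        northernmost row, matching the ESRI ASCII layout.
    cellsize
        Cell edge length in abstract planar units (1 unit ≈ 1 km for the
        default configuration, giving 1 km² cells).
    xllcorner, yllcorner
        Coordinates of the lower-left corner.
    nodata
        Value used for missing cells on disk.
    cell_area_km2
        Area represented by one cell, used for areal summaries.
    """

    values: np.ndarray
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0
    cell_area_km2: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New raster with the same geometry but different values."""
        if values.shape != self.values.shape:
            raise ValueError(
                f"shape {values.shape} does not match raster geometry "
                f"{self.values.shape}"
            )
        return replace(self, values=np.asarray(values, dtype=float))

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of a cell center; row 0 is the top (north) row."""
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - row - 0.5) * self.cellsize
        return x, y

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.cellsize, other.cellsize)
            and math.isclose(self.xllcorner, other.xllcorner)
            and math.isclose(self.yllcorner, other.yllcorner)
        )


def check_stack(stack: dict[str, RasterGrid]) -> None:
    """Raise if the layers of a predictor stack disagree on geometry."""
    if not stack:
        raise ValueError("empty raster stack")
    names = list(stack)
    ref = stack[names[0]]
    for name in names[1:]:
        if not stack[name].same_geometry(ref):
            raise ValueError(
                f"raster geometry mismatch: layer '{name}' does not match "
                f"layer '{names[0]}'"
            )


def write_ascii_raster(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_raster(path, cell_area_km2: float | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc).

    If ``cell_area_km2`` is not given it is derived from the header cell
    size under the convention that one planar unit is one kilometre.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value", "xllcenter", "yllcenter",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ESRI ASCII header: missing '{key}'")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    body = "".join(lines[n_header:])
    values = np.array(body.split(), dtype=float)
    if values.size != nrows * ncols:
        raise ValueError(
            f"ESRI ASCII body has {values.size} values, expected "
            f"{nrows}×{ncols} = {nrows * ncols}"
        )
    values = values.reshape(nrows, ncols)
    values[values == nodata] = np.nan
    if cell_area_km2 is None:
        cell_area_km2 = header["cellsize"] ** 2
    return RasterGrid(
        values=values,
        cellsize=header["cellsize"],
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        nodata=nodata,
        cell_area_km2=cell_area_km2,
    )
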