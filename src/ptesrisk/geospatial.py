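"""Inverse-distance-weighted interpolation onto regular grids.

The geochemical distribution maps are continuous surfaces built from the
15 station values by IDW: ẑ(q) = Σ wᵢzᵢ / Σ wᵢ with wᵢ = dᵢ⁻ᵖ over the
k nearest samples (all samples by default, power p = 2). A query closer
than ε = 1e-12 to a sample returns that sample's value exactly, so IDW
is an exact interpolator, and every estimate is a convex combination of
sample values (bounded by their min and max).

Distances are planar Euclidean on the supplied coordinates; for
longitude/latitude input the surface is method-faithful but not
geodesic — a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import ConcentrationTable

ZERO_DISTANCE_EPS = 1e-12
NODATA = -9999.0


class IDWRegressor(BaseEstimator, RegressorMixin):
    """Inverse-distance-weighted spatial regressor.

    Parameters
    ----------
    power : float, default 2.0
        Distance decay exponent p > 0; large p approaches
        nearest-neighbor interpolation.
    max_neighbors : int or None, default None
        Use only the k nearest samples per query; None uses all.
    eps : float, default 1e-12
        Distance below which a query is snapped to the sample value.
    """

    def __init__(self, power: float = 2.0, max_neighbors: int | None = None,
                 eps: float = ZERO_DISTANCE_EPS):
        self.power = power
        self.max_neighbors = max_neighbors
        self.eps = eps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of planar coordinates")
        if len(X) == 0:
            raise ValueError("IDW needs at least one sample")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if self.power <= 0:
            raise ValueError("power must be > 0")
        self.X_ = X
        self.y_ = y
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        # (m, n) pairwise distances
        d = np.sqrt(((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2))
        out = np.empty(len(X))
        for i in range(len(X)):
            di = d[i]
            hit = np.where(di < self.eps)[0]
            if hit.size:
                out[i] = self.y_[hit[0]]
                continue
            if self.max_neighbors is not None and self.max_neighbors < len(di):
                sel = np.argpartition(di, self.max_neighbors)[: self.max_neighbors]
            else:
                sel = slice(None)
            w = di[sel] ** (-self.power)
            out[i] = (w * self.y_[sel]).sum() / w.sum()
        return out


def idw_point(samples, query, power: float = 2.0,
              max_neighbors: int | None = None) -> float:
    """IDW estimate at one query point from (x, y, z) samples."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("IDW needs at least one sample")
    reg = IDWRegressor(power=power, max_neighbors=max_neighbors)
    reg.fit(samples[:, :2], samples[:, 2])
    return float(reg.predict([query])[0])


@dataclass
class GridRaster:
    """Regular row-major grid of interpolated values.

    Row 0 is the top (northernmost) row, matching the ESRI ASCII
    convention; the origin is the lower-left corner of the grid.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray  # (n_rows, n_cols), NODATA where masked
    element: str = ""
    medium: str = ""
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, y decreasing with row index."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows)[::-1] + 0.5) * self.cell_size
        return xs, ys


def idw_grid(table: ConcentrationTable, element: str,
             origin: tuple[float, float], cell_size: float,
             n_rows: int, n_cols: int, power: float = 2.0,
             max_neighbors: int | None = None,
             mask: np.ndarray | None = None) -> GridRaster:
    """Interpolate one element of a station table onto a regular grid.

    ``mask`` (boolean, True = keep) lets callers blank cells outside the
    study area; masked cells carry the nodata sentinel.
    """
    if element not in table.values.columns:
        raise KeyError(f"element {element!r} not in table")
    if table.coordinates is None:
        raise ValueError("table has no station coordinates")
    z = table.values[element]
    ok = z.notna()
    reg = IDWRegressor(power=power, max_neighbors=max_neighbors)
    reg.fit(table.coordinates.loc[ok, ["x", "y"]].to_numpy(), z[ok].to_numpy())

    raster = GridRaster(origin=origin, cell_size=cell_size,
                        values=np.full((n_rows, n_cols), NODATA),
                        element=element, medium=table.medium)
    xs, ys = raster.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    est = reg.predict(pts).reshape(n_rows, n_cols)
    if mask is not None:
        est = np.where(mask, est, NODATA)
    raster.values = est
    return raster


def write_raster(raster: GridRaster, path, fmt: str = "esri_ascii") -> None:
    """Write a raster as ESRI ASCII grid or x,y,value CSV triples."""
    path = Path(path)
    if fmt == "esri_ascii":
        lines = [
            f"ncols {raster.n_cols}",
            f"nrows {raster.n_rows}",
            f"xllcorner {float(raster.origin[0])!r}",
            f"yllcorner {float(raster.origin[1])!r}",
            f"cellsize {float(raster.cell_size)!r}",
            f"NODATA_value {float(raster.nodata)!r}",
        ]
        for row in raster.values:
            lines.append(" ".join(repr(float(v)) for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "csv":
        xs, ys = raster.cell_centers()
        with path.open("w") as fh:
            fh.write("x,y,value\n")
            for i, y in enumerate(ys):
                for j, x in enumerate(xs):
                    fh.write(
                        f"{float(x)!r},{float(y)!r},{float(raster.values[i, j])!r}\n"
                    )
    else:
        raise ValueError(f"format must be esri_ascii|csv, got {fmt!r}")


def read_raster(path) -> GridRaster:
    """Read an ESRI ASCII grid written by :func:`write_raster`."""
    lines = Path(path).read_text().strip().splitlines()
    header = {}
    for line in lines[:6]:
        key, val = line.split(None, 1)
        header[key.lower()] = float(val)
    values = np.array([[float(v) for v in line.split()] for line in lines[6:]])
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("raster body does not match header dimensions")
    return GridRaster(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        values=values,
        nodata=header["nodata_value"],
    )
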