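"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

Rasters here are small synthetic covariate surfaces on a projected metric
grid: row 0 is the northernmost row, ``origin_x``/``origin_y`` are the
coordinates of the *top-left corner* of the grid, and cells are square.
The ESRI ASCII grid format is used for storage because it is plain text and
readable by every GIS; note the format's header records the *lower-left*
corner, which is converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DomainError

DEFAULT_NODATA = -9999.0


@dataclass
class RasterLayer:
    """A single-band grid of floats on a projected metric coordinate system.

    Parameters
    ----------
    values
        2-D array, row 0 = northernmost row.
    origin_x, origin_y
        Projected coordinates (m) of the grid's top-left corner.
    cell_size
        Side length of a (square) cell in meters.
    nodata
        Sentinel for missing cells.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 30.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ConfigurationError(
                f"raster grid must be 2-D with >= 2 rows and columns, got shape {self.values.shape}"
            )
        if not self.cell_size > 0:
            raise ConfigurationError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def same_geometry(self, other: "RasterLayer") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
        )

    # -- coordinate transforms -------------------------------------------------

    def rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map projected coordinates to (row, col) indices (nearest cell).

        Points are assigned to the cell whose square they fall in; indices may
        be out of range, use :meth:`inside` to test containment.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        return row, col

    def inside(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.rowcol(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell sample; raises DomainError for points off the grid."""
        row, col = self.rowcol(x, y)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        if not np.all(ok):
            bad = np.argwhere(~np.atleast_1d(ok))[:3].ravel()
            raise DomainError(f"points off the raster extent (first indices: {bad.tolist()})")
        return self.values[row, col]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, shaped like values."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_y,
        )

    # -- I/O -------------------------------------------------------------------

    def write_ascii(self, path: str | Path, fmt: str = "%.6g") -> None:
        """Write as an ESRI ASCII grid (header uses the lower-left corner)."""
        path = Path(path)
        yll = self.origin_y - self.n_rows * self.cell_size
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin_x!r}\n"
            f"yllcorner {yll!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterLayer":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        n_rows = int(header["nrows"])
        cell = header["cellsize"]
        return cls(
            values=values.reshape(n_rows, int(header["ncols"])),
            origin_x=header["xllcorner"],
            origin_y=header["yllcorner"] + n_rows * cell,
            cell_size=cell,
            nodata=header.get("nodata_value", DEFAULT_NODATA),
        )


@dataclass
class CovariateStack:
    """Aligned covariate layers used to annotate strata.

    ``canopy`` is percent canopy in [0, 100]; ``water`` a {0,1} mask;
    ``elevation`` in meters. ``dist_water`` (m) and ``sri`` (dimensionless)
    are derived on demand by :func:`thermalsteps.covariates.derive_stack`.
    """

    canopy: RasterLayer
    water: RasterLayer
    elevation: RasterLayer
    dist_water: RasterLayer | None = None
    sri: RasterLayer | None = None
    latitude: float = field(default=np.deg2rad(65.0))

    def __post_init__(self) -> None:
        for name, layer in (("water", self.water), ("elevation", self.elevation)):
            if not self.canopy.same_geometry(layer):
                raise ConfigurationError(f"layer '{name}' not aligned with canopy layer")
        c = self.canopy.values
        valid = c != self.canopy.nodata
        if valid.any() and (c[valid].min() < 0 or c[valid].max() > 100):
            raise ConfigurationError("canopy layer must lie in [0, 100]")
        w = self.water.values
        wvalid = w != self.water.nodata
        if not np.isin(w[wvalid], (0.0, 1.0)).all():
            raise ConfigurationError("water mask must contain only {0, 1, nodata}")
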