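"""Regular-grid containers shared by the habitat and elevation layers.

Both layers live on the same planar, metric grid: origin ``(x0, y0)`` at the
lower-left corner, square cells of ``cell_size`` metres, row index increasing
northward.  Grids are stored as plain numpy arrays and serialized either as
ESRI ASCII grids (text, interoperable) or bundled in a ``.npz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Wetland class codes.  ``other_tidal`` (mostly unvegetated inter- and
#: subtidal flats) is the reference level everywhere in the analysis.
CLASS_NAMES = ("other_tidal", "eelgrass", "shellfish", "tidal_marsh")
CLASS_CODES = {name: i for i, name in enumerate(CLASS_NAMES)}
EXCLUDED = -1
REFERENCE_CLASS = "other_tidal"


@dataclass(frozen=True)
class GridGeometry:
    """Placement of a regular grid in a planar metric CRS."""

    x0: float
    y0: float
    cell_size: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def x1(self) -> float:
        return self.x0 + self.nx * self.cell_size

    @property
    def y1(self) -> float:
        return self.y0 + self.ny * self.cell_size

    def cell_index(self, x, y):
        """Column/row index of the cell containing each point.

        Returns ``(ix, iy, inside)``; indices are only meaningful where
        ``inside`` is True.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.x0) / self.cell_size).astype(np.int64)
        iy = np.floor((y - self.y0) / self.cell_size).astype(np.int64)
        inside = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        return ix, iy, inside

    def cell_centers(self):
        """Meshgrid of cell-center coordinates, shape ``(ny, nx)`` each."""
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return np.meshgrid(cx, cy)


@dataclass
class HabitatGrid:
    """Categorical wetland map: one class code per cell, or -1 (excluded)."""

    geometry: GridGeometry
    classes: np.ndarray  # int8, shape (ny, nx)
    reference_class: str = REFERENCE_CLASS

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int8)
        if self.classes.shape != (self.geometry.ny, self.geometry.nx):
            raise ValueError("class array shape does not match geometry")
        if self.reference_class not in CLASS_NAMES:
            raise ValueError(f"unknown reference class {self.reference_class!r}")
        bad = ~np.isin(self.classes, [EXCLUDED, *CLASS_CODES.values()])
        if bad.any():
            raise ValueError("class array contains codes outside the legend")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True inside the study area."""
        return self.classes != EXCLUDED

    def class_code_at(self, x, y):
        """Class code of the cell containing each point (-1 if excluded).

        Raises for points outside the grid extent.
        """
        ix, iy, inside = self.geometry.cell_index(x, y)
        if not np.all(inside):
            raise ValueError("point(s) outside the grid extent")
        return self.classes[iy, ix]

    def class_at(self, x: float, y: float) -> str:
        code = int(self.class_code_at(x, y))
        if code == EXCLUDED:
            return "excluded"
        return CLASS_NAMES[code]

    def class_fractions(self) -> dict[str, float]:
        """Areal fraction of each wetland class within the study mask."""
        inside = self.mask
        total = int(inside.sum())
        return {
            name: float(np.count_nonzero(self.classes == code) / total)
            for name, code in CLASS_CODES.items()
        }


@dataclass
class ElevationGrid:
    """Per-cell elevation (m, one vertical datum) with a source tag.

    ``source`` is 0 where the value came from the DEM, 1 where it came from
    the bathymetry layer.
    """

    geometry: GridGeometry
    values: np.ndarray  # float64, shape (ny, nx)
    source: np.ndarray = field(default=None)  # int8: 0=dem, 1=bathymetry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.ny, self.geometry.nx):
            raise ValueError("elevation array shape does not match geometry")
        if self.source is None:
            self.source = np.zeros(self.values.shape, dtype=np.int8)
        else:
            self.source = np.asarray(self.source, dtype=np.int8)

    def value_at(self, x, y):
        ix, iy, inside = self.geometry.cell_index(x, y)
        if not np.all(inside):
            raise ValueError("point(s) outside the grid extent")
        return self.values[iy, ix]


def write_ascii_grid(path: str | Path, geometry: GridGeometry, values: np.ndarray,
                     nodata: float = -9999.0) -> None:
    """Write one band as an ESRI ASCII grid (rows written north to south)."""
    values = np.asarray(values, dtype=float)
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {geometry.nx}\n"
        f"nrows {geometry.ny}\n"
        f"xllcorner {geometry.x0!r}\n"
        f"yllcorner {geometry.y0!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[GridGeometry, np.ndarray]:
    """Read an ESRI ASCII grid; NODATA cells come back as NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    geom = GridGeometry(
        x0=header["xllcorner"], y0=header["yllcorner"],
        cell_size=header["cellsize"],
        nx=int(header["ncols"]), ny=int(header["nrows"]),
    )
    data = np.atleast_2d(data)[::-1].copy()
    nodata = header.get("nodata_value")
    if nodata is not None:
        data[data == nodata] = np.nan
    return geom, data


def save_landscape_npz(path: str | Path, habitat: HabitatGrid,
                       elevation: ElevationGrid) -> None:
    if habitat.geometry != elevation.geometry:
        raise ValueError("habitat and elevation grids must share geometry")
    g = habitat.geometry
    np.savez(
        path,
        x0=g.x0, y0=g.y0, cell_size=g.cell_size,
        classes=habitat.classes, elevation=elevation.values,
        source=elevation.source,
    )


def load_landscape_npz(path: str | Path) -> tuple[HabitatGrid, ElevationGrid]:
    with np.load(path) as z:
        classes = z["classes"]
        geom = GridGeometry(
            x0=float(z["x0"]), y0=float(z["y0"]),
            cell_size=float(z["cell_size"]),
            nx=classes.shape[1], ny=classes.shape[0],
        )
        habitat = HabitatGrid(geom, classes)
        elevation = ElevationGrid(geom, z["elevation"], z["source"])
    return habitat, elevation
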