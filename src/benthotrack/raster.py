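"""Planar categorical rasters for benthoscape (seabed substrate) maps.

All coordinates are planar metres. The internal row convention is
*south-up*: row 0 is the southernmost row of cells. Cells are square and
half-open, ``[x0, x0 + cell) x [y0, y0 + cell)``, so every in-bounds point
maps to exactly one cell and points on shared edges are assigned
deterministically.

Substrate classes follow the five-class benthoscape scheme used for the
Bras d'Or Lake (coarse sediments; silt/mud with <= 50% gravel; mixed
sediments with a veneer of mud; deep and shallow silt/mud), with "no data"
kept as a first-class categorical level because selection estimates are
reported for unmapped seabed as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

#: Sentinel class code for cells without substrate data. Kept as an
#: ordinary categorical level throughout the analyses.
NODATA: int = -1

#: Benthoscape class scheme: code -> name.
SUBSTRATE_NAMES: dict[int, str] = {
    0: "Coarse sediments",
    1: "Silt/mud with <= 50% gravel",
    2: "Mixed sediments with a veneer of mud",
    3: "Deep silt/mud (> 50 m)",
    4: "Shallow silt/mud (<= 50 m)",
    NODATA: "No data",
}

#: The baseline substrate against which selection is expressed: the least
#: abundant class within the array, used by all analysed individuals.
REFERENCE_CLASS: int = 1

VALID_CODES = frozenset(SUBSTRATE_NAMES)


class RasterError(ValueError):
    """Malformed raster definition or file."""


class OutOfBoundsError(ValueError):
    """A queried point falls outside the raster extent."""


@dataclass(frozen=True)
class SubstrateClass:
    """A single benthoscape class (code plus human-readable name)."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in VALID_CODES:
            raise RasterError(f"unknown substrate class code {self.code}")

    @property
    def name(self) -> str:
        return SUBSTRATE_NAMES[self.code]

    @property
    def is_nodata(self) -> bool:
        return self.code == NODATA


@dataclass
class BenthoscapeRaster:
    """Categorical substrate grid in planar metre coordinates.

    Parameters
    ----------
    origin_x, origin_y
        Coordinates (m) of the lower-left (south-west) corner.
    cell_size
        Side length (m) of the square cells; must be positive.
    values
        Integer class codes, shape ``(n_rows, n_cols)``; row 0 is the
        *southernmost* row. Every value must be a declared class code
        (0-4) or :data:`NODATA`.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise RasterError("raster values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise RasterError(f"cell_size must be > 0, got {self.cell_size}")
        bad = set(np.unique(self.values)) - VALID_CODES
        if bad:
            raise RasterError(f"unknown class codes in raster: {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered extent."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    # -- point -> cell ----------------------------------------------------

    def cell_index(self, x, y):
        """Map point(s) to (row, col) under the half-open cell rule.

        Raises
        ------
        OutOfBoundsError
            If any point lies outside ``bounds``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.bounds
        ok = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
        if not np.all(ok):
            bad = np.argwhere(~np.atleast_1d(ok)).ravel()
            i = int(bad[0])
            px = np.atleast_1d(x)[i]
            py = np.atleast_1d(y)[i]
            raise OutOfBoundsError(
                f"point ({px}, {py}) outside raster bounds "
                f"x in [{xmin}, {xmax}), y in [{ymin}, {ymax})"
            )
        col = np.floor((x - xmin) / self.cell_size).astype(np.int64)
        row = np.floor((y - ymin) / self.cell_size).astype(np.int64)
        return row, col

    def extract_code(self, x, y):
        """Class code(s) of the cell(s) containing the point(s)."""
        row, col = self.cell_index(x, y)
        return self.values[row, col]

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates of all cell centres as (X, Y) 2-D arrays."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


def extract_class(raster: BenthoscapeRaster, x: float, y: float) -> SubstrateClass:
    """Substrate class of the cell containing point ``(x, y)``."""
    return SubstrateClass(int(raster.extract_code(x, y)))


def class_proportions(raster: BenthoscapeRaster, region) -> dict[int, float]:
    """Fraction of each class among cells whose centres fall inside ``region``.

    ``region`` is a shapely polygon in the same metre coordinates. NODATA
    is reported as its own level. Fractions sum to 1 (to ~1e-12).

    Raises
    ------
    ValueError
        If no cell centre falls inside the region.
    """
    region = shapely.geometry.shape(region) if isinstance(region, dict) else region
    X, Y = raster.cell_centres()
    inside = shapely.contains_xy(region, X.ravel(), Y.ravel())
    if not inside.any():
        raise ValueError("region covers no raster cell centres")
    codes = raster.values.ravel()[inside]
    counts = {int(c): int(n) for c, n in zip(*np.unique(codes, return_counts=True))}
    total = codes.size
    return {c: n / total for c, n in counts.items()}


# -- I/O -------------------------------------------------------------------

_ASCII_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")

# GeoTIFF georeferencing tags for a north-up, axis-aligned grid.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


def write_raster(raster: BenthoscapeRaster, path, format: str | None = None) -> None:
    """Write a raster as an ESRI-ASCII text grid or single-band GeoTIFF.

    Format is inferred from the suffix (.tif/.tiff -> geotiff, else
    text_grid) unless given explicitly.
    """
    path = Path(path)
    fmt = format or ("geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "text_grid")
    # Both on-disk formats store rows north-to-south; flip the south-up grid.
    north_up = raster.values[::-1]
    if fmt == "text_grid":
        with open(path, "w") as fh:
            fh.write(f"ncols {raster.n_cols}\n")
            fh.write(f"nrows {raster.n_rows}\n")
            fh.write(f"xllcorner {raster.origin_x!r}\n")
            fh.write(f"yllcorner {raster.origin_y!r}\n")
            fh.write(f"cellsize {raster.cell_size!r}\n")
            fh.write("nodata_value -9999\n")
            grid = np.where(north_up == NODATA, -9999, north_up)
            np.savetxt(fh, grid, fmt="%d")
    elif fmt == "geotiff":
        import tifffile

        xmin, ymin, xmax, ymax = raster.bounds
        c = raster.cell_size
        extratags = [
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (c, c, 0.0)),
            # raster point (0,0) at the top-left (north-west) corner
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, xmin, ymax, 0.0)),
        ]
        tifffile.imwrite(path, north_up.astype(np.int32), extratags=extratags)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def read_raster(path, format: str | None = None) -> BenthoscapeRaster:
    """Read a raster written by :func:`write_raster` (round-trip exact)."""
    path = Path(path)
    fmt = format or ("geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "text_grid")
    if fmt == "text_grid":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def _read_ascii(path: Path) -> BenthoscapeRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise RasterError(f"{path}: no data rows")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (*_ASCII_KEYS, "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        missing = [k for k in _ASCII_KEYS if k not in header]
        if missing:
            raise RasterError(f"{path}: malformed header, missing {missing}")
        if header["cellsize"] <= 0:
            raise RasterError(f"{path}: cellsize must be > 0, got {header['cellsize']}")
        grid = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise RasterError(
            f"{path}: grid shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = int(header.get("nodata_value", -9999))
    grid = np.where(grid == nodata, NODATA, grid)
    return BenthoscapeRaster(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        values=grid[::-1],  # file is north-up; internal rows are south-up
    )


def _read_geotiff(path: Path) -> BenthoscapeRaster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        grid = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise RasterError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
    if abs(sx - sy) > 1e-9 * max(sx, sy):
        raise RasterError(f"{path}: non-square cells ({sx} x {sy})")
    if sx <= 0:
        raise RasterError(f"{path}: cellsize must be > 0, got {sx}")
    tie = tags[_TAG_MODEL_TIEPOINT]
    xmin = tie[3] - tie[0] * sx
    ymax = tie[4] + tie[1] * sy
    grid = np.asarray(grid, dtype=np.int64)
    if grid.ndim != 2:
        raise RasterError(f"{path}: expected a single-band raster")
    return BenthoscapeRaster(
        origin_x=xmin,
        origin_y=ymax - grid.shape[0] * sy,
        cell_size=float(sx),
        values=grid[::-1],
    )
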