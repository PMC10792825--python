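"""Synthetic alpine landscapes: elevation fields and derived terrain rasters.

All rasters live on one co-registered grid in projected metres, row 0 at the
northern edge.  Terrain derivatives (slope, aspect) use Horn's 3x3
finite-difference stencil, the algorithm behind the standard GIS surface
tools.  Aspect is measured in degrees from north, clockwise, and is split
into the two linear variables

    northness = cos(aspect * pi / 180)
    eastness  = sin(aspect * pi / 180)

so that -1 represents southern/western and +1 northern/eastern exposures.
Tree cover density (tcd, percent) is generated as a monotone decreasing
function of elevation plus smooth noise, calibrated to a target
elevation-tcd correlation, in three epoch layers (2012/2015/2018).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

HABITAT_RASTERS = ("elevation", "slope", "tcd", "northness", "eastness")
TCD_EPOCHS = (2012, 2015, 2018)


@dataclass
class LandscapeStack:
    """Co-registered single-band rasters on a shared grid.

    ``x0, y0`` is the outer corner of the lower-left (south-west) cell;
    ``cell_size`` is in metres.  Arrays are indexed ``[row, col]`` with row 0
    at the northern edge.
    """

    x0: float
    y0: float
    cell_size: float
    elevation: np.ndarray
    slope: np.ndarray
    aspect: np.ndarray
    northness: np.ndarray
    eastness: np.ndarray
    tcd: dict[int, np.ndarray] = field(default_factory=dict)
    flat: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the full grid."""
        ny, nx = self.shape
        return (
            self.x0,
            self.x0 + nx * self.cell_size,
            self.y0,
            self.y0 + ny * self.cell_size,
        )

    def cell_index(self, x, y):
        """Row/column of the cell containing each point (vectorized)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ny, nx = self.shape
        col = np.floor((x - self.x0) / self.cell_size).astype(np.int64)
        row = np.floor((self.y0 + ny * self.cell_size - y) / self.cell_size)
        row = row.astype(np.int64)
        # points exactly on the top/right boundary belong to the edge cell
        col = np.where((x == self.x0 + nx * self.cell_size), nx - 1, col)
        row = np.where((y == self.y0 + ny * self.cell_size), 0, row)
        return row, col

    def contains(self, x, y):
        xmin, xmax, ymin, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def sample(self, name: str, x, y, epoch_year: int | None = None):
        """Raster value of the cell containing each point.

        ``name='tcd'`` requires either ``epoch_year`` (calendar year of the
        fix; the nearest epoch layer is used, ties towards the earlier
        epoch) or an array of years.
        """
        row, col = self.cell_index(x, y)
        ny, nx = self.shape
        if np.any((row < 0) | (row >= ny) | (col < 0) | (col >= nx)):
            raise ValueError("point outside raster extent")
        if name == "tcd":
            if epoch_year is None:
                raise ValueError("tcd sampling requires epoch_year")
            years = np.broadcast_to(np.asarray(epoch_year), row.shape)
            out = np.empty(row.shape, dtype=float)
            for ep in sorted(self.tcd):
                sel = nearest_epoch(years) == ep
                out[sel] = self.tcd[ep][row[sel], col[sel]]
            return out
        return getattr(self, name)[row, col]

    def interior_point_mask(self, x, y, margin: float):
        xmin, xmax, ymin, ymax = self.extent
        return (
            (x >= xmin + margin)
            & (x <= xmax - margin)
            & (y >= ymin + margin)
            & (y <= ymax - margin)
        )


def nearest_epoch(years, epochs=TCD_EPOCHS):
    """Nearest tree-cover epoch to each calendar year; ties -> earlier epoch."""
    years = np.asarray(years)
    eps = np.asarray(sorted(epochs))
    dist = np.abs(years[..., None] - eps)
    # argmin takes the first (earlier) epoch on ties
    out = eps[np.argmin(dist, axis=-1)]
    return out if years.ndim else out[()]


def derive_terrain(elevation: np.ndarray, cell_size: float):
    """Slope, aspect, northness and eastness from an elevation raster.

    Horn's method: 3x3 weighted finite differences with edge replication.
    Aspect is the downslope direction, degrees clockwise from north; flat
    cells (zero gradient) get aspect 0 with a flat flag, and
    northness = eastness = 0 there as the neutral value.

    Returns (slope_deg, aspect_deg, northness, eastness, flat_mask).
    """
    z = np.asarray(elevation, dtype=float)
    if z.ndim != 2 or z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("elevation raster must be at least 3x3")
    if not np.all(np.isfinite(z)):
        raise ValueError("elevation raster contains non-finite values")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")

    p = np.pad(z, 1, mode="edge")
    a = p[:-2, :-2]; b = p[:-2, 1:-1]; c = p[:-2, 2:]
    d = p[1:-1, :-2];                  f = p[1:-1, 2:]
    g = p[2:, :-2];  h = p[2:, 1:-1];  i = p[2:, 2:]
    # row 0 is north: +x east, +y north
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell_size)

    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    flat = (dzdx == 0) & (dzdy == 0)
    # downslope direction, clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[flat] = 0.0
    northness = np.where(flat, 0.0, np.cos(np.radians(aspect)))
    eastness = np.where(flat, 0.0, np.sin(np.radians(aspect)))
    return slope, aspect, northness, eastness, flat


def generate_landscape(
    n_rows: int = 200,
    n_cols: int = 200,
    cell_size: float = 20.0,
    elevation_range: tuple[float, float] = (1380.0, 3173.0),
    smoothness: float = 8.0,
    tcd_elevation_corr: float = -0.6,
    epoch_perturbation_sd: float = 1.5,
    x0: float = 0.0,
    y0: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> LandscapeStack:
    """Smoothed random elevation field plus coupled tree-cover epochs.

    White Gaussian noise is low-pass filtered (Gaussian kernel,
    ``smoothness`` in cells) and rescaled exactly to ``elevation_range``.
    The tcd base layer is built so its in-sample Pearson correlation with
    elevation equals ``tcd_elevation_corr`` exactly before the epoch
    perturbations; the three epoch layers add small smoothed noise and are
    clipped to [0, 100].
    """
    if n_rows < 50 or n_cols < 50:
        raise ValueError("grid must be at least 50 x 50 cells")
    lo, hi = elevation_range
    vals = [lo, hi, smoothness, tcd_elevation_corr, cell_size]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite configuration value")
    if hi <= lo:
        raise ValueError("elevation range must be increasing")
    if not -1.0 < tcd_elevation_corr < 1.0:
        raise ValueError("target correlation must be in (-1, 1)")

    rng = np.random.default_rng(seed)
    zr = ndimage.gaussian_filter(rng.standard_normal((n_rows, n_cols)), smoothness)
    zr = (zr - zr.min()) / (zr.max() - zr.min())
    elevation = lo + zr * (hi - lo)

    ez = _unit(elevation.ravel())
    noise = ndimage.gaussian_filter(
        rng.standard_normal((n_rows, n_cols)), smoothness / 2
    ).ravel()
    # residualize the noise against elevation so the mix hits the target
    # correlation exactly in-sample
    nraw = _unit(noise)
    nz = _unit(nraw - (np.dot(nraw, ez) / np.dot(ez, ez)) * ez)
    r = tcd_elevation_corr
    t = r * ez + np.sqrt(1.0 - r * r) * nz
    tcd_base = ((t - t.min()) / (t.max() - t.min()) * 100.0).reshape(n_rows, n_cols)

    tcd = {}
    for ep in TCD_EPOCHS:
        if ep == 2015:
            pert = 0.0
        else:
            pert = ndimage.gaussian_filter(
                rng.standard_normal((n_rows, n_cols)), smoothness / 2
            )
            pert = pert / pert.std() * epoch_perturbation_sd
        tcd[ep] = np.clip(tcd_base + pert, 0.0, 100.0)

    slope, aspect, northness, eastness, flat = derive_terrain(elevation, cell_size)
    return LandscapeStack(
        x0=x0, y0=y0, cell_size=cell_size,
        elevation=elevation, slope=slope, aspect=aspect,
        northness=northness, eastness=eastness, tcd=tcd, flat=flat,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    """Centre and scale a vector to zero mean, unit (population) SD."""
    v = v - v.mean()
    s = v.std()
    if s == 0:
        raise ValueError("degenerate field: zero variance")
    return v / s


# --- raster I/O -----------------------------------------------------------
#
# Rasters are written as single-band float32 TIFF with a JSON sidecar
# carrying the grid origin, cell size and nodata tag; ESRI ASCII grid
# (.asc) is supported as a plain-text alternative.

def write_raster(path, array: np.ndarray, x0: float, y0: float,
                 cell_size: float, nodata: float = -9999.0) -> None:
    path = Path(path)
    if path.suffix == ".asc":
        ny, nx = array.shape
        header = (
            f"ncols {nx}\nnrows {ny}\nxllcorner {x0}\nyllcorner {y0}\n"
            f"cellsize {cell_size}\nNODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, np.where(np.isfinite(array), array, nodata), fmt="%.6f")
    else:
        import tifffile

        tifffile.imwrite(
            path, np.where(np.isfinite(array), array, nodata).astype(np.float32)
        )
        meta = {"x0": x0, "y0": y0, "cell_size": cell_size, "nodata": nodata}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_raster(path):
    """Returns (array, x0, y0, cell_size); nodata cells become NaN."""
    path = Path(path)
    if path.suffix == ".asc":
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            arr = np.loadtxt(fh)
        arr[arr == meta["nodata_value"]] = np.nan
        return arr, meta["xllcorner"], meta["yllcorner"], meta["cellsize"]
    import tifffile

    arr = tifffile.imread(path).astype(float)
    meta = json.loads(Path(str(path) + ".json").read_text())
    arr[arr == meta["nodata"]] = np.nan
    return arr, meta["x0"], meta["y0"], meta["cell_size"]


def save_stack(stack: LandscapeStack, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    kw = dict(x0=stack.x0, y0=stack.y0, cell_size=stack.cell_size)
    for name in ("elevation", "slope", "aspect", "northness", "eastness"):
        write_raster(directory / f"{name}.tif", getattr(stack, name), **kw)
    for ep, arr in stack.tcd.items():
        write_raster(directory / f"tcd_{ep}.tif", arr, **kw)


def load_stack(directory) -> LandscapeStack:
    directory = Path(directory)
    elevation, x0, y0, cs = read_raster(directory / "elevation.tif")
    layers = {}
    for name in ("slope", "aspect", "northness", "eastness"):
        layers[name], *_ = read_raster(directory / f"{name}.tif")
    tcd = {}
    for f in sorted(directory.glob("tcd_*.tif")):
        tcd[int(f.stem.split("_")[1])] = read_raster(f)[0]
    flat = (layers["slope"] == 0)
    return LandscapeStack(x0=x0, y0=y0, cell_size=cs, elevation=elevation,
                          tcd=tcd, flat=flat, **layers)
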