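"""Gridded distance-to-landcover layers.

Habitat covariates for the step-selection models are Euclidean
distance-to-feature surfaces (meters) on a shared rectangular grid, one
layer per landcover class (roads, settlements, pans, grassland,
floodplain, mixed woodland, mopane).  Layers are sampled at arbitrary
projected coordinates by bilinear interpolation with edge clamping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

LANDCOVER_CLASSES = (
    "roads",
    "settlements",
    "pans",
    "grassland",
    "floodplain",
    "mixed_woodland",
    "mopane",
)

#: landcover classes whose features are rasterized as polylines rather
#: than scattered patches (roads cross the whole extent)
_LINEAR_CLASSES = ("roads",)


@dataclass
class Landscape:
    """A stack of distance-to-feature grids on one rectangular extent.

    Grids are stored with shape ``(ny, nx)``; cell ``(iy, ix)`` is centered
    at ``(x0 + (ix + 0.5) * resolution, y0 + (iy + 0.5) * resolution)``.
    All layer values are >= 0 meters and 0 exactly on feature cells.
    """

    x0: float
    y0: float
    resolution: float
    nx: int
    ny: int
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in meters."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.resolution,
            self.y0 + self.ny * self.resolution,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.resolution
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.resolution
        return xs, ys

    def _fractional_index(self, x, y):
        fx = (np.asarray(x, float) - self.x0) / self.resolution - 0.5
        fy = (np.asarray(y, float) - self.y0) / self.resolution - 0.5
        return fx, fy

    def sample(self, layer: str, x, y) -> np.ndarray:
        """Bilinear sample of one layer at projected coordinates (meters).

        Coordinates beyond the grid are clamped to the edge cells
        (constant extrapolation), so values are defined everywhere.
        """
        grid = self.layers[layer]
        fx, fy = self._fractional_index(x, y)
        fx = np.clip(fx, 0.0, self.nx - 1.0)
        fy = np.clip(fy, 0.0, self.ny - 1.0)
        ix0 = np.clip(np.floor(fx).astype(int), 0, self.nx - 2) if self.nx > 1 else np.zeros_like(fx, int)
        iy0 = np.clip(np.floor(fy).astype(int), 0, self.ny - 2) if self.ny > 1 else np.zeros_like(fy, int)
        tx = fx - ix0
        ty = fy - iy0
        ix1 = np.minimum(ix0 + 1, self.nx - 1)
        iy1 = np.minimum(iy0 + 1, self.ny - 1)
        v00 = grid[iy0, ix0]
        v10 = grid[iy0, ix1]
        v01 = grid[iy1, ix0]
        v11 = grid[iy1, ix1]
        return (
            v00 * (1 - tx) * (1 - ty)
            + v10 * tx * (1 - ty)
            + v01 * (1 - tx) * ty
            + v11 * tx * ty
        )

    def layer_moments(self, layer: str) -> tuple[float, float]:
        """Landscape-wide mean and SD of one layer (meters)."""
        grid = self.layers[layer]
        return float(grid.mean()), float(grid.std())


def _rasterize_points(nx, ny, n, rng):
    mask = np.zeros((ny, nx), dtype=bool)
    ix = rng.integers(0, nx, size=n)
    iy = rng.integers(0, ny, size=n)
    mask[iy, ix] = True
    return mask


def _rasterize_polylines(nx, ny, n_lines, rng):
    """Random extent-crossing polylines, rasterized by dense sampling."""
    mask = np.zeros((ny, nx), dtype=bool)
    for _ in range(max(1, n_lines)):
        # endpoints on opposite edges with a random mid-point kink
        x_ends = rng.uniform(0, nx, size=2)
        p0 = np.array([x_ends[0], 0.0])
        p1 = np.array([x_ends[1], ny - 1.0])
        if rng.random() < 0.5:
            p0, p1 = p0[::-1], p1[::-1]
        mid = np.array([rng.uniform(0, nx), rng.uniform(0, ny)])
        for a, b in ((p0, mid), (mid, p1)):
            npts = int(4 * max(nx, ny))
            ts = np.linspace(0.0, 1.0, npts)
            xs = np.clip(a[0] + ts * (b[0] - a[0]), 0, nx - 1).astype(int)
            ys = np.clip(a[1] + ts * (b[1] - a[1]), 0, ny - 1).astype(int)
            mask[ys, xs] = True
    return mask


def generate_landscape(
    extent: tuple[float, float] = (40_000.0, 40_000.0),
    resolution: float = 250.0,
    feature_density_per_class: dict[str, float] | None = None,
    seed: int | None = None,
    x0: float = 0.0,
    y0: float = 0.0,
) -> Landscape:
    """Scatter features per landcover class and build distance layers.

    Parameters
    ----------
    extent
        (width, height) of the landscape in meters; must be divisible by
        ``resolution``.
    resolution
        Cell size in meters.
    feature_density_per_class
        Expected features per square meter, keyed by class name; classes
        not listed get a default of ``4e-9`` (a handful of patches on a
        40 km x 40 km landscape).  Roads are drawn as extent-crossing
        polylines, with the density interpreted as lines per 1e9 m^2.
    seed
        Seed for the patch process; identical seeds give bit-identical
        landscapes.
    """
    width, height = extent
    if width % resolution or height % resolution:
        raise ValueError("resolution must divide both extent dimensions")
    nx, ny = int(width / resolution), int(height / resolution)
    rng = np.random.default_rng(seed)
    densities = dict.fromkeys(LANDCOVER_CLASSES, 4e-9)
    if feature_density_per_class:
        densities.update(feature_density_per_class)
    if any(d <= 0 for d in densities.values()):
        raise ValueError("feature densities must be > 0")

    ls = Landscape(x0=x0, y0=y0, resolution=resolution, nx=nx, ny=ny)
    area = width * height
    for cls in LANDCOVER_CLASSES:
        n = int(rng.poisson(densities[cls] * area))
        if n == 0:
            warnings.warn(
                f"zero features drawn for class {cls!r}; forcing one feature",
                stacklevel=2,
            )
            n = 1
        if cls in _LINEAR_CLASSES:
            mask = _rasterize_polylines(nx, ny, n, rng)
        else:
            mask = _rasterize_points(nx, ny, n, rng)
        dist = distance_transform_edt(~mask) * resolution
        ls.layers[cls] = dist
    return ls


# ---------------------------------------------------------------------------
# plain-text grid IO (ESRI ASCII grid)

def write_ascii_grid(path, landscape: Landscape, layer: str) -> None:
    grid = landscape.layers[layer]
    with open(path, "w") as fh:
        fh.write(f"ncols {landscape.nx}\n")
        fh.write(f"nrows {landscape.ny}\n")
        fh.write(f"xllcorner {landscape.x0}\n")
        fh.write(f"yllcorner {landscape.y0}\n")
        fh.write(f"cellsize {landscape.resolution}\n")
        fh.write("NODATA_value -9999\n")
        # ESRI convention: first data row is the NORTH edge
        for row in grid[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    grid = np.asarray(rows)[::-1]  # back to south-up storage
    return grid, header


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
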