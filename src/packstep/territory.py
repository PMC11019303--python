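"""Trailing-window utilization distributions and territorial covariates.

For any reference day and pack, a utilization distribution (UD) is a
Gaussian kernel density built from the pack's GPS fixes in the trailing
window ``[day - w, day)`` for w in {7, 14, 30, 90} days.  The 50% (core)
and 95% (boundary) isopleths are the smallest density super-level sets
holding that fraction of UD mass; territorial covariates are signed
Euclidean distances to those outlines (negative strictly inside, zero on
the outline, positive outside), for the focal pack's own fields and —
taking the minimum over packs — for its neighbors'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, distance_transform_edt

WINDOWS = (7, 14, 30, 90)
LEVELS = (50, 95)


@dataclass
class UDField:
    """A normalized kernel-density grid for one pack and window."""

    pack_id: object
    reference_date: pd.Timestamp
    window_days: int
    x0: float
    y0: float
    resolution: float
    grid: np.ndarray  # (ny, nx), sums to 1
    bandwidth: float  # meters
    n_fixes: int

    @property
    def nx(self) -> int:
        return self.grid.shape[1]

    @property
    def ny(self) -> int:
        return self.grid.shape[0]

    def cell_centers(self):
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.resolution
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.resolution
        return xs, ys


def normal_reference_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Bivariate normal-scale bandwidth: pooled SD times n^(-1/6)."""
    n = len(x)
    sigma = np.sqrt(0.5 * (np.var(x) + np.var(y)))
    return float(sigma * n ** (-1.0 / 6.0))


def rolling_ud(
    fixes: pd.DataFrame,
    pack_id,
    reference_date,
    window_days: int,
    bandwidth: float | None = None,
    resolution: float = 250.0,
    extent: tuple[float, float, float, float] | None = None,
    min_fixes: int = 16,
) -> UDField | None:
    """Gaussian-kernel UD from the pack's fixes in ``[ref - w, ref)``.

    Returns ``None`` (an undefined field, which propagates to covariate
    incompleteness) when fewer than ``min_fixes`` fixes fall in the
    window.  The density is the exact kernel sum evaluated at cell
    centers, normalized to unit mass over the grid.  The default
    bandwidth is the normal-reference rule on the window's fixes,
    floored at one grid cell.
    """
    ref = pd.Timestamp(reference_date)
    t0 = ref - pd.Timedelta(days=window_days)
    sub = fixes[
        (fixes["pack_id"] == pack_id)
        & (fixes["timestamp"] >= t0)
        & (fixes["timestamp"] < ref)
    ]
    if len(sub) < min_fixes:
        return None
    fx = sub["x"].to_numpy(float)
    fy = sub["y"].to_numpy(float)
    h = bandwidth if bandwidth is not None else normal_reference_bandwidth(fx, fy)
    h = max(h, resolution)
    if extent is None:
        # pad generously so density super-level sets cannot clip
        pad = max(3.0 * h, 4.0 * resolution)
        extent = (fx.min() - pad, fy.min() - pad, fx.max() + pad, fy.max() + pad)
    xmin, ymin, xmax, ymax = extent
    nx = int(np.ceil((xmax - xmin) / resolution))
    ny = int(np.ceil((ymax - ymin) / resolution))
    xs = xmin + (np.arange(nx) + 0.5) * resolution
    ys = ymin + (np.arange(ny) + 0.5) * resolution
    # separable exact Gaussian kernel sum: grid = Ky^T Kx
    kx = np.exp(-0.5 * ((xs[None, :] - fx[:, None]) / h) ** 2)
    ky = np.exp(-0.5 * ((ys[None, :] - fy[:, None]) / h) ** 2)
    grid = ky.T @ kx
    total = grid.sum()
    if total <= 0:
        return None
    grid /= total
    return UDField(
        pack_id=pack_id,
        reference_date=ref,
        window_days=window_days,
        x0=xmin,
        y0=ymin,
        resolution=resolution,
        grid=grid,
        bandwidth=h,
        n_fixes=len(sub),
    )


@dataclass
class IsoplethDistance:
    """Signed distance (meters) to one isopleth outline of a UD.

    The enclosed region is the smallest super-level set of the density
    holding at least ``level``% of UD mass; its sign convention is
    negative strictly inside, positive outside.  Distances are grid
    accurate (within one cell diagonal).
    """

    ud: UDField
    level: int
    threshold: float
    mask: np.ndarray
    signed_grid: np.ndarray
    enclosed_mass: float

    def distance(self, x, y) -> np.ndarray:
        """Signed distance at projected points; the sign is decided by
        the containing cell so it always agrees with a point-in-region
        test against the gridded region."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        ud = self.ud
        ix = np.floor((x - ud.x0) / ud.resolution).astype(int)
        iy = np.floor((y - ud.y0) / ud.resolution).astype(int)
        inside_grid = (ix >= 0) & (ix < ud.nx) & (iy >= 0) & (iy < ud.ny)
        out = np.empty(len(x))
        if inside_grid.any():
            out[inside_grid] = self.signed_grid[iy[inside_grid], ix[inside_grid]]
        if (~inside_grid).any():
            # off-grid points are always outside the region: brute
            # distance to the region's boundary cell centers
            bx, by = self._boundary_centers()
            xo = x[~inside_grid]
            yo = y[~inside_grid]
            d = np.sqrt(
                (xo[:, None] - bx[None, :]) ** 2 + (yo[:, None] - by[None, :]) ** 2
            ).min(axis=1)
            out[~inside_grid] = d
        return out

    def _boundary_centers(self):
        ud = self.ud
        interior = binary_erosion(self.mask)
        edge = self.mask & ~interior
        iy, ix = np.nonzero(edge)
        xs = ud.x0 + (ix + 0.5) * ud.resolution
        ys = ud.y0 + (iy + 0.5) * ud.resolution
        return xs, ys

    def to_wkt(self) -> str:
        """Region outline as a WKT (multi)polygon of cell squares."""
        from shapely import unary_union
        from shapely.geometry import box

        ud = self.ud
        iy, ix = np.nonzero(self.mask)
        cells = [
            box(
                ud.x0 + i * ud.resolution,
                ud.y0 + j * ud.resolution,
                ud.x0 + (i + 1) * ud.resolution,
                ud.y0 + (j + 1) * ud.resolution,
            )
            for i, j in zip(ix, iy)
        ]
        return unary_union(cells).wkt


def isopleth_signed_distance(ud: UDField, level: int) -> IsoplethDistance:
    """Extract the ``level``% isopleth and its signed-distance field.

    The threshold is the smallest density whose super-level set holds at
    least ``level``% of UD mass, so the enclosed mass overshoots the
    nominal level by at most one cell's mass.  Raises if the region
    touches the grid edge (the extent must be padded so isopleths never
    clip).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    flat = ud.grid.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level / 100.0))
    k = min(k, len(flat) - 1)
    threshold = flat[order[k]]
    mask = ud.grid >= threshold
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError(
            "isopleth touches the grid edge; enlarge the extent padding"
        )
    d_out = distance_transform_edt(~mask) * ud.resolution
    d_in = distance_transform_edt(mask) * ud.resolution
    signed = np.where(mask, -d_in, d_out)
    return IsoplethDistance(
        ud=ud,
        level=level,
        threshold=float(threshold),
        mask=mask,
        signed_grid=signed,
        enclosed_mass=float(flat[order[: k + 1]].sum()),
    )


class UDTerritorySource:
    """Cached per-(pack, day, window) territorial covariates.

    ``values`` returns, per query point, the signed distances to the
    focal pack's own isopleths and the minimum signed distance over all
    neighboring packs' isopleths (most-inside/nearest neighbor), for
    every requested window x level, plus a ``territory_complete`` flag
    that is 1 only when every own and neighbor value is defined.
    """

    def __init__(
        self,
        fixes: pd.DataFrame,
        windows=WINDOWS,
        levels=LEVELS,
        resolution: float = 250.0,
        bandwidth: float | None = None,
        min_fixes: int = 16,
        extent: tuple[float, float, float, float] | None = None,
    ):
        self.fixes = fixes.copy()
        self.fixes["timestamp"] = pd.to_datetime(self.fixes["timestamp"])
        self.windows = tuple(windows)
        self.levels = tuple(levels)
        self.resolution = resolution
        self.bandwidth = bandwidth
        self.min_fixes = min_fixes
        # default: each UD grid adapts to its own window's fixes (with
        # generous padding), so isopleths can never clip the extent no
        # matter how far a pack wanders; signed-distance queries handle
        # off-grid points explicitly
        self.extent = extent
        self.packs = sorted(self.fixes["pack_id"].unique())
        self._ud_cache: dict = {}
        self._iso_cache: dict = {}

    def ud(self, pack_id, date, window) -> UDField | None:
        key = (pack_id, pd.Timestamp(date), window)
        if key not in self._ud_cache:
            self._ud_cache[key] = rolling_ud(
                self.fixes,
                pack_id,
                date,
                window,
                bandwidth=self.bandwidth,
                resolution=self.resolution,
                extent=self.extent,
                min_fixes=self.min_fixes,
            )
        return self._ud_cache[key]

    def isopleth(self, pack_id, date, window, level) -> IsoplethDistance | None:
        key = (pack_id, pd.Timestamp(date), window, level)
        if key not in self._iso_cache:
            ud = self.ud(pack_id, date, window)
            self._iso_cache[key] = (
                None if ud is None else isopleth_signed_distance(ud, level)
            )
        return self._iso_cache[key]

    def columns(self) -> list[str]:
        cols = []
        for w in self.windows:
            for side in ("own", "neigh"):
                for lv in self.levels:
                    cols.append(f"dist_{w}_{side}_{lv}")
        return cols

    def values(self, pack_ids, timestamps, x, y) -> pd.DataFrame:
        """Territorial covariates (km) at query points.

        The reference day of each query is the UTC date of its
        timestamp; windows are half-open ``[day - w, day)`` so the focal
        day's own fixes never feed the field being scored.
        """
        pack_ids = np.asarray(pack_ids)
        dates = pd.DatetimeIndex(timestamps).normalize()
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        n = len(x)
        out = {col: np.full(n, np.nan) for col in self.columns()}
        for (date, focal), idx in pd.DataFrame(
            {"date": dates, "pack": pack_ids}
        ).groupby(["date", "pack"]).groups.items():
            idx = np.asarray(idx)
            px, py = x[idx], y[idx]
            for w in self.windows:
                for lv in self.levels:
                    iso = self.isopleth(focal, date, w, lv)
                    if iso is not None:
                        out[f"dist_{w}_own_{lv}"][idx] = iso.distance(px, py) / 1000.0
                    best = None
                    for other in self.packs:
                        if other == focal:
                            continue
                        iso_o = self.isopleth(other, date, w, lv)
                        if iso_o is None:
                            continue
                        d = iso_o.distance(px, py) / 1000.0
                        best = d if best is None else np.minimum(best, d)
                    if best is not None:
                        out[f"dist_{w}_neigh_{lv}"][idx] = best
        df = pd.DataFrame(out)
        df["territory_complete"] = np.isfinite(df.to_numpy(float)).all(axis=1).astype(float)
        return df


def nearest_concurrent_neighbor(
    fixes: pd.DataFrame,
    focal_pack,
    timestamps,
    x,
    y,
    max_lag: pd.Timedelta = pd.Timedelta(hours=3),
) -> np.ndarray:
    """Distance (meters) to the nearest other-pack fix within ``max_lag``.

    NaN when no neighboring fix co-occurs within the lag.
    """
    others = fixes[fixes["pack_id"] != focal_pack].sort_values("timestamp")
    ot = others["timestamp"].to_numpy()
    ox = others["x"].to_numpy(float)
    oy = others["y"].to_numpy(float)
    times = pd.DatetimeIndex(timestamps).to_numpy()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    out = np.full(len(x), np.nan)
    if len(others) == 0:
        return out
    lo = np.searchsorted(ot, times - max_lag.to_numpy())
    hi = np.searchsorted(ot, times + max_lag.to_numpy(), side="right")
    for i in range(len(x)):
        if hi[i] > lo[i]:
            d = np.hypot(ox[lo[i] : hi[i]] - x[i], oy[lo[i] : hi[i]] - y[i])
            out[i] = d.min()
    return out
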