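"""Larval dispersal matrices.

Two dispersal kernels are supported:

* isolation by distance (IBD): the relative probability of transport between
  patches i and j is ``a ** d_ij`` with ``d_ij`` the over-water distance in
  km and ``0 < a < 1`` a dimensionless decay base, scanned by default from
  0.40 to 0.99 in steps of 0.01 (60 values);
* isolation by oceanographic distance (IBOD): a Lagrangian particle-tracking
  surrogate advects larvae in a gridded current field; larvae drift for a
  precompetency period (default 9 days), may settle on the first
  reef-bearing cell they enter during the competency window (days 9-19),
  and their settlement weight decays exponentially with age past
  precompetency (survival curve).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import KM_PER_DEG, Raster

logger = logging.getLogger(__name__)


def default_scan_grid() -> np.ndarray:
    """The default IBD decay-base grid: 0.40 to 0.99 by 0.01 (60 values)."""
    return np.round(np.arange(40, 100) / 100.0, 2)


@dataclass
class IBDKernelConfig:
    a: float = 0.95
    scan_grid: np.ndarray = field(default_factory=default_scan_grid)
    distance_unit: str = "km"

    def __post_init__(self) -> None:
        if not 0 < self.a < 1:
            raise ValueError("decay base a must be in (0, 1)")
        g = np.asarray(self.scan_grid, dtype=float)
        if len(g) == 0 or np.any(np.diff(g) <= 0):
            raise ValueError("scan_grid must be sorted and unique")
        self.scan_grid = g


@dataclass
class LarvalParams:
    """Biological parameters of the transport surrogate.

    ``decay_rate`` (per day) controls the exponential survival decline over
    the competency window; the default puts survival at 5% at the end of the
    window (day 19) relative to its start (day 9).
    """

    precompetency_days: float = 9.0
    competency_end_days: float = 19.0
    decay_rate: float = math.log(20.0) / 10.0
    release_per_cell_per_day: int = 1
    release_days: int = 30
    timestep_hours: float = 1.0

    def __post_init__(self) -> None:
        if self.precompetency_days >= self.competency_end_days:
            raise ValueError("precompetency must end before the competency window closes")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive")
        if self.timestep_hours > 24.0:
            raise ValueError("timestep must not exceed 24 h")


@dataclass
class DispersalMatrix:
    """Row-indexed settlement probabilities D[source, destination]."""

    patch_ids: list
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.patch_ids)
        if self.D.shape != (n, n):
            raise ValueError("dispersal matrix shape does not match patch ids")
        if (self.D < -1e-12).any() or (self.D > 1 + 1e-9).any():
            raise ValueError("dispersal probabilities must lie in [0, 1]")
        if (self.D.sum(axis=1) > 1 + 1e-9).any():
            raise ValueError("dispersal rows must sum to at most 1")

    def subset(self, patch_ids, renormalize: bool = False) -> "DispersalMatrix":
        pos = {pid: i for i, pid in enumerate(self.patch_ids)}
        idx = np.array([pos[p] for p in patch_ids])
        D = self.D[np.ix_(idx, idx)].copy()
        if renormalize:
            s = D.sum(axis=1, keepdims=True)
            np.divide(D, s, out=D, where=s > 0)
        return DispersalMatrix(list(patch_ids), D)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.D, index=self.patch_ids,
                     columns=self.patch_ids).to_csv(path, float_format="%.17g")


def ibd_matrix(dist, a: float, normalize: bool = True) -> DispersalMatrix:
    """Isolation-by-distance dispersal matrix, raw weight ``a ** d``.

    Unreachable pairs (infinite distance) get weight zero; the diagonal
    (d = 0) gets raw weight 1, i.e. self-recruitment is maximal within a
    row.  With ``normalize`` the rows are scaled into settlement
    distributions summing to 1 (rows with no reachable destination are left
    all-zero).
    """
    if not 0 < a < 1:
        raise ValueError("decay base a must be in (0, 1)")
    d = np.asarray(dist.values, dtype=float)
    with np.errstate(under="ignore"):
        W = np.power(a, d)
    W[~np.isfinite(d)] = 0.0
    if normalize:
        s = W.sum(axis=1, keepdims=True)
        np.divide(W, s, out=W, where=s > 0)
    else:
        # keep raw relative weights but guarantee the row-sum contract
        s = W.sum(axis=1, keepdims=True)
        scale = max(1.0, float(s.max()))
        W = W / scale
    return DispersalMatrix(list(dist.patch_ids), W)


def load_external_dispersal(path, grid=None) -> DispersalMatrix:
    """Load and validate a dispersal matrix CSV (patch ids in the header).

    If ``grid`` is given the matrix is reordered to the grid's patch order;
    a mismatch in the id sets is an error.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("dispersal matrix rows and columns must carry the same ids")
    D = df.to_numpy(dtype=float)
    if (D < 0).any():
        raise ValueError("dispersal matrix has negative entries")
    if (D.sum(axis=1) > 1 + 1e-9).any():
        raise ValueError("dispersal matrix rows must sum to at most 1")
    ids = list(df.index)
    if grid is not None:
        want = [str(p) for p in grid.patches.index]
        have = [str(i) for i in ids]
        if sorted(want) != sorted(have):
            raise ValueError("dispersal matrix ids do not match the patch grid")
        order = [have.index(w) for w in want]
        D = D[np.ix_(order, order)]
        ids = list(grid.patches.index)
    return DispersalMatrix(ids, D)


class CurrentField:
    """Bilinear space / linear time interpolator over a (time, lat, lon) u,v field."""

    def __init__(self, ds):
        for var in ("u", "v"):
            if var not in ds:
                raise ValueError(f"current field is missing variable {var!r}")
        self.lon = np.asarray(ds["lon"].values, dtype=float)
        self.lat = np.asarray(ds["lat"].values, dtype=float)
        self.time = np.asarray(ds["time"].values, dtype=float) if "time" in ds.dims else np.array([0.0])
        u = np.asarray(ds["u"].values, dtype=float)
        v = np.asarray(ds["v"].values, dtype=float)
        if u.ndim == 2:
            u = u[None]
            v = v[None]
        if np.isnan(u).any() or np.isnan(v).any():
            raise ValueError("current field contains NaN values inside the domain")
        if np.any(np.diff(self.lon) <= 0) or np.any(np.diff(self.lat) <= 0):
            raise ValueError("current field coordinates must be increasing")
        self.u = u
        self.v = v

    def __call__(self, lon, lat, t_days):
        """Velocities (m/s) at positions and a common time (days)."""
        if len(self.time) > 1:
            tt = np.clip(t_days, self.time[0], self.time[-1])
            k = np.clip(np.searchsorted(self.time, tt) - 1, 0, len(self.time) - 2)
            w = (tt - self.time[k]) / (self.time[k + 1] - self.time[k])
            u3 = (1 - w) * self.u[k] + w * self.u[k + 1]
            v3 = (1 - w) * self.v[k] + w * self.v[k + 1]
        else:
            u3, v3 = self.u[0], self.v[0]
        xi = np.interp(lon, self.lon, np.arange(len(self.lon)))
        yi = np.interp(lat, self.lat, np.arange(len(self.lat)))
        x0 = np.clip(np.floor(xi).astype(int), 0, len(self.lon) - 2)
        y0 = np.clip(np.floor(yi).astype(int), 0, len(self.lat) - 2)
        fx = xi - x0
        fy = yi - y0
        u = ((1 - fy) * ((1 - fx) * u3[y0, x0] + fx * u3[y0, x0 + 1])
             + fy * ((1 - fx) * u3[y0 + 1, x0] + fx * u3[y0 + 1, x0 + 1]))
        v = ((1 - fy) * ((1 - fx) * v3[y0, x0] + fx * v3[y0, x0 + 1])
             + fy * ((1 - fx) * v3[y0 + 1, x0] + fx * v3[y0 + 1, x0 + 1]))
        return u, v

    def covers(self, lon, lat) -> np.ndarray:
        return ((lon >= self.lon[0]) & (lon <= self.lon[-1])
                & (lat >= self.lat[0]) & (lat <= self.lat[-1]))


def _patch_cell_lookup(grid):
    """Map (row_key, col_key) of the patch grid lattice to patch row index."""
    res = grid.resolution
    keys = {}
    for i, pid in enumerate(grid.patches.index):
        lon = grid.patches["lon"].iloc[i]
        lat = grid.patches["lat"].iloc[i]
        keys[(int(np.floor(lat / res)), int(np.floor(lon / res)))] = i
    return keys


def surrogate_transport(grid, currents, land: Raster | None,
                        params: LarvalParams, seed: int = 0) -> DispersalMatrix:
    """Particle-tracking surrogate for current-driven larval transport.

    Particles are released at patch centroids (``release_per_cell_per_day``
    per patch per day for ``release_days`` days) and advected with a
    midpoint (2nd-order) scheme.  Settlement can occur from the end of the
    precompetency period until the competency window closes, in the first
    reef-bearing grid cell entered, with weight ``exp(-lambda (t - t_pre))``.
    Particles stepping onto land are reflected to their previous position;
    particles leaving the current-field domain, or still adrift when the
    window closes, are lost.  Rows of D are normalized by the number of
    particles released per source, so rows sum to at most 1.
    """
    field_ = currents if isinstance(currents, CurrentField) else CurrentField(currents)
    n = grid.n_patches
    lon0 = grid.patches["lon"].to_numpy(dtype=float)
    lat0 = grid.patches["lat"].to_numpy(dtype=float)
    if not np.all(field_.covers(lon0, lat0)):
        raise ValueError("current field does not cover all patch centroids")
    cell_of = _patch_cell_lookup(grid)
    res = grid.resolution

    dt_days = params.timestep_hours / 24.0
    n_steps = int(np.ceil(params.competency_end_days / dt_days))
    sec = params.timestep_hours * 3600.0

    D = np.zeros((n, n))
    released = np.zeros(n)
    lost = np.zeros(n)
    settled = np.zeros(n)
    per_day = params.release_per_cell_per_day

    for day in range(params.release_days):
        for _ in range(per_day):
            src = np.arange(n)
            lon = lon0.copy()
            lat = lat0.copy()
            active = np.ones(n, dtype=bool)
            released += 1
            t_rel = float(day)
            for step in range(n_steps):
                age = step * dt_days
                t_abs = t_rel + age
                # settlement check before moving (a particle sitting on reef
                # at the moment it becomes competent settles immediately)
                if age >= params.precompetency_days:
                    idx = np.nonzero(active)[0]
                    if idx.size:
                        rk = np.floor(lat[idx] / res).astype(int)
                        ck = np.floor(lon[idx] / res).astype(int)
                        w = math.exp(-params.decay_rate
                                     * (age - params.precompetency_days))
                        for ii, r, c in zip(idx, rk, ck):
                            dest = cell_of.get((int(r), int(c)))
                            if dest is not None:
                                D[src[ii], dest] += w
                                settled[src[ii]] += 1
                                active[ii] = False
                if not active.any():
                    break
                idx = np.nonzero(active)[0]
                la, lo = lat[idx], lon[idx]
                u1, v1 = field_(lo, la, t_abs)
                mlon = lo + 0.5 * sec * u1 / (KM_PER_DEG * 1000 * np.cos(np.deg2rad(la)))
                mlat = la + 0.5 * sec * v1 / (KM_PER_DEG * 1000)
                u2, v2 = field_(np.clip(mlon, field_.lon[0], field_.lon[-1]),
                                np.clip(mlat, field_.lat[0], field_.lat[-1]),
                                t_abs + 0.5 * dt_days)
                nlon = lo + sec * u2 / (KM_PER_DEG * 1000 * np.cos(np.deg2rad(la)))
                nlat = la + sec * v2 / (KM_PER_DEG * 1000)
                # out of domain -> lost
                inside = field_.covers(nlon, nlat)
                if land is not None:
                    inside &= land.contains(nlon, nlat)
                gone = idx[~inside]
                if gone.size:
                    active[gone] = False
                    for ii in gone:
                        lost[src[ii]] += 1
                keep = inside
                kidx = idx[keep]
                if land is not None and kidx.size:
                    r, c = land.cell_index(nlon[keep], nlat[keep])
                    on_land = land.values[r, c].astype(bool)
                    # reflected: stay at previous position
                    move = ~on_land
                    lon[kidx[move]] = nlon[keep][move]
                    lat[kidx[move]] = nlat[keep][move]
                else:
                    lon[kidx] = nlon[keep]
                    lat[kidx] = nlat[keep]
            # window closed: survivors are lost
            still = np.nonzero(active)[0]
            for ii in still:
                lost[src[ii]] += 1

    with np.errstate(invalid="ignore"):
        D = np.divide(D, released[:, None], out=np.zeros_like(D),
                      where=released[:, None] > 0)
    dm = DispersalMatrix(list(grid.patches.index), D)
    dm.released = released
    dm.lost = lost
    dm.settled = settled
    return dm
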