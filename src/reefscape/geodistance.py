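"""Over-water geographic distances between habitat patches.

Shortest water paths are computed on a rasterized land mask: water cells are
graph nodes, 8-neighbouring water cells are connected by edges weighted with
the great-circle distance between cell centers (diagonals get their true
geodesic length), and patch-to-patch distances are Dijkstra shortest paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .raster import Raster, haversine_km

logger = logging.getLogger(__name__)


@dataclass
class GeoDistanceMatrix:
    """Square symmetric matrix of over-water distances (km) between patches."""

    patch_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.patch_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match patch ids")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite], self.values.T[finite]):
            raise ValueError("distance matrix must be symmetric")

    def subset(self, patch_ids) -> "GeoDistanceMatrix":
        pos = {pid: i for i, pid in enumerate(self.patch_ids)}
        idx = np.array([pos[p] for p in patch_ids])
        return GeoDistanceMatrix(list(patch_ids), self.values[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.patch_ids,
                     columns=self.patch_ids).to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "GeoDistanceMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        ids = list(df.index)
        return cls(ids, df.to_numpy(dtype=float))


def build_water_graph(land: Raster):
    """Build the 8-connected traversal graph over water cells.

    Returns ``(node_index, nodes_rc, graph)`` where ``node_index`` is an
    (nrows, ncols) array holding each water cell's node id (-1 for land),
    ``nodes_rc`` the (n, 2) array of water cell row/col coordinates, and
    ``graph`` a symmetric CSR matrix of great-circle edge lengths in km.
    """
    water = ~land.values.astype(bool)
    if not water.any():
        raise ValueError("land raster has no water cells")
    node_index = -np.ones(water.shape, dtype=int)
    nodes_rc = np.argwhere(water)
    node_index[water] = np.arange(len(nodes_rc))

    rows_i, cols_j, weights = [], [], []
    # four unique neighbour directions; symmetry supplies the other four
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0 = slice(max(0, -dr), water.shape[0] - max(0, dr))
        c0 = slice(max(0, -dc), water.shape[1] - max(0, dc))
        r1 = slice(max(0, dr), water.shape[0] - max(0, -dr))
        c1 = slice(max(0, dc), water.shape[1] - max(0, -dc))
        pair = water[r0, c0] & water[r1, c1]
        src = node_index[r0, c0][pair]
        dst = node_index[r1, c1][pair]
        rr, cc = np.nonzero(pair)
        rr = rr + max(0, -dr)
        cc = cc + max(0, -dc)
        lon1, lat1 = land.cell_center(rr, cc)
        lon2, lat2 = land.cell_center(rr + dr, cc + dc)
        w = haversine_km(lon1, lat1, lon2, lat2)
        rows_i.append(src)
        cols_j.append(dst)
        weights.append(w)
    if rows_i:
        src = np.concatenate(rows_i)
        dst = np.concatenate(cols_j)
        w = np.concatenate(weights)
    else:  # single water cell
        src = dst = np.array([], dtype=int)
        w = np.array([])
    n = len(nodes_rc)
    graph = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([src, dst]),
                                  np.concatenate([dst, src]))),
        shape=(n, n),
    ).tocsr()
    return node_index, nodes_rc, graph


def overwater_distance(grid, land: Raster) -> GeoDistanceMatrix:
    """Shortest over-water distances (km) between patch centroids.

    Patch centroids falling on land cells are snapped to the nearest water
    cell (logged).  Pairs in disconnected water bodies get ``inf``.
    """
    node_index, nodes_rc, graph = build_water_graph(land)
    lons = grid.patches["lon"].to_numpy()
    lats = grid.patches["lat"].to_numpy()
    if not np.all(land.contains(lons, lats)):
        bad = grid.patches.index[~land.contains(lons, lats)]
        raise ValueError(f"patch centroid(s) outside land raster extent: {list(bad)}")
    rows, cols = land.cell_index(lons, lats)
    src_nodes = np.empty(len(rows), dtype=int)
    wlon, wlat = land.cell_center(nodes_rc[:, 0], nodes_rc[:, 1])
    for k, (r, c) in enumerate(zip(rows, cols)):
        nid = node_index[r, c]
        if nid < 0:
            d = haversine_km(lons[k], lats[k], wlon, wlat)
            nid = int(np.argmin(d))
            logger.warning(
                "patch %s centroid lies on a land cell; snapped to nearest "
                "water cell %.1f km away",
                grid.patches.index[k], float(d[nid]),
            )
        src_nodes[k] = nid

    unique_nodes, inverse = np.unique(src_nodes, return_inverse=True)
    dist_from = dijkstra(graph, directed=False, indices=unique_nodes)
    d = dist_from[inverse][:, src_nodes]
    d = 0.5 * (d + d.T)  # symmetrize float noise
    np.fill_diagonal(d, 0.0)
    return GeoDistanceMatrix(list(grid.patches.index), d)


def greatcircle_matrix(grid) -> GeoDistanceMatrix:
    """Great-circle (no-land) distance matrix between patch centroids."""
    lons = grid.patches["lon"].to_numpy()
    lats = grid.patches["lat"].to_numpy()
    d = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return GeoDistanceMatrix(list(grid.patches.index), d)


def n_water_components(land: Raster) -> int:
    """Number of disconnected water bodies in the land raster."""
    _, _, graph = build_water_graph(land)
    n, _ = connected_components(graph, directed=False)
    return n
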