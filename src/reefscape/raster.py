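"""Lightweight geographic raster container.

A :class:`Raster` is a 2-D numpy array on a regular longitude/latitude
lattice.  Row 0 is the northernmost row, matching the usual image/raster
convention.  Cell geometry is geographic (degrees); conversions to physical
lengths use a spherical Earth.

Serialization uses the Esri ASCII grid format (plain text), which keeps
fixtures human-readable and diff-able.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean kilometres per degree of latitude on a sphere of radius 6371.0088 km.
KM_PER_DEG = np.pi * 6371.0088 / 180.0

#: Hectares per square kilometre.
HA_PER_KM2 = 100.0


@dataclass
class Raster:
    """Regular lon/lat grid of values.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; row 0 is the northernmost row.
    west, south : float
        Geographic coordinates (degrees) of the outer edge of the grid.
    resolution : float
        Cell size in degrees (square cells).
    """

    values: np.ndarray
    west: float
    south: float
    resolution: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def north(self) -> float:
        return self.south + self.nrows * self.resolution

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.resolution

    @property
    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.ncols) + 0.5) * self.resolution

    @property
    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 first (northernmost)."""
        return self.north - (np.arange(self.nrows) + 0.5) * self.resolution

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.west)
            & (lon < self.east)
            & (lat >= self.south)
            & (lat < self.north)
        )

    def cell_index(self, lon, lat):
        """Return (row, col) of the cell containing each point.

        Raises
        ------
        ValueError
            If any point falls outside the raster extent.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if not np.all(self.contains(lon, lat)):
            raise ValueError("point(s) outside raster extent")
        col = np.floor((lon - self.west) / self.resolution).astype(int)
        row = np.floor((self.north - lat) / self.resolution).astype(int)
        # guard against points numerically on the north/east edge
        col = np.clip(col, 0, self.ncols - 1)
        row = np.clip(row, 0, self.nrows - 1)
        return row, col

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.west + (col + 0.5) * self.resolution
        lat = self.north - (row + 0.5) * self.resolution
        return lon, lat

    def cell_area_ha(self, row) -> np.ndarray:
        """Area of cells in a given row, in hectares (cos-latitude corrected)."""
        _, lat = self.cell_center(row, 0)
        km_ew = self.resolution * KM_PER_DEG * np.cos(np.deg2rad(lat))
        km_ns = self.resolution * KM_PER_DEG
        return km_ew * km_ns * HA_PER_KM2

    # -- I/O ----------------------------------------------------------------

    def to_ascii(self, path) -> None:
        """Write as an Esri ASCII grid (text)."""
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.west!r}\n"
            f"yllcorner {self.south!r}\n"
            f"cellsize {self.resolution!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%g")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(
            values=values,
            west=meta["xllcorner"],
            south=meta["yllcorner"],
            resolution=meta["cellsize"],
            nodata=meta.get("nodata_value", -9999.0),
        )


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * 6371.0088 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
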