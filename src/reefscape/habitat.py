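"""Reefscape composition and configuration.

This module turns a benthic habitat map (raster of geomorphological class
codes, or shapely polygons tagged with class ids) and a density typology into
a gridded mosaic of habitat patches: the :class:`PatchGrid`.  Each patch is
one grid cell (default 0.25 deg) holding per-class reef areas in hectares and,
after a density realization, an abundance ``N`` of adults.

The typology is hierarchical with three nested levels:

* L1 — all reef confounded (a single class);
* L2 — shallow reefs vs variable-depth reefs, the latter assigned a
  hundred-fold lower density than the shallow aggregate;
* L3 — six geomorphological classes, each split into a shallow and a
  variable-depth stratum (variable-depth density = shallow density / 100).

Two perturbation operators support sensitivity analyses:

* :func:`degrade_composition` — re-aggregate class areas up the hierarchy
  (L3 -> L2 -> L1), losing compositional detail but keeping geometry;
* :func:`fragment` — remove whole patches at random (sampled genetic sites
  are protected) until a target fraction of the total reef area is gone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .raster import HA_PER_KM2, KM_PER_DEG, Raster

logger = logging.getLogger(__name__)

LEVELS = ("L1", "L2", "L3")


@dataclass(frozen=True)
class TypologyClass:
    class_id: str
    name: str
    level: str
    depth_stratum: str  # "shallow" | "variable_depth"
    density_mean: float  # ind / ha
    density_sd: float  # ind / ha


@dataclass
class HabitatTypology:
    """Density typology at one hierarchy level, with links to coarser levels.

    ``classes`` maps class_id -> :class:`TypologyClass` for the active level.
    ``parent_map`` maps every class id (any level) to its class id one level
    up; the single L1 class maps to itself.
    """

    level: str
    classes: dict
    parent_map: dict
    all_classes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown typology level {self.level!r}")
        if not self.classes:
            raise ValueError("typology has no classes at the requested level")
        for c in self.classes.values():
            if c.density_mean < 0 or c.density_sd < 0:
                raise ValueError(f"negative density for class {c.class_id!r}")

    def at_level(self, level: str) -> "HabitatTypology":
        """Return the typology restricted to another hierarchy level."""
        if level == self.level:
            return self
        classes = {
            cid: c for cid, c in self.all_classes.items() if c.level == level
        }
        return HabitatTypology(
            level=level,
            classes=classes,
            parent_map=self.parent_map,
            all_classes=self.all_classes,
        )

    def ancestor(self, class_id: str, level: str) -> str:
        """Class id of the ancestor of ``class_id`` at coarser ``level``."""
        cid = class_id
        seen = set()
        while self.all_classes[cid].level != level:
            if cid in seen:
                raise ValueError(f"parent chain loops at {cid!r}")
            seen.add(cid)
            if cid not in self.parent_map:
                raise ValueError(f"class {class_id!r} has no ancestor at {level}")
            cid = self.parent_map[cid]
        return cid


def _default_typology_path() -> Path:
    return Path(str(resources.files("reefscape").joinpath("data/typology.csv")))


def load_typology(table_file=None, level: str = "L3") -> HabitatTypology:
    """Load a typology CSV and return the typology at the requested level.

    The CSV has columns ``class_id, level3, level2, level1, depth_stratum,
    density_mean, density_sd``.  Rows with a ``level3`` entry define L3
    classes, rows with only ``level2`` define L2 classes, and the row with
    only ``level1`` defines the single L1 class.  Variable-depth rows may
    leave the density blank, in which case it is derived as the shallow
    counterpart's density divided by one hundred.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown typology level {level!r}")
    path = _default_typology_path() if table_file is None else table_file
    df = pd.read_csv(path, dtype={"class_id": str})
    required = {"class_id", "level3", "level2", "level1", "depth_stratum",
                "density_mean", "density_sd"}
    if not required.issubset(df.columns):
        raise ValueError(f"typology file missing columns {sorted(required - set(df.columns))}")
    df = df.copy()
    for col in ("level3", "level2", "level1", "depth_stratum"):
        df[col] = df[col].fillna("").astype(str).str.strip()

    def row_level(row):
        if row["level3"]:
            return "L3"
        if row["level2"]:
            return "L2"
        return "L1"

    df["level"] = df.apply(row_level, axis=1)

    # derive missing variable-depth densities from the shallow counterpart
    for i, row in df.iterrows():
        if np.isnan(row["density_mean"]):
            if row["depth_stratum"] != "variable_depth":
                raise ValueError(
                    f"missing density for shallow class {row['class_id']!r}"
                )
            lvl = row["level"]
            name_col = "level3" if lvl == "L3" else "level2"
            mask = (
                (df["level"] == lvl)
                & (df[name_col] == row[name_col])
                & (df["depth_stratum"] == "shallow")
            )
            if lvl == "L2":
                # the shallow L2 aggregate is the "Shallow reefs" row
                mask = (df["level"] == "L2") & (df["depth_stratum"] == "shallow")
            counterpart = df[mask]
            if counterpart.empty:
                raise ValueError(
                    f"no shallow counterpart for variable-depth class "
                    f"{row['class_id']!r}"
                )
            df.loc[i, "density_mean"] = counterpart["density_mean"].iloc[0] / 100.0
            df.loc[i, "density_sd"] = counterpart["density_sd"].iloc[0] / 100.0

    if (df["density_mean"] < 0).any() or (df["density_sd"] < 0).any():
        bad = df.loc[(df["density_mean"] < 0) | (df["density_sd"] < 0), "class_id"]
        raise ValueError(f"negative density for class(es) {list(bad)}")

    all_classes = {}
    for _, row in df.iterrows():
        name = row["level3"] or row["level2"] or row["level1"]
        all_classes[row["class_id"]] = TypologyClass(
            class_id=row["class_id"],
            name=name,
            level=row["level"],
            depth_stratum=row["depth_stratum"],
            density_mean=float(row["density_mean"]),
            density_sd=float(row["density_sd"]),
        )

    # parent links: L3 -> L2 row with the same level2 name, L2 -> the L1 row
    parent_map = {}
    l2_by_name = {
        row["level2"]: row["class_id"]
        for _, row in df[df["level"] == "L2"].iterrows()
    }
    l1_rows = df[df["level"] == "L1"]
    if len(l1_rows) != 1:
        raise ValueError("typology must define exactly one L1 class")
    l1_id = l1_rows["class_id"].iloc[0]
    for _, row in df.iterrows():
        if row["level"] == "L3":
            if row["level2"] not in l2_by_name:
                raise ValueError(
                    f"L3 class {row['class_id']!r} has no L2 parent "
                    f"{row['level2']!r}"
                )
            parent_map[row["class_id"]] = l2_by_name[row["level2"]]
        elif row["level"] == "L2":
            parent_map[row["class_id"]] = l1_id
        else:
            parent_map[row["class_id"]] = l1_id

    classes = {cid: c for cid, c in all_classes.items() if c.level == level}
    return HabitatTypology(
        level=level, classes=classes, parent_map=parent_map,
        all_classes=all_classes,
    )


@dataclass
class PatchGrid:
    """Gridded mosaic of reef habitat patches.

    ``patches`` is indexed by integer patch_id with columns ``lon``, ``lat``
    (cell centers, degrees), ``N`` (abundance, NaN until a density
    realization is drawn) and ``sampled_site_code`` (site code of an attached
    genetic sampling location, or None).  ``class_areas`` is a patch x class
    table of reef areas in hectares.
    """

    resolution: float
    patches: pd.DataFrame
    class_areas: pd.DataFrame

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not self.patches.index.is_unique:
            raise ValueError("patch ids must be unique")
        if (self.class_areas.values < 0).any():
            raise ValueError("negative class areas")
        totals = self.class_areas.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("patches must have positive total reef area")

    @property
    def patch_ids(self) -> np.ndarray:
        return self.patches.index.to_numpy()

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def total_area_ha(self) -> float:
        return float(self.class_areas.values.sum())

    @property
    def abundance(self) -> np.ndarray:
        return self.patches["N"].to_numpy(dtype=float)

    @property
    def sampled_sites(self) -> dict:
        """Mapping site_code -> patch_id for sampled patches."""
        mask = self.patches["sampled_site_code"].notna()
        sub = self.patches.loc[mask, "sampled_site_code"]
        return {code: pid for pid, code in sub.items()}

    def copy(self) -> "PatchGrid":
        return PatchGrid(
            resolution=self.resolution,
            patches=self.patches.copy(),
            class_areas=self.class_areas.copy(),
        )

    def subset(self, patch_ids) -> "PatchGrid":
        patch_ids = list(patch_ids)
        return PatchGrid(
            resolution=self.resolution,
            patches=self.patches.loc[patch_ids].copy(),
            class_areas=self.class_areas.loc[patch_ids].copy(),
        )

    def attach_sites(self, sites: pd.DataFrame) -> "PatchGrid":
        """Attach genetic sampling sites (columns: code, lon, lat).

        A site is attached to the patch whose cell contains its coordinates;
        if that cell holds no reef patch the site is snapped to the nearest
        patch centroid (warning logged).
        """
        out = self.copy()
        lons = out.patches["lon"].to_numpy()
        lats = out.patches["lat"].to_numpy()
        half = self.resolution / 2.0
        for _, row in sites.iterrows():
            code, lon, lat = row["code"], row["lon"], row["lat"]
            inside = (np.abs(lons - lon) <= half) & (np.abs(lats - lat) <= half)
            if inside.any():
                pid = out.patches.index[np.argmax(inside)]
            else:
                d2 = (lons - lon) ** 2 + (lats - lat) ** 2
                pid = out.patches.index[int(np.argmin(d2))]
                logger.warning(
                    "site %s at (%.3f, %.3f) falls in a reef-free cell; "
                    "snapped to patch %s", code, lon, lat, pid,
                )
            out.patches.loc[pid, "sampled_site_code"] = code
        return out

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path, sidecar: dict | None = None) -> None:
        """Serialize as long-format CSV plus a JSON sidecar."""
        path = Path(path)
        rows = []
        for pid in self.patches.index:
            p = self.patches.loc[pid]
            for cid in self.class_areas.columns:
                area = self.class_areas.loc[pid, cid]
                if area > 0:
                    rows.append(
                        dict(patch_id=pid, lon=p["lon"], lat=p["lat"],
                             class_id=cid, area_ha=area, N=p["N"],
                             sampled_site_code=p["sampled_site_code"])
                    )
        pd.DataFrame(rows).to_csv(path, index=False)
        meta = {"resolution": self.resolution}
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "PatchGrid":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        areas = df.pivot_table(index="patch_id", columns="class_id",
                               values="area_ha", fill_value=0.0)
        first = df.drop_duplicates("patch_id").set_index("patch_id")
        patches = first[["lon", "lat", "N", "sampled_site_code"]].copy()
        patches["sampled_site_code"] = patches["sampled_site_code"].where(
            patches["sampled_site_code"].notna(), None
        )
        patches = patches.loc[areas.index]
        return cls(resolution=meta["resolution"], patches=patches,
                   class_areas=areas)


def _empty_patch_frame(index) -> pd.DataFrame:
    df = pd.DataFrame(index=index)
    df["lon"] = np.nan
    df["lat"] = np.nan
    df["N"] = np.nan
    df["sampled_site_code"] = None
    return df


def grid_habitat(habitat, land: Raster | None = None,
                 resolution: float = 0.25, code_map: dict | None = None) -> PatchGrid:
    """Grid a habitat map into a :class:`PatchGrid`.

    Parameters
    ----------
    habitat : Raster or iterable of (shapely geometry, class_id)
        Habitat map.  A raster holds integer class codes (0 = no reef) and
        requires ``code_map`` mapping codes to class ids.  Polygons carry
        their class id directly.
    land : Raster, optional
        Land mask sharing the geographic CRS; used only for validation.
    resolution : float
        Grid cell size in degrees; cell boundaries are aligned to multiples
        of the resolution.

    One patch is created per cell intersecting at least one habitat pixel or
    polygon; class areas are in hectares with a cos-latitude correction.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")

    accum: dict = {}  # (row_key, col_key) -> {class_id: area_ha}

    def add(key, cid, area):
        accum.setdefault(key, {})
        accum[key][cid] = accum[key].get(cid, 0.0) + area

    if isinstance(habitat, Raster):
        if code_map is None:
            raise ValueError("code_map is required for raster habitat input")
        vals = habitat.values.astype(int)
        rows, cols = np.nonzero(vals > 0)
        if rows.size == 0:
            raise ValueError("habitat raster contains no reef pixels")
        unknown = set(np.unique(vals[rows, cols])) - set(code_map)
        if unknown:
            raise ValueError(f"unknown habitat class code(s): {sorted(unknown)}")
        lon, lat = habitat.cell_center(rows, cols)
        pix_area = habitat.cell_area_ha(rows)
        ckey = np.floor(lon / resolution).astype(int)
        rkey = np.floor(lat / resolution).astype(int)
        for r, c, code, a in zip(rkey, ckey, vals[rows, cols], pix_area):
            add((int(r), int(c)), code_map[int(code)], float(a))
    else:
        geoms = list(habitat)
        if not geoms:
            raise ValueError("no habitat geometries supplied")
        for geom, cid in geoms:
            w, s, e, n = geom.bounds
            c0 = int(np.floor(w / resolution))
            c1 = int(np.floor(e / resolution))
            r0 = int(np.floor(s / resolution))
            r1 = int(np.floor(n / resolution))
            hit = False
            for rr in range(r0, r1 + 1):
                for cc in range(c0, c1 + 1):
                    cell = box(cc * resolution, rr * resolution,
                               (cc + 1) * resolution, (rr + 1) * resolution)
                    inter = geom.intersection(cell)
                    if inter.is_empty or inter.area == 0:
                        continue
                    hit = True
                    lat_c = (rr + 0.5) * resolution
                    deg2ha = (KM_PER_DEG ** 2) * np.cos(np.deg2rad(lat_c)) * HA_PER_KM2
                    add((rr, cc), cid, inter.area * deg2ha)
            if not hit:
                raise ValueError("habitat geometry does not overlap the grid")

    keys = sorted(accum)
    class_ids = sorted({cid for d in accum.values() for cid in d})
    index = pd.Index(range(len(keys)), name="patch_id")
    areas = pd.DataFrame(0.0, index=index, columns=class_ids)
    patches = _empty_patch_frame(index)
    for pid, (rk, ck) in enumerate(keys):
        for cid, a in accum[(rk, ck)].items():
            areas.loc[pid, cid] = a
        patches.loc[pid, "lon"] = (ck + 0.5) * resolution
        patches.loc[pid, "lat"] = (rk + 0.5) * resolution
    return PatchGrid(resolution=resolution, patches=patches, class_areas=areas)


def compute_abundance(grid: PatchGrid, typology: HabitatTypology,
                      seed: int | np.random.Generator = 0) -> PatchGrid:
    """Fill patch abundances from one random density realization.

    One Gaussian density is drawn per habitat class (shared by all patches of
    that class within the realization) and truncated at zero; the abundance
    of a patch is the sum over classes of density x class area.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing = set(grid.class_areas.columns) - set(typology.classes)
    if missing:
        raise ValueError(f"grid classes not in typology: {sorted(missing)}")
    out = grid.copy()
    density = {}
    for cid in sorted(typology.classes):
        c = typology.classes[cid]
        density[cid] = max(0.0, float(rng.normal(c.density_mean, c.density_sd)))
    dens_vec = np.array([density[cid] for cid in grid.class_areas.columns])
    out.patches["N"] = grid.class_areas.values @ dens_vec
    return out


def degrade_composition(grid: PatchGrid, typology: HabitatTypology,
                        to_level: str) -> PatchGrid:
    """Re-aggregate class areas to a coarser typology level.

    Geometry, patch count and sampled-site flags are unchanged; only the
    compositional detail (and hence which densities apply) is lost.
    """
    if to_level not in LEVELS:
        raise ValueError(f"unknown level {to_level!r}")
    out = grid.copy()
    mapping = {}
    for cid in grid.class_areas.columns:
        if cid not in typology.all_classes:
            raise ValueError(f"orphan class {cid!r} not in typology")
        if typology.all_classes[cid].level == to_level:
            mapping[cid] = cid
        else:
            mapping[cid] = typology.ancestor(cid, to_level)
    new_cols = sorted(set(mapping.values()))
    areas = pd.DataFrame(0.0, index=grid.class_areas.index, columns=new_cols)
    for cid in grid.class_areas.columns:
        areas[mapping[cid]] += grid.class_areas[cid]
    out.class_areas = areas
    out.patches["N"] = np.nan  # abundances must be redrawn at the new level
    return out


def fragment(grid: PatchGrid, removal_fraction: float,
             seed: int | np.random.Generator = 0,
             protected=None) -> PatchGrid:
    """Remove whole patches at random until a fraction of reef area is gone.

    Patches carrying a sampled genetic site (or listed in ``protected``) are
    never removed.  Removal proceeds in a seeded random order and stops at
    the first patch whose removal reaches the target area, so the target is
    overshot by at most one patch.  For a fixed seed the removed sets are
    nested across increasing ``removal_fraction``.
    """
    if not 0 <= removal_fraction < 1:
        raise ValueError("removal_fraction must be in [0, 1)")
    if removal_fraction == 0:
        return grid.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    protected = set(protected) if protected is not None else set(
        grid.sampled_sites.values()
    )
    areas = grid.class_areas.sum(axis=1)
    total = float(areas.sum())
    target = removal_fraction * total
    candidates = [pid for pid in grid.patches.index if pid not in protected]
    avail = float(areas.loc[candidates].sum())
    if target > avail + 1e-9:
        raise ValueError(
            f"removal_fraction {removal_fraction} exceeds unprotected area "
            f"fraction {avail / total:.3f}"
        )
    order = list(np.array(candidates)[rng.permutation(len(candidates))])
    removed, cum = [], 0.0
    for pid in order:
        if cum >= target:
            break
        removed.append(pid)
        cum += float(areas.loc[pid])
    keep = [pid for pid in grid.patches.index if pid not in set(removed)]
    return grid.subset(keep)
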