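"""Synthetic study systems with known ground truth.

Everything the pipeline consumes can be generated here: a multi-archipelago
reefscape (habitat class raster + land mask), a divergence-free current
field with a jet and eddies, and "observed" genotype datasets produced by
running the gene-flow model forward under a known dispersal kernel with
per-patch Wright-Fisher drift and multinomial sampling of individuals.

Drift is deliberately added to the truth generator even though the forward
projection used for fitting is purely deterministic: without it the truth
would homogenize completely and carry no recoverable structure, whereas real
populations hold a migration-drift balance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .dispersal import ibd_matrix
from .geneflow import (
    GeneFlowConfig,
    build_migrant_matrix,
    init_state,
    transition_matrix,
)
from .habitat import PatchGrid, _empty_patch_frame
from .popgen import GenotypeTable, SiteGenotypes, write_genepop
from .raster import Raster

logger = logging.getLogger(__name__)

#: Specimen counts per sampled location in the empirical survey that the
#: generator emulates (23 sites, 11 to 48 individuals each).
TABLE2_SAMPLE_SIZES = (
    14, 19, 38, 43, 27, 24, 45, 45, 45, 45, 43, 48,
    46, 47, 25, 47, 38, 46, 11, 22, 41, 42, 41,
)

#: Habitat class codes for synthetic habitat rasters.
CODE_MAP = {
    1: "fringing_s",
    2: "outer_barrier_s",
    3: "intermediate_s",
    4: "atoll_bank_s",
    5: "oceanic_island_s",
    6: "fringing_v",
    7: "outer_barrier_v",
}


@dataclass
class SyntheticScenario:
    """Parameters of a ground-truth scenario."""

    seed: int = 0
    true_a: float = 0.90
    n_sites_sampled: int = 12
    individuals_per_site: tuple = TABLE2_SAMPLE_SIZES
    n_loci: int = 15
    alleles_per_locus: int = 10
    drift_mode: str = "wright_fisher"  # or "none"
    ne_cap: int = 500
    t_truth: int = 100
    f: float = 0.1

    def __post_init__(self) -> None:
        if self.drift_mode not in ("none", "wright_fisher"):
            raise ValueError(f"unknown drift_mode {self.drift_mode!r}")
        if min(self.n_sites_sampled, self.n_loci, self.alleles_per_locus,
               self.t_truth) < 1:
            raise ValueError("scenario counts must be positive")


def recovery_scenario(seed: int, true_a: float) -> SyntheticScenario:
    """Study conditions of the desk-scale parameter-recovery experiment.

    A 20-patch clustered toy, 16 sampled sites with survey-like sample
    sizes, 15 loci, Wright-Fisher drift capped at Ne = 500, and a truth
    horizon matching the 50-generation scan horizon.
    """
    return SyntheticScenario(
        seed=seed, true_a=true_a, n_sites_sampled=16, n_loci=15,
        alleles_per_locus=10, drift_mode="wright_fisher", ne_cap=500,
        t_truth=50, f=0.1,
    )


# ---------------------------------------------------------------------------
# Reefscape geometry

def toy_patch_grid(n_patches: int = 20, seed: int = 0,
                   n_clusters: int = 4, cluster_span_deg: float = 0.35,
                   domain=(162.0, 166.0, -22.0, -18.0)) -> PatchGrid:
    """Abstract clustered patch layout for desk-scale experiments.

    Patches are grouped into archipelago-like clusters: within-cluster
    spacing of a few tens of km, between-cluster spacing of 100+ km, so an
    IBD kernel produces contrast at both scales.  Areas are uniform draws on
    50-500 ha of a single shallow reef class, and abundances are filled with
    a fixed fringing-reef density (256 ind/ha): with a single class a shared
    Gaussian draw would zero out entire realizations, so the toy keeps
    density deterministic and leaves stochasticity to initial frequencies
    and drift.
    """
    rng = np.random.default_rng(seed)
    w, e, s, n = domain
    centers = np.column_stack([
        rng.uniform(w + 0.5, e - 0.5, n_clusters),
        rng.uniform(s + 0.5, n - 0.5, n_clusters),
    ])
    # enforce a minimum cluster separation by resampling pathological draws
    for _ in range(200):
        d = np.hypot(centers[:, 0, None] - centers[None, :, 0],
                     centers[:, 1, None] - centers[None, :, 1])
        np.fill_diagonal(d, np.inf)
        if d.min() > 1.0:
            break
        k = np.unravel_index(np.argmin(d), d.shape)[0]
        centers[k] = [rng.uniform(w + 0.5, e - 0.5),
                      rng.uniform(s + 0.5, n - 0.5)]
    sizes = np.full(n_clusters, n_patches // n_clusters)
    sizes[: n_patches % n_clusters] += 1
    index = pd.Index(range(n_patches), name="patch_id")
    patches = _empty_patch_frame(index)
    lon, lat = [], []
    for c, size in zip(centers, sizes):
        lon.extend(c[0] + rng.uniform(-cluster_span_deg, cluster_span_deg, size))
        lat.extend(c[1] + rng.uniform(-cluster_span_deg, cluster_span_deg, size))
    patches["lon"] = lon
    patches["lat"] = lat
    areas = pd.DataFrame(
        {"fringing_s": rng.uniform(50.0, 500.0, n_patches)}, index=index
    )
    patches["N"] = 256.0 * areas["fringing_s"].to_numpy()
    return PatchGrid(resolution=0.25, patches=patches, class_areas=areas)


def make_reefscape(seed: int = 0, domain=(160.0, 168.0, -23.0, -14.0),
                   habitat_resolution: float = 0.1,
                   land_resolution: float = 0.1):
    """Synthetic multi-archipelago reefscape.

    Returns ``(habitat, code_map, land)`` where ``habitat`` is a raster of
    habitat class codes (0 = no reef) and ``land`` a boolean land raster.
    The geography emulates a barrier-reef mainland with fringing and outer
    barrier reefs, an atoll group to the northwest, and an isolated island
    group to the east, giving at least two reef groups disconnected by
    distance.
    """
    rng = np.random.default_rng(seed)
    w, e, s, n = domain
    nrows = int(round((n - s) / land_resolution))
    ncols = int(round((e - w) / land_resolution))
    land = np.zeros((nrows, ncols), dtype=int)
    lr = Raster(land, west=w, south=s, resolution=land_resolution)
    lon_g, lat_g = np.meshgrid(lr.lon_centers, lr.lat_centers)

    # elongated mainland (NW-SE oriented ellipse) in the west-center
    cx, cy = w + 0.35 * (e - w), s + 0.45 * (n - s)
    ux = (lon_g - cx) * np.cos(0.6) + (lat_g - cy) * np.sin(0.6)
    uy = -(lon_g - cx) * np.sin(0.6) + (lat_g - cy) * np.cos(0.6)
    mainland = (ux / 1.8) ** 2 + (uy / 0.45) ** 2 < 1.0
    # small eastern island
    ix, iy = w + 0.85 * (e - w), s + 0.55 * (n - s)
    island = ((lon_g - ix) ** 2 + (lat_g - iy) ** 2) < 0.15 ** 2
    land_mask = mainland | island
    lr = Raster(land_mask.astype(int), west=w, south=s,
                resolution=land_resolution)

    hrows = int(round((n - s) / habitat_resolution))
    hcols = int(round((e - w) / habitat_resolution))
    hab = np.zeros((hrows, hcols), dtype=int)
    hr = Raster(hab, west=w, south=s, resolution=habitat_resolution)
    hlon, hlat = np.meshgrid(hr.lon_centers, hr.lat_centers)
    hux = (hlon - cx) * np.cos(0.6) + (hlat - cy) * np.sin(0.6)
    huy = -(hlon - cx) * np.sin(0.6) + (hlat - cy) * np.cos(0.6)
    rad = np.sqrt((hux / 1.8) ** 2 + (huy / 0.45) ** 2)
    # lagoon side (huy < 0) of the reef complex is variable-depth habitat,
    # holding the hundred-fold lower densities that make the composition
    # levels genuinely different
    deep_side = huy < 0
    fring = (rad >= 1.0) & (rad < 1.25)
    barrier = (rad >= 1.55) & (rad < 1.75)
    hab[fring] = 1
    hab[fring & deep_side] = 6
    hab[barrier] = 2
    hab[barrier & deep_side] = 7
    inter = (rad >= 1.25) & (rad < 1.55) & (rng.random(hab.shape) < 0.25)
    hab[inter] = 3
    # broad variable-depth apron outside the barrier
    apron = (rad >= 1.75) & (rad < 2.05) & (rng.random(hab.shape) < 0.5)
    hab[apron & deep_side] = 7
    hab[apron & ~deep_side] = 6
    # NW atoll group
    for _ in range(4):
        ax = w + (e - w) * rng.uniform(0.05, 0.2)
        ay = s + (n - s) * rng.uniform(0.75, 0.95)
        ring = np.sqrt((hlon - ax) ** 2 + (hlat - ay) ** 2)
        hab[(ring >= 0.10) & (ring < 0.22)] = 4
    # eastern island fringing reef
    iring = np.sqrt((hlon - ix) ** 2 + (hlat - iy) ** 2)
    hab[(iring >= 0.15) & (iring < 0.35)] = 5
    # reef never overlaps land
    lrow, lcol = lr.cell_index(hlon.ravel(), hlat.ravel())
    on_land = lr.values[lrow, lcol].astype(bool).reshape(hab.shape)
    hab[on_land] = 0
    habitat = Raster(hab, west=w, south=s, resolution=habitat_resolution)
    return habitat, dict(CODE_MAP), lr


def make_currents(domain=(160.0, 168.0, -23.0, -14.0), jet_speed: float = 0.3,
                  n_eddies: int = 3, seed: int = 0,
                  resolution: float = 0.25, n_times: int = 1) -> xr.Dataset:
    """Divergence-free synthetic current field (steady jet + eddies).

    Velocities derive from a streamfunction, u = -dpsi/dy, v = dpsi/dx,
    evaluated with the same central differences a finite-difference
    divergence check would use, so the discrete divergence vanishes to
    rounding error.  A constant metre-per-degree metric (f-plane style) is
    used so the scale factors commute with the difference operators.
    Units are m/s; dims are (time, lat, lon) with time in days.
    """
    rng = np.random.default_rng(seed)
    w, e, s, n = domain
    lon = np.arange(w, e + resolution / 2, resolution)
    lat = np.arange(s, n + resolution / 2, resolution)
    LON, LAT = np.meshgrid(lon, lat)
    m_per_deg = 111_194.9
    # jet: eastward band centred mid-domain
    lat0 = (s + n) / 2.0
    width = (n - s) / 8.0
    psi = -jet_speed * (width * m_per_deg) * np.tanh((LAT - lat0) / width)
    for _ in range(n_eddies):
        ex = rng.uniform(w + 1, e - 1)
        ey = rng.uniform(s + 1, n - 1)
        sig = rng.uniform(0.4, 1.0)
        amp = rng.uniform(-0.5, 0.5) * (sig * m_per_deg)
        r2 = (LON - ex) ** 2 + (LAT - ey) ** 2
        psi = psi + amp * np.exp(-r2 / (2 * sig ** 2))
    dpsi_dlat = np.gradient(psi, lat, axis=0)
    dpsi_dlon = np.gradient(psi, lon, axis=1)
    u = -dpsi_dlat / m_per_deg
    v = dpsi_dlon / m_per_deg
    time = np.arange(n_times, dtype=float)
    U = np.broadcast_to(u, (n_times, *u.shape)).copy()
    V = np.broadcast_to(v, (n_times, *v.shape)).copy()
    return xr.Dataset(
        {"u": (("time", "lat", "lon"), U), "v": (("time", "lat", "lon"), V)},
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"description": "synthetic divergence-free surface currents",
               "units": "m s-1"},
    )


# ---------------------------------------------------------------------------
# Ground-truth genotypes

def wright_fisher_resample(Q: np.ndarray, n_eff: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """One generation of per-patch binomial/multinomial drift.

    Each patch x locus frequency vector is replaced by the allele
    frequencies of ``2 * n_eff`` sampled gene copies.
    """
    n, L, K = Q.shape
    out = np.empty_like(Q)
    copies = (2 * n_eff).astype(int)
    for i in range(n):
        if copies[i] < 2:
            out[i] = Q[i]
            continue
        for l in range(L):
            out[i, l] = rng.multinomial(copies[i], Q[i, l]) / copies[i]
    return out


def assign_sampled_sites(grid: PatchGrid, n_sites: int,
                         rng: np.random.Generator) -> PatchGrid:
    """Mark ``n_sites`` patches as genetic sampling sites (codes S01, S02...).

    Sites are spread across the layout by greedy farthest-point selection so
    every archipelago is represented, mimicking a survey design.  When
    abundances are available, candidates are limited to the upper half of
    the abundance distribution: field surveys target reefs where the species
    is actually found, never near-empty variable-depth patches.
    """
    if n_sites > grid.n_patches:
        raise ValueError("cannot sample more sites than patches")
    lon = grid.patches["lon"].to_numpy()
    lat = grid.patches["lat"].to_numpy()
    N = grid.abundance
    if not np.isnan(N).any():
        cutoff = np.median(N[N > 0]) if (N > 0).any() else 0.0
        candidates = np.nonzero(N >= cutoff)[0]
    else:
        candidates = np.arange(grid.n_patches)
    if len(candidates) < n_sites:
        candidates = np.arange(grid.n_patches)
    blocked = np.ones(grid.n_patches, dtype=bool)
    blocked[candidates] = False
    chosen = [int(rng.choice(candidates))]
    while len(chosen) < n_sites:
        d = np.full(grid.n_patches, np.inf)
        for k in chosen:
            d = np.minimum(d, (lon - lon[k]) ** 2 + (lat - lat[k]) ** 2)
        d[chosen] = -np.inf
        d[blocked] = -np.inf
        # soften determinism: pick among the top-3 farthest
        top = np.argsort(d)[-3:]
        top = top[d[top] > -np.inf]
        chosen.append(int(rng.choice(top)))
    out = grid.copy()
    for rank, idx in enumerate(sorted(chosen)):
        pid = out.patches.index[idx]
        out.patches.loc[pid, "sampled_site_code"] = f"S{rank + 1:02d}"
    return out


def run_truth(scenario: SyntheticScenario, grid: PatchGrid, dist,
              rng: np.random.Generator):
    """Forward-simulate patch allele frequencies under the true kernel.

    The projection is stepped generation by generation so Wright-Fisher
    drift (effective size ``min(N_i, ne_cap)``) can be injected after each
    migration update.  Returns the final (patch, locus, allele) array.
    """
    D = ibd_matrix(dist, a=scenario.true_a, normalize=True)
    cfg = GeneFlowConfig(
        n_replicates=1, n_loci=scenario.n_loci,
        alleles_per_locus=scenario.alleles_per_locus,
        generations=scenario.t_truth, f=scenario.f, seed=scenario.seed,
    )
    M = build_migrant_matrix(grid, D, scenario.f)
    P = transition_matrix(M)
    state = init_state(cfg, grid.n_patches, seed=rng)
    Q = state.Q
    n_eff = np.minimum(np.maximum(grid.abundance, 2.0), scenario.ne_cap)
    flatshape = (grid.n_patches, -1)
    for _ in range(scenario.t_truth):
        Q = (P @ Q.reshape(flatshape)).reshape(Q.shape)
        Q = Q / Q.sum(axis=2, keepdims=True)
        if scenario.drift_mode == "wright_fisher":
            Q = wright_fisher_resample(Q, n_eff, rng)
    return Q


def sample_genotypes(Q: np.ndarray, grid: PatchGrid,
                     individuals_per_site, rng: np.random.Generator,
                     loci=None) -> GenotypeTable:
    """Draw diploid individuals multinomially from patch allele frequencies."""
    sampled = grid.sampled_sites
    codes = sorted(sampled)
    if not codes:
        raise ValueError("grid has no sampled sites")
    pos = {pid: i for i, pid in enumerate(grid.patches.index)}
    n_loci, n_alleles = Q.shape[1], Q.shape[2]
    loci = loci or [f"Locus{j + 1}" for j in range(n_loci)]
    sizes = list(individuals_per_site)
    sites = []
    for k, code in enumerate(codes):
        n_ind = int(sizes[k % len(sizes)])
        q = Q[pos[sampled[code]]]
        calls = np.zeros((n_ind, n_loci, 2), dtype=int)
        for j in range(n_loci):
            draws = rng.choice(n_alleles, size=(n_ind, 2), p=q[j])
            calls[:, j, :] = draws + 1  # allele codes are 1-based
        names = [f"{code}_{i + 1:03d}" for i in range(n_ind)]
        sites.append(SiteGenotypes(code=code, individuals=names, calls=calls))
    return GenotypeTable(loci=loci, sites=sites)


def make_observed_genotypes(scenario: SyntheticScenario, grid: PatchGrid,
                            dist, out_dir=None):
    """Generate an "observed" genotype dataset with a known dispersal truth.

    Runs the gene-flow model under the scenario's true kernel (with optional
    Wright-Fisher drift), samples individuals at the grid's sampled sites,
    and optionally writes a GENEPOP file plus a JSON truth manifest.

    Returns ``(table, truth_Q, manifest)``.
    """
    rng = np.random.default_rng(scenario.seed)
    if not grid.sampled_sites:
        grid = assign_sampled_sites(grid, scenario.n_sites_sampled, rng)
    if np.isnan(grid.abundance).any():
        raise ValueError("grid abundances not set; run compute_abundance first")
    Q = run_truth(scenario, grid, dist, rng)
    table = sample_genotypes(Q, grid, scenario.individuals_per_site, rng)
    manifest = {
        "true_a": scenario.true_a,
        "seed": scenario.seed,
        "t_truth": scenario.t_truth,
        "f": scenario.f,
        "drift_mode": scenario.drift_mode,
        "ne_cap": scenario.ne_cap,
        "n_loci": scenario.n_loci,
        "alleles_per_locus": scenario.alleles_per_locus,
        "sites": {c: int(len(table.site(c).individuals))
                  for c in table.site_codes},
        "sampled_patches": {c: int(p) for c, p in grid.sampled_sites.items()},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genepop(table, out_dir / "observed.gen")
        (out_dir / "truth.json").write_text(json.dumps(manifest, indent=2))
    return table, Q, manifest
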