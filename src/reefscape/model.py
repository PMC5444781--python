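"""Model / results interface to the kernel-fitting analysis.

:class:`ReefscapeModel` bundles the data a fit needs — an observed genetic
distance matrix over sampled sites, the patch grid, and the over-water
geographic distances — and ``fit()`` scans the isolation-by-distance decay
base, returning a :class:`ReefscapeResults` with the selected kernel, its
Mantel correlation and permutation p-value, and the full scan table.
Sensitivity analyses and plots hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import (
    MantelResult,
    ScanResult,
    mantel,
    scan_kernels,
    sensitivity_experiment,
)
from .dispersal import default_scan_grid, ibd_matrix
from .geneflow import GeneFlowConfig, run_simulation, simulated_distance_matrix
from .popgen import allele_freqs, site_chord_matrix, standardize


class ReefscapeModel:
    """Fit a larval dispersal kernel to observed genetic structure.

    Parameters
    ----------
    observed : DataFrame or ndarray
        Observed genetic distance matrix over the sampled sites.  A
        DataFrame is reordered to the grid's sampled site codes; an ndarray
        must already follow site-code order (sorted).
    grid : PatchGrid
        Habitat patch grid with sampled sites attached and, unless a
        typology is supplied, abundances filled.
    distances : GeoDistanceMatrix
        Over-water distances between all patches, km.
    config : GeneFlowConfig, optional
        Gene-flow simulation settings (replicates, loci, horizon, fertility).
    typology : HabitatTypology, optional
        When given, every replicate draws a fresh density realization.
    scan_grid : array-like, optional
        Candidate decay bases; defaults to 0.40..0.99 step 0.01.
    """

    def __init__(self, observed, grid, distances, config=None, typology=None,
                 scan_grid=None):
        self.grid = grid
        self.distances = distances
        self.config = config or GeneFlowConfig()
        self.typology = typology
        self.scan_grid = (np.asarray(scan_grid, dtype=float)
                          if scan_grid is not None else default_scan_grid())
        sampled = grid.sampled_sites
        if len(sampled) < 3:
            raise ValueError("need at least 3 sampled sites")
        self.site_codes = sorted(sampled)
        self.sampled_patch_ids = [sampled[c] for c in self.site_codes]
        if isinstance(observed, pd.DataFrame):
            missing = set(self.site_codes) - set(observed.index)
            if missing:
                raise ValueError(f"observed matrix missing sites {sorted(missing)}")
            observed = observed.loc[self.site_codes, self.site_codes].to_numpy()
        observed = np.asarray(observed, dtype=float)
        if observed.shape != (len(self.site_codes),) * 2:
            raise ValueError("observed matrix does not match sampled sites")
        self.observed = np.asarray(standardize(observed), dtype=float)

    @classmethod
    def from_genotypes(cls, table, grid, distances, **kwargs):
        """Build the model from a genotype table (chord distances computed)."""
        saf = allele_freqs(table)
        codes = sorted(set(table.site_codes) & set(grid.sampled_sites))
        if len(codes) < 3:
            raise ValueError("fewer than 3 genotyped sites match the grid")
        obs = site_chord_matrix(saf, sites=codes)
        return cls(standardize(obs), grid, distances, **kwargs)

    def fit(self, n_permutations: int = 999, seed: int | None = None) -> "ReefscapeResults":
        """Scan the kernel grid and test the best kernel's Mantel correlation."""
        scan = scan_kernels(
            self.observed, self.grid, self.distances, self.config,
            scan_grid=self.scan_grid, typology=self.typology,
            sampled_patch_ids=self.sampled_patch_ids,
        )
        seed = self.config.seed if seed is None else seed
        best = scan.best_a
        if np.isnan(best):
            mantel_res = MantelResult(r=np.nan, p=np.nan,
                                      n_permutations=n_permutations, seed=seed)
            sim = None
        else:
            D = ibd_matrix(self.distances, a=best, normalize=True)
            ens = run_simulation(self.grid, D, self.config,
                                 typology=self.typology)
            sim = simulated_distance_matrix(ens, self.sampled_patch_ids)
            mantel_res = mantel(self.observed, np.asarray(sim, dtype=float),
                                n_permutations=n_permutations, seed=seed)
        return ReefscapeResults(model=self, scan=scan, best_a=best,
                                mantel_result=mantel_res,
                                simulated=sim)


@dataclass
class ReefscapeResults:
    """Results of a kernel scan: best decay base and its support."""

    model: ReefscapeModel
    scan: ScanResult
    best_a: float
    mantel_result: MantelResult
    simulated: np.ndarray | None = None

    @property
    def scan_table(self) -> pd.DataFrame:
        return self.scan.table

    def summary(self) -> str:
        t = self.scan.table
        lines = [
            "Reefscape dispersal-kernel fit",
            "=" * 46,
            f"sampled sites:        {len(self.model.site_codes)}",
            f"habitat patches:      {self.model.grid.n_patches}",
            f"kernel grid:          {t['a'].min():.2f}..{t['a'].max():.2f}"
            f" ({len(t)} values)",
            f"replicates per value: {self.model.config.n_replicates}",
            f"generations:          {self.model.config.generations}",
            f"fertility f:          {self.model.config.f:g}",
            "-" * 46,
            f"best decay base a:    {self.best_a:.2f}",
        ]
        row = t.loc[t["a"] == self.best_a]
        if len(row):
            r = row.iloc[0]
            lines.append(
                f"median Mantel r:      {r['r_median']:.3f} "
                f"[{r['r_q05']:.3f}, {r['r_q95']:.3f}]"
            )
        lines.append(
            f"Mantel test:          r = {self.mantel_result.r:.3f}, "
            f"p = {self.mantel_result.p:.4g} "
            f"({self.mantel_result.n_permutations} permutations)"
        )
        return "\n".join(lines)

    def sensitivity(self, typology, n_replicates: int = 99, seed: int = 0,
                    fragmentation_levels=(0.0, 0.2, 0.4, 0.6, 0.8),
                    composition_levels=("L3", "L2", "L1"),
                    external_D=None) -> pd.DataFrame:
        """Composition x fragmentation sensitivity table at the fitted kernel."""
        return sensitivity_experiment(
            self.model.observed, self.model.grid, typology, self.best_a,
            self.model.config, dist=self.model.distances,
            fragmentation_levels=fragmentation_levels,
            composition_levels=composition_levels,
            n_replicates=n_replicates, seed=seed, external_D=external_D,
        )

    def plot_scan(self, ax=None):
        """Median Mantel r (with 5-95% band) against the decay base."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.scan.table
        ax.plot(t["a"], t["r_median"], color="C0", label="median r")
        ax.fill_between(t["a"], t["r_q05"], t["r_q95"], alpha=0.25,
                        color="C0", label="5-95% replicates")
        ax.axvline(self.best_a, ls="--", color="C3",
                   label=f"best a = {self.best_a:.2f}")
        ax.set_xlabel("IBD decay base a")
        ax.set_ylabel("Mantel r (simulated vs observed)")
        ax.legend()
        return ax
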