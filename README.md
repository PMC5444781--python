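# reefscape

Seascape genetics of patchy coral-reef habitat: does the composition (which
habitat types, at which densities) and configuration (where the patches are,
how fragmented) of a reefscape shape the spatial genetic structure of a
sedentary reef invertebrate with a short pelagic larval phase?

The package implements a forward modelling chain for giant-clam-like species
on multi-archipelago reefscapes:

1. **Habitat** — a benthic habitat map is gridded into 0.25° patches; a
   three-level geomorphological typology (L1 all reef; L2 shallow vs
   variable-depth; L3 six classes per depth stratum) assigns each class a
   Gaussian density (ind·ha⁻¹), with variable-depth densities fixed at 1/100
   of their shallow counterparts. Patch abundance is
   `N_i = Σ_c density_c × area_{ic}`.
2. **Geographic distance** — over-water shortest paths between patch
   centroids on a 0.1° rasterized land mask (8-connected Dijkstra with
   great-circle edge lengths).
3. **Dispersal kernels** — isolation by distance (IBD),
   `P_ij = a^{d_ij}` with decay base `a ∈ (0,1)` scanned over 0.40–0.99 in
   steps of 0.01, and an isolation-by-oceanographic-distance (IBOD)
   surrogate: Lagrangian particle tracking in a gridded current field with a
   9-day precompetency period, settlement on the first reef cell entered
   during days 9–19, and exponentially decaying survival.
4. **Gene flow** — a matrix projection of allele frequencies,
   `Q_{t+1} = norm(A Q_t + N Q_t)` with migrant matrix
   `A[j,i] = f · N_i · D_ij` (`f` a fertility rate), run from random initial
   frequencies (99 replicates by default). Migration is the only force, so
   connected patches homogenize; the *rate pattern* of homogenization is the
   model's signal.
5. **Comparison** — Cavalli-Sforza & Edwards chord distances
   `d_l = (2√2/π)·√(1 − Σ_a √(p_a q_a))` between sampled sites, standardized
   to maximum 1, compared with the observed genetic distance matrix by
   Mantel correlation; the kernel scan picks the decay base with the highest
   median r, and a sensitivity design crosses typology degradation
   (L3→L2→L1) with random habitat fragmentation (20–80% area removal,
   sampled sites protected).

Everything runs on synthetic study systems with known ground truth: a
reefscape generator (barrier-reef mainland, atoll group, isolated island),
a divergence-free current generator (jet + eddies), and an "observed"
genotype generator that adds per-patch Wright–Fisher drift and multinomial
individual sampling on top of the projection model, written as GENEPOP
files.

## Worked example

```python
import numpy as np
from reefscape import GeneFlowConfig, ReefscapeModel, allele_freqs, site_chord_matrix, standardize
from reefscape.geodistance import greatcircle_matrix
from reefscape.synthetic import (SyntheticScenario, assign_sampled_sites,
                                 make_observed_genotypes, toy_patch_grid)

grid = toy_patch_grid(20, seed=0)                       # 4 clusters, 20 patches
grid = assign_sampled_sites(grid, 16, np.random.default_rng(0))
dist = greatcircle_matrix(grid)

truth = SyntheticScenario(seed=0, true_a=0.90, n_sites_sampled=16, t_truth=50)
table, _, _ = make_observed_genotypes(truth, grid, dist)  # GENEPOP-style data

model = ReefscapeModel.from_genotypes(
    table, grid, dist,
    config=GeneFlowConfig(n_replicates=20, generations=50, f=0.1, seed=1))
res = model.fit(n_permutations=999, seed=2)
print(res.summary())
```

prints

```
Reefscape dispersal-kernel fit
==============================================
sampled sites:        16
habitat patches:      20
kernel grid:          0.40..0.99 (60 values)
replicates per value: 20
generations:          50
fertility f:          0.1
----------------------------------------------
best decay base a:    0.91
median Mantel r:      0.812 [0.762, 0.833]
Mantel test:          r = 0.816, p = 0.001 (999 permutations)
```

The scan recovers the decay base the data were generated with
(`a* = 0.90`, recovered 0.91),
and the permutation test confirms the fitted kernel's simulated genetic
distances correlate with the "observed" ones far beyond chance.
`res.sensitivity(typology)` then quantifies how much of that agreement
survives habitat degradation, and `res.plot_scan()` draws the scan profile.

A full pipeline run (synthetic inputs → grid → distances → scan →
sensitivity, with a manifest and byte-identical reruns) is available as

```bash
reefscape synth --out synthetic --seed 7
reefscape run --config run.yaml --seed 7
```

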