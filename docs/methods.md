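# Methods

## Model overview

The package models spatial genetic structure as the outcome of larval
migration alone across a mosaic of reef habitat patches. Three layers feed
the projection:

**Habitat composition.** A habitat map (raster of geomorphological class
codes, or class-tagged polygons) is gridded at 0.25° so that each
reef-bearing cell becomes one patch with per-class areas in hectares
(spherical-Earth cosine-latitude correction for cell geometry; a cell is a
patch only if its total reef area is positive). Densities come from a
three-level typology: L1 treats all reef as one class (224 ± 193 ind·ha⁻¹);
L2 separates shallow reef (224 ± 193) from variable-depth reef, whose
density is fixed at the shallow value divided by one hundred (no field
estimates exist for depth, so the hundred-fold rule is a structural
assumption, not a fit); L3 resolves six geomorphological classes per depth
stratum (shallow fringing 256 ± 272, intermediate 200 ± 84, outer barrier
329 ± 269, oceanic patch 104 ± 42, oceanic island 109 ± 93, atoll/bank
234 ± 0; variable-depth values are each /100). A density *realization* draws
one Gaussian value per class — shared by all patches of that class — and
truncates negatives to zero, so a realization represents one plausible
regional density field rather than independent patch noise. With the large
listed standard deviations, truncation at zero is common and intended: it
preserves non-negativity with less distortion than redrawing.

**Geographic distance.** Over-water distances are shortest paths on a 0.1°
rasterized land mask: water cells are nodes, 8-neighbour water pairs are
edges weighted by the great-circle distance between cell centers (so
diagonals carry their true geodesic length), and pairwise patch distances
come from Dijkstra runs. 8-connectivity bounds the discretization error at
roughly 8% of path length, against ~41% for 4-connectivity. Distances are
in kilometres; this unit choice is load-bearing because the dispersal
kernel's decay base is dimensionally tied to it. Centroids on land cells
are snapped to the nearest water cell with a logged warning.

**Dispersal.** Two kernels produce a row-indexed matrix
`D[source, destination]` of settlement probabilities.

* *Isolation by distance (IBD)*: raw weight `a^d` with `0 < a < 1`; `d = 0`
  gives weight 1, so self-recruitment dominates each row. Rows are
  normalized to settlement distributions by default, which makes the
  fertility rate the single knob for migration intensity (the raw kernel is
  only defined up to a scale). The scan grid is 0.40–0.99 by 0.01 — exactly
  60 candidate kernels. At the upper end (`a = 0.95`) the raw weight at
  150 km is below 10⁻³, i.e. effectively no dispersal beyond that range.
* *Isolation by oceanographic distance (IBOD)*: a particle-tracking
  surrogate. Particles are released at patch centroids (default one per
  patch per day), advected by bilinearly interpolated currents with a
  midpoint (2nd-order) scheme at a 1-hour step, cannot settle before day 9
  (precompetency), then settle in the first reef-bearing cell they enter up
  to day 19, contributing weight `exp(-λ(t − 9))` with `λ = ln(20)/10 ≈
  0.30 d⁻¹` so survival falls to 5% at the window's close. Particles
  stepping onto land are reflected to their previous position (killing them
  would empty coastal release cells); particles leaving the domain or
  outliving the window are lost. Rows are normalized by particles released,
  so row sums ≤ 1 and every particle is accounted settled or lost exactly.

**Gene flow.** For allele frequencies `Q` over (patch × locus × allele), one
generation is `Q_{t+1} = norm(A Q_t + N Q_t)`: resident adults (`N` copies
of the local frequencies) plus migrant progeny, where
`A[dest, source] = f · N_source · D[source → dest]` is time-invariant and
`f` is the per-adult fertility. The per-patch, per-locus renormalization
divides every allele by the same total, so the update is linear:
`Q_{t+1} = P Q_t` with `P = rownorm(A + diag(N))` row-stochastic. The
implementation exploits this with a matrix power (`run_simulation`), which
is bit-compatible (to 1e-10) with explicit stepping (`project_step`);
patches with no residents and no inflow become identity rows and carry
their frequencies forward. Because `P` is row-stochastic and (for connected,
positive migration) primitive, trajectories converge to a common frequency
vector — the model has no stationary structure, and all information lives in
*how fast* pairs of patches homogenize from random starts. Initial
frequencies are flat Dirichlet per patch × locus (defaults: 15 loci, 10
alleles per locus, matching a microsatellite panel), with 99 independent
replicates by default.

**Comparison.** Genetic distance between sites is the Cavalli-Sforza &
Edwards chord distance, per locus `d_l = (2√2/π)·√(1 − Σ_a √(p_a q_a))`,
averaged over loci (several variants of the constant exist in the
literature; since simulated matrices are standardized to a maximum of 1
before comparison, and Pearson correlation is scale-invariant, the choice
does not affect rankings). Simulated distances are averaged over replicates
and then standardized; replicate-level Mantel correlations drive the scan
ranking. The Mantel test is one-tailed (greater) with the (count+1)/(perm+1)
correction, Pearson by default; a Spearman column is reported as a
robustness check but never used for ranking. An exact enumeration mode
exists for small matrices. The kernel scan ranks decay bases by median
replicate r; the sensitivity design crosses typology level (L3/L2/L1) with
fragmentation (0–80% of reef area removed as whole unsampled patches,
seeded, with removed sets nested across fractions for a fixed seed) and
reports per-scenario medians with 5%/95% quantiles.

## Synthetic study systems

The generator produces every input the chain needs, with known truth:

* `make_reefscape` — a 0.1° land/habitat pair: an elongated mainland with a
  fringing belt, an outer barrier ring, scattered intermediate reef, a
  broad variable-depth apron, a northwest atoll group and an isolated
  eastern island (≥ 2 groups disconnected at the 100 km scale). The lagoon
  side of the reef complex is variable-depth habitat, so roughly half the
  mapped area carries hundred-fold lower densities — without that contrast,
  degrading the typology to L1 would cost the model nothing and the
  composition sensitivity would be vacuous.
* `make_currents` — a streamfunction-derived (hence discretely
  divergence-free) steady jet plus Gaussian eddies, in m/s on a lon/lat
  grid with a constant metre-per-degree metric.
* `make_observed_genotypes` — runs the projection under a known decay base
  `a*`, stepping generation by generation so per-patch Wright–Fisher
  resampling (effective size `min(N_i, 500)`, floor 2) can inject drift,
  then samples diploid individuals multinomially at the sampled sites and
  writes GENEPOP plus a JSON truth manifest. Drift is deliberately absent
  from the *fitting* model but present in the *truth*: a purely
  deterministic truth would homogenize completely and leave nothing to
  recover, while real data hold a migration–drift balance.
* `toy_patch_grid` — an abstract 20-patch, 4-cluster layout (within-cluster
  spacing tens of km, between-cluster 100+ km) used by the desk-scale
  recovery experiment. It carries a fixed fringing density (256 ind·ha⁻¹)
  instead of a Gaussian draw, because with a single habitat class the
  shared class draw would zero out ~17% of realizations wholesale.
* `assign_sampled_sites` — greedy farthest-point placement restricted to
  the upper half of the abundance distribution, mimicking surveys that
  sample where the organism is actually found; site sample sizes default to
  the 23 survey values (11–48 individuals).

## Study conditions of the built-in experiments

* *Kernel recovery*: truths `a* ∈ {0.85, 0.90, 0.95}` on the 20-patch toy,
  16 sampled sites, 15 loci × 10 alleles, drift capped at Ne = 500, truth
  horizon 50 generations; the scan uses 20 replicates per decay base at the
  same 50-generation horizon with `f = 0.1`. Matching the truth and scan
  horizons keeps the estimator centred; a longer truth horizon biases the
  recovered base upward by ~0.01–0.02.
* *Degradation sensitivity*: truth from the full synthetic L3 map
  (`a* = 0.9`), 14 sampled sites, 30 replicates per scenario of
  (fragment → degrade → redraw densities → project → Mantel), compared
  one-sidedly (Mann–Whitney) between 0% and 80% fragmentation and between
  L3 and L1 composition.

These scales (tens of patches, tens of replicates, 50 generations) are the
package's chosen desk-scale defaults; all are plain config values and grow
without code changes.

## Numerical choices and edge cases

* Simplex preservation is enforced to 1e-10 after every step; terminal
  renormalization removes matrix-power rounding drift.
* Chord distances below 1e-6 of the squared term (i.e. `1 − Σ√(pq) <
  1e-12`) are clamped to exactly zero: the square root otherwise amplifies
  ~1e-16 rounding noise between identical frequency vectors into ~1e-8
  distances, which standardization to max 1 would then inflate to order 1.
* An all-zero distance matrix is returned unchanged by standardization
  (with a warning), and a constant observed matrix yields undefined Mantel
  r, reported as NaN rather than a value.
* Distance and dispersal matrices serialize with 17 significant digits and
  re-parse with round-trip float precision; the pipeline always consumes
  the serialized distance matrix so cached and fresh runs follow an
  identical numerical path and reruns are byte-identical.
* Gaussian density draws are truncated at zero; `sd = 0` degenerates to the
  exact mean independent of seed.
* Fragmentation removes whole patches in a seeded random order until the
  target area is reached, overshooting by at most one patch; requesting
  more than the unprotected area is an error.

## What the synthetic tests do and do not show

Passing the recovery and sensitivity suites shows the chain is internally
consistent: data generated by this model, with drift and finite sampling,
lead back to the generating kernel, and degrading the habitat inputs
degrades the fit in the expected direction. It does not validate the model
against real populations — real microsatellite data carry null alleles,
selection, temporal variation in currents, and within-cell habitat detail
that the generator deliberately omits (no null-allele corrections are
implemented; synthetic data contain none). The IBOD surrogate is a
simplified tracker on synthetic currents, not an ocean model; matrices from
a full hydrodynamic simulation can be supplied via
`load_external_dispersal`.

## Known limitations

* Non-overlapping generations; no mutation, selection, or within-patch age
  structure.
* The projection is deterministic, so replicate spread reflects initial
  conditions and density draws only; drift exists solely in the synthetic
  truth generator.
* Mantel correlation is known to be sensitive to spatial autocorrelation;
  conclusions should rest on relative comparisons between scenarios, not on
  absolute r values (the Spearman column is a check, not a remedy).
* Distances assume larvae travel over water at equal cost everywhere;
  bathymetry and lagoon circulation are ignored.
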