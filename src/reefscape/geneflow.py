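"""Allele-frequency projection under migration.

The model tracks, for every habitat patch, the allele frequencies at a set
of unlinked codominant loci.  Each generation the patch receives migrant
progeny according to a time-invariant migrant matrix ``A`` (with
``A[dest, source] = f * N_source * D[source -> dest]``, ``f`` a fertility
rate and ``N`` the patch abundances) on top of its resident adults
(``N_dest`` copies of its own frequencies), and the result is renormalized
to the simplex per patch and locus.  Migration is the only evolutionary
force: there is no drift, mutation or selection, so connected systems
progressively homogenize and the *rate* at which pairs of patches converge
carries the signal that is compared with observed genetic structure.

Because the per-step renormalization divides every allele of a patch by the
same total, the update is linear: ``Q_{t+1} = P Q_t`` with
``P = rownorm(A + diag(N))``.  Patches with no residents and no inflow keep
their frequencies (identity row).  ``run_simulation`` exploits this with a
matrix power; ``project_step`` exposes the single-generation contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .popgen import chord_matrix, standardize

logger = logging.getLogger(__name__)


@dataclass
class GeneFlowConfig:
    n_replicates: int = 99
    n_loci: int = 15
    alleles_per_locus: int = 10
    generations: int = 100
    f: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_replicates", "n_loci", "alleles_per_locus",
                     "generations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.f <= 0:
            raise ValueError("fertility rate f must be positive")


@dataclass
class AlleleFrequencyState:
    """Allele frequencies Q over (patch, locus, allele) at one generation."""

    Q: np.ndarray
    generation: int = 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 3:
            raise ValueError("Q must have shape (patch, locus, allele)")
        if (self.Q < -1e-12).any():
            raise ValueError("allele frequencies must be non-negative")
        sums = self.Q.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-10):
            raise ValueError("allele frequencies must sum to 1 per patch x locus")


@dataclass
class MigrantMatrix:
    """Expected migrants per generation, A[dest, source] = f N_source D[source, dest]."""

    A: np.ndarray
    N: np.ndarray
    f: float
    patch_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if (self.A < 0).any():
            raise ValueError("migrant matrix entries must be non-negative")
        if (self.N < 0).any():
            raise ValueError("abundances must be non-negative")


def build_migrant_matrix(grid, D, f: float) -> MigrantMatrix:
    """Migrant matrix from abundances and a dispersal matrix.

    ``A[dest, source] = f * N_source * D[source, dest]``: each source patch
    produces ``f N`` progeny, distributed over destinations by its dispersal
    row.  The matrix is treated as time-invariant by the projection.
    """
    if f <= 0:
        raise ValueError("fertility rate f must be positive")
    if list(grid.patches.index) != list(D.patch_ids):
        raise ValueError("patch grid and dispersal matrix ids do not match")
    N = grid.abundance
    if np.isnan(N).any():
        raise ValueError("grid abundances not set; run compute_abundance first")
    A = f * (D.D * N[:, None]).T  # transpose: rows = destination
    return MigrantMatrix(A=A, N=N, f=f, patch_ids=list(grid.patches.index))


def init_state(config: GeneFlowConfig, n_patches: int,
               seed=None, replicate_id: int = 0) -> AlleleFrequencyState:
    """Random initial frequencies: flat Dirichlet per patch x locus."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    g = rng.gamma(1.0, size=(n_patches, config.n_loci, config.alleles_per_locus))
    Q = g / g.sum(axis=2, keepdims=True)
    return AlleleFrequencyState(Q=Q, generation=0, replicate_id=replicate_id)


def transition_matrix(M: MigrantMatrix) -> np.ndarray:
    """Row-stochastic one-generation transition P = rownorm(A + diag(N)).

    Rows with zero total (empty patch, no inflow) become identity rows so
    such patches carry their frequencies forward.
    """
    full = M.A + np.diag(M.N)
    totals = full.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d patch(es) with no residents and no inflow carry "
                       "frequencies forward", int(zero.sum()))
    P = np.zeros_like(full)
    nz = ~zero
    P[nz] = full[nz] / totals[nz, None]
    P[zero, zero] = 1.0
    return P


def project_step(state: AlleleFrequencyState, M: MigrantMatrix) -> AlleleFrequencyState:
    """Advance the allele frequencies by one generation."""
    n, L, K = state.Q.shape
    if M.A.shape != (n, n):
        raise ValueError("migrant matrix does not match the state")
    flat = state.Q.reshape(n, L * K)
    raw = M.A @ flat + M.N[:, None] * flat
    raw = raw.reshape(n, L, K)
    totals = raw.sum(axis=2)
    Q = state.Q.copy()
    ok = totals > 0
    # patches with no inflow are exact fixed points; skip the division so
    # their frequencies are carried over bit-for-bit
    ok &= (M.A.sum(axis=1) > 0)[:, None]
    Q[ok] = raw[ok] / totals[ok][:, None]
    if (totals == 0).any():
        logger.warning("%d patch-locus rows had zero inflow and residents; "
                       "frequencies carried over", int((totals == 0).sum()))
    return AlleleFrequencyState(Q=Q, generation=state.generation + 1,
                                replicate_id=state.replicate_id)


@dataclass
class Ensemble:
    """Replicate terminal states of the projection."""

    Q: np.ndarray  # (replicate, patch, locus, allele)
    patch_ids: list
    config: GeneFlowConfig
    generation: int


def run_simulation(grid, D, config: GeneFlowConfig, typology=None,
                   snapshots=None) -> Ensemble:
    """Run replicate projections to the configured horizon.

    Each replicate draws a fresh random initial state and, when a typology
    is supplied, a fresh density realization (so abundance uncertainty
    propagates into the ensemble).  Uses the matrix-power fast path of the
    linear update; equivalent to iterating :func:`project_step`.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_replicates)
    n = grid.n_patches
    out = np.empty((config.n_replicates, n, config.n_loci,
                    config.alleles_per_locus))
    snaps = {} if snapshots else None
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        g = compute_abundance_like(grid, typology, rng)
        M = build_migrant_matrix(g, D, config.f)
        P = transition_matrix(M)
        state = init_state(config, n, seed=rng, replicate_id=rep)
        flat = state.Q.reshape(n, -1)
        if snapshots:
            acc = flat
            prev = 0
            for t in sorted(snapshots):
                acc = np.linalg.matrix_power(P, t - prev) @ acc
                prev = t
                snaps.setdefault(t, []).append(
                    _renorm(acc.reshape(state.Q.shape)))
            QT = np.linalg.matrix_power(P, config.generations - prev) @ acc
        else:
            QT = np.linalg.matrix_power(P, config.generations) @ flat
        out[rep] = _renorm(QT.reshape(state.Q.shape))
    ens = Ensemble(Q=out, patch_ids=list(grid.patches.index), config=config,
                   generation=config.generations)
    if snaps is not None:
        ens.snapshots = {t: np.array(v) for t, v in snaps.items()}
    return ens


def compute_abundance_like(grid, typology, rng):
    """Fresh density realization if a typology is given, else the grid as-is."""
    if typology is None:
        if np.isnan(grid.abundance).any():
            raise ValueError("grid abundances not set and no typology supplied")
        return grid
    from .habitat import compute_abundance

    return compute_abundance(grid, typology, rng)


def _renorm(Q: np.ndarray) -> np.ndarray:
    totals = Q.sum(axis=-1, keepdims=True)
    return np.divide(Q, totals, out=Q.copy(), where=totals > 0)


def replicate_distance_matrices(ensemble: Ensemble, sampled_patch_ids) -> np.ndarray:
    """Per-replicate chord-distance matrices over the sampled patches."""
    pos = {pid: i for i, pid in enumerate(ensemble.patch_ids)}
    idx = np.array([pos[p] for p in sampled_patch_ids])
    if len(idx) < 2:
        raise ValueError("need at least two sampled patches")
    return np.array([chord_matrix(ensemble.Q[r][idx])
                     for r in range(ensemble.Q.shape[0])])


def simulated_distance_matrix(ensemble: Ensemble, sampled_patch_ids) -> np.ndarray:
    """Replicate-averaged, standardized chord-distance matrix.

    Distances are averaged over replicates first, then scaled so the maximum
    off-diagonal entry is 1 (skipped with a warning for an all-zero matrix).
    """
    mats = replicate_distance_matrices(ensemble, sampled_patch_ids)
    return standardize(mats.mean(axis=0))
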