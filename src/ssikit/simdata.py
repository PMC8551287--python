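"""Simulation of multi-cycle doubled-haploid breeding populations.

Generates biparental DH families across breeding cycles with shared parents
between cycles, dominant 0/1 marker coding, per-cycle heterogeneous QTL
effects (controlled by a cross-cycle effect correlation), phenotypes at a
target within-cycle heritability, and plot-level alpha-lattice-style trial
records for the phenotype-adjustment module.

Recombination follows Haldane's mapping function (no interference): along a
chromosome the parental origin of a gamete is a two-state Markov chain whose
switch probability between adjacent markers at map distance d Morgans is
r = (1 - exp(-2 d)) / 2.  A DH line is a single F1 gamete doubled, so marker
values stay exactly 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

__all__ = [
    "GeneticMap",
    "CrossingPlan",
    "TraitArchitecture",
    "SimulatedPopulation",
    "default_map",
    "simulate_founders",
    "make_dh_family",
    "overlapping_plan",
    "sample_architecture",
    "simulate_population",
    "simulate_trial",
]


@dataclass
class GeneticMap:
    """Marker map: chromosome index and genetic position (Morgans) per marker."""

    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=int)
        self.position = np.asarray(self.position, dtype=float)
        if self.chromosome.shape != self.position.shape or self.chromosome.ndim != 1:
            raise ValueError("chromosome and position must be 1-D and equally long")
        if self.n_markers == 0:
            raise ValueError("map must contain at least one marker")
        for c in np.unique(self.chromosome):
            pos = self.position[self.chromosome == c]
            if pos.size < 1:
                raise ValueError(f"chromosome {c} has no markers")
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions on chromosome {c} must be non-decreasing")

    @property
    def n_markers(self) -> int:
        return self.chromosome.size


def default_map(n_markers: int, n_chromosomes: int = 10, length: float = 1.0) -> GeneticMap:
    """Equally spaced markers on ``n_chromosomes`` chromosomes of ``length`` Morgans."""
    if n_markers < n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    chrom, pos = [], []
    for c, m in enumerate(per):
        chrom.extend([c] * m)
        pos.extend(np.linspace(0.0, length, m).tolist())
    return GeneticMap(np.array(chrom), np.array(pos))


@dataclass
class CrossingPlan:
    """Which founders are crossed in each cycle and how many DH lines per family.

    ``founder_pools[c]`` lists the founder indices available in cycle ``c``;
    ``families[c]`` is a list of (parent_a, parent_b) founder-index pairs;
    ``n_dh[c]`` the DH count per family in that cycle.  Founder indices shared
    between cycles model the common parents connecting generations.
    """

    founder_pools: list[list[int]]
    families: list[list[tuple[int, int]]]
    n_dh: list[int]

    def __post_init__(self) -> None:
        if not self.families or all(len(f) == 0 for f in self.families):
            raise ValueError("crossing plan has no families")
        if not (len(self.founder_pools) == len(self.families) == len(self.n_dh)):
            raise ValueError("founder_pools, families and n_dh must align by cycle")
        for c, fams in enumerate(self.families):
            pool = set(self.founder_pools[c])
            for pa, pb in fams:
                if pa not in pool or pb not in pool:
                    raise ValueError(
                        f"cycle {c}: family parents ({pa},{pb}) not in the cycle's founder pool"
                    )
            if self.n_dh[c] < 1:
                raise ValueError("family sizes must be >= 1")

    @property
    def n_cycles(self) -> int:
        return len(self.families)

    @property
    def n_founders(self) -> int:
        return max(max(pool) for pool in self.founder_pools if pool) + 1


def overlapping_plan(
    n_cycles: int,
    founders_per_cycle: int,
    n_shared: int,
    families_per_cycle: int,
    dh_per_family: int,
    seed: int,
) -> CrossingPlan:
    """Build a plan where consecutive cycles share ``n_shared`` founders.

    Cycle 0 gets founders 0..F-1; each later cycle reuses ``n_shared`` random
    founders from the previous cycle's pool and adds fresh ones.  Families are
    random parent pairs (distinct parents) within the cycle's pool.
    """
    if n_shared > founders_per_cycle:
        raise ValueError("n_shared cannot exceed founders_per_cycle")
    rng = np.random.default_rng(seed)
    pools: list[list[int]] = []
    next_id = 0
    for c in range(n_cycles):
        if c == 0:
            pool = list(range(founders_per_cycle))
            next_id = founders_per_cycle
        elif n_shared == founders_per_cycle:
            pool = list(pools[-1])  # one homogeneous founder pool for all cycles
        else:
            carried = rng.choice(pools[-1], size=n_shared, replace=False).tolist()
            fresh = list(range(next_id, next_id + founders_per_cycle - n_shared))
            next_id += founders_per_cycle - n_shared
            pool = carried + fresh
        pools.append(pool)
    families = []
    for c in range(n_cycles):
        fams = []
        for _ in range(families_per_cycle):
            pa, pb = rng.choice(pools[c], size=2, replace=False)
            fams.append((int(pa), int(pb)))
        families.append(fams)
    return CrossingPlan(pools, families, [dh_per_family] * n_cycles)


@dataclass
class TraitArchitecture:
    """QTL positions, per-cycle effect vectors and the heritability target.

    ``effects`` has one row per cycle; rows are correlated draws so that
    ``rho_g`` controls how similar marker effects are between cycles
    (``rho_g = 1`` means a single homogeneous effect vector).
    """

    qtl_idx: np.ndarray
    effects: np.ndarray  # (n_cycles, n_qtl)
    rho_g: float
    h2_true: float
    intercepts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.qtl_idx = np.asarray(self.qtl_idx, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.ndim != 2 or self.effects.shape[1] != self.qtl_idx.size:
            raise ValueError("effects must be (n_cycles, n_qtl)")
        if not (0.0 <= self.rho_g <= 1.0):
            raise ValueError("rho_g must be in [0, 1]")
        if not (0.0 < self.h2_true <= 1.0):
            raise ValueError("h2_true must be in (0, 1]")
        if self.intercepts is None:
            self.intercepts = np.zeros(self.effects.shape[0])
        else:
            self.intercepts = np.asarray(self.intercepts, dtype=float)
            if self.intercepts.size != self.effects.shape[0]:
                raise ValueError("one intercept per cycle required")


def sample_architecture(
    n_markers: int,
    n_qtl: int,
    n_cycles: int,
    rho_g: float,
    h2_true: float,
    seed: int,
    effect_sd: float = 1.0,
) -> TraitArchitecture:
    """Draw QTL positions and equicorrelated per-cycle effect vectors.

    Effects at each QTL are a multivariate-normal draw across cycles with
    pairwise correlation ``rho_g``, generated through the shared+idiosyncratic
    decomposition ``e_c = sqrt(rho) * z + sqrt(1-rho) * z_c``.
    """
    if n_qtl > n_markers:
        raise ValueError("cannot place more QTL than markers")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(n_markers, size=n_qtl, replace=False))
    shared = rng.normal(0.0, effect_sd, size=n_qtl)
    own = rng.normal(0.0, effect_sd, size=(n_cycles, n_qtl))
    effects = np.sqrt(rho_g) * shared[None, :] + np.sqrt(1.0 - rho_g) * own
    return TraitArchitecture(qtl, effects, rho_g, h2_true)


@dataclass
class SimulatedPopulation:
    """Markers plus per-line truth: cycle, family, parents, breeding value, phenotype."""

    markers: MarkerMatrix
    true_bv: np.ndarray
    phenotype: np.ndarray
    pedigree: pd.DataFrame = field(repr=False)

    @property
    def ids(self) -> np.ndarray:
        return self.markers.ids

    @property
    def cycles(self) -> np.ndarray:
        return self.markers.cycles

    @property
    def n_lines(self) -> int:
        return self.markers.n_lines


def simulate_founders(
    n_founders: int,
    gmap: GeneticMap,
    allele_freq_spec: float | np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Independent founder haplotypes: Bernoulli presence calls per marker."""
    if n_founders < 2:
        raise ValueError("need at least two founders")
    freqs = np.broadcast_to(np.asarray(allele_freq_spec, dtype=float), (gmap.n_markers,))
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("allele presence frequencies must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return (rng.random((n_founders, gmap.n_markers)) < freqs).astype(np.int8)


def _gamete_origins(gmap: GeneticMap, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """0/1 parental-origin matrix for recombinant F1 gametes (Haldane Markov chain)."""
    p = gmap.n_markers
    origins = np.empty((n_gametes, p), dtype=np.int8)
    for c in np.unique(gmap.chromosome):
        idx = np.flatnonzero(gmap.chromosome == c)
        d = np.diff(gmap.position[idx])
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        start = rng.integers(0, 2, size=n_gametes)
        switches = rng.random((n_gametes, d.size)) < r
        # cumulative XOR of switch events along the chromosome
        state = (start[:, None] + np.concatenate(
            [np.zeros((n_gametes, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
        )) % 2
        origins[:, idx] = state.astype(np.int8)
    return origins


def make_dh_family(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    gmap: GeneticMap,
    n_dh: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """DH progeny of an A x B cross: one recombinant F1 gamete per line, doubled."""
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    if parent_a.size != gmap.n_markers or parent_b.size != gmap.n_markers:
        raise ValueError("parent haplotype length must match the map")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    origins = _gamete_origins(gmap, n_dh, rng)
    return np.where(origins == 0, parent_a[None, :], parent_b[None, :]).astype(np.int8)


def simulate_population(
    plan: CrossingPlan,
    gmap: GeneticMap,
    arch: TraitArchitecture,
    seed: int,
    founder_freq: float | np.ndarray = 0.5,
) -> SimulatedPopulation:
    """Simulate the full multi-cycle DH population with phenotypes.

    The true breeding value of line i in cycle c is
    ``intercept_c + sum_q effects[c, q] * x[i, qtl_q]``; phenotypes are the
    within-cycle-centred breeding values plus Gaussian noise whose variance is
    set from the empirical within-cycle BV variance so the realized
    within-cycle heritability matches ``arch.h2_true`` in expectation.
    """
    if arch.effects.shape[0] != plan.n_cycles:
        raise ValueError("architecture cycle count must match the crossing plan")
    if arch.qtl_idx.max(initial=-1) >= gmap.n_markers:
        raise ValueError("QTL indices exceed the marker map")
    rng = np.random.default_rng(seed)
    founders = simulate_founders(plan.n_founders, gmap, founder_freq, rng)

    rows, ids, cycles, fams, pa_ids, pb_ids = [], [], [], [], [], []
    for c in range(plan.n_cycles):
        for f, (pa, pb) in enumerate(plan.families[c]):
            X_fam = make_dh_family(founders[pa], founders[pb], gmap, plan.n_dh[c], rng)
            rows.append(X_fam)
            fam_label = f"C{c}F{f:02d}"
            for k in range(plan.n_dh[c]):
                ids.append(f"{fam_label}L{k:03d}")
                cycles.append(c)
                fams.append(fam_label)
                pa_ids.append(pa)
                pb_ids.append(pb)
    X = np.vstack(rows)
    cycles_arr = np.array(cycles)
    markers = MarkerMatrix(X, np.array(ids, dtype=object), cycles_arr, np.array(fams, dtype=object))

    bv = np.empty(X.shape[0])
    pheno = np.empty(X.shape[0])
    Xq = X[:, arch.qtl_idx].astype(float)
    for c in range(plan.n_cycles):
        mask = cycles_arr == c
        bv[mask] = arch.intercepts[c] + Xq[mask] @ arch.effects[c]
        centred = bv[mask] - bv[mask].mean()
        var_g = centred.var()
        if arch.h2_true >= 1.0 or var_g == 0.0:
            noise = np.zeros(mask.sum())
        else:
            sd_e = np.sqrt(var_g * (1.0 - arch.h2_true) / arch.h2_true)
            noise = rng.normal(0.0, sd_e, size=mask.sum())
            # calibrate the draw: centre, remove its in-sample projection on
            # the signal, and rescale to the exact target variance, so the
            # realized within-cycle heritability equals h2_true
            noise -= noise.mean()
            noise -= (noise @ centred) / (centred @ centred) * centred
            noise *= sd_e / noise.std()
        pheno[mask] = centred + noise

    pedigree = pd.DataFrame(
        {"line_id": ids, "cycle": cycles, "family": fams, "parent_a": pa_ids, "parent_b": pb_ids}
    )
    return SimulatedPopulation(markers, bv, pheno, pedigree)


def simulate_trial(
    population: SimulatedPopulation,
    n_locations: int,
    n_reps: int,
    blocks_per_rep: int,
    variance_spec: dict | None = None,
    seed: int = 0,
    mu: float = 0.0,
) -> pd.DataFrame:
    """Plot-level records: one row per line x location x replicate.

    ``variance_spec`` keys (all default 0 except error = 1): ``block``
    (random incomplete-block variance), ``error`` (residual variance),
    ``gxl`` (genotype-by-location variance), ``location`` and ``rep``
    (spread of the additive location and rep-within-location effects).
    Blocks are a fresh random partition of the lines within each replicate.
    """
    if min(n_locations, n_reps, blocks_per_rep) < 1:
        raise ValueError("location/rep/block counts must be >= 1")
    spec = {"block": 0.0, "error": 1.0, "gxl": 0.0, "location": 0.0, "rep": 0.0}
    if variance_spec:
        unknown = set(variance_spec) - set(spec)
        if unknown:
            raise ValueError(f"unknown variance keys: {sorted(unknown)}")
        spec.update(variance_spec)
    if any(v < 0 for v in spec.values()):
        raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    n = population.n_lines
    g_eff = population.true_bv - population.true_bv.mean()

    loc_eff = rng.normal(0.0, np.sqrt(spec["location"]), size=n_locations)
    rep_eff = rng.normal(0.0, np.sqrt(spec["rep"]), size=(n_locations, n_reps))
    gxl_eff = rng.normal(0.0, np.sqrt(spec["gxl"]), size=(n, n_locations))

    records = []
    for j in range(n_locations):
        for k in range(n_reps):
            order = rng.permutation(n)
            block_of = np.empty(n, dtype=int)
            block_of[order] = np.arange(n) * blocks_per_rep // n
            b_eff = rng.normal(0.0, np.sqrt(spec["block"]), size=blocks_per_rep)
            noise = rng.normal(0.0, np.sqrt(spec["error"]), size=n)
            value = (
                mu + g_eff + loc_eff[j] + rep_eff[j, k] + gxl_eff[:, j] + b_eff[block_of] + noise
            )
            records.append(
                pd.DataFrame(
                    {
                        "genotype": population.ids,
                        "location": f"loc{j}",
                        "rep": f"rep{k}",
                        "block": [f"loc{j}_rep{k}_b{b}" for b in block_of],
                        "value": value,
                        "_block_effect": b_eff[block_of],
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
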