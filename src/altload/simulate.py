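"""Genome-scale individual-based non-Wright-Fisher forward simulator.

Re-creates the stochastic experiment behind the deterministic theory: a
finite population in which early-acting recessive deleterious mutations
recur across a multi-chromosome genome, each generation N mothers are drawn
with replacement from the survivors, every mother produces two half-sib
embryos, embryos undergo early viability selection, and a dead embryo can be
replaced either by its surviving sibling (treatment: reproductive
compensation) or by a random non-sibling embryo (control), before seed-stage
selection on inbreeding status.

Internally the population is a dense 0/1 haplotype matrix over the currently
segregating mutation columns; recombination uses the exact two-state parity
process of crossovers along each chromosome (the probability of an odd
number of Poisson crossovers between adjacent sites at genetic distance d is
(1 - exp(-2d))/2), which reproduces Poisson crossover counts with uniform
breakpoints at the level of site inheritance while vectorizing across all
gametes of a generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ExtinctionError, GenomeMap, ReplacementMode, SimParams

__all__ = [
    "MutationRegistry",
    "Individual",
    "Population",
    "BalanceResult",
    "build_genome_map",
    "draw_gamete",
    "embryo_viability",
    "generation_step",
    "run_to_balance",
    "seed_single_variant",
]


def build_genome_map(config) -> GenomeMap:
    """Build the deterministic site grid from a SimParams-like config."""
    if isinstance(config, GenomeMap):
        return config
    if isinstance(config, SimParams):
        return config.genome_map()
    return GenomeMap(**dict(config))


@dataclass
class MutationRegistry:
    """Registry of live (segregating) mutations, column-aligned with the
    population haplotype matrix, plus a log of fixed mutations."""

    site: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    mid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    origin_generation: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    s: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    h: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    next_id: int = 0
    fixed: list = field(default_factory=list)

    @property
    def n_live(self) -> int:
        return self.site.size

    def add(self, sites, generation: int, s: float, h: float) -> np.ndarray:
        """Register new mutations at ``sites``; returns their ids."""
        k = len(sites)
        ids = np.arange(self.next_id, self.next_id + k, dtype=np.int64)
        self.next_id += k
        self.site = np.concatenate([self.site, np.asarray(sites, dtype=np.int64)])
        self.mid = np.concatenate([self.mid, ids])
        self.origin_generation = np.concatenate(
            [self.origin_generation, np.full(k, generation, dtype=np.int64)]
        )
        self.s = np.concatenate([self.s, np.full(k, s, dtype=float)])
        self.h = np.concatenate([self.h, np.full(k, h, dtype=float)])
        return ids

    def subset(self, keep: np.ndarray) -> "MutationRegistry":
        return MutationRegistry(
            site=self.site[keep],
            mid=self.mid[keep],
            origin_generation=self.origin_generation[keep],
            s=self.s[keep],
            h=self.h[keep],
            next_id=self.next_id,
            fixed=self.fixed,
        )

    def log_fixed(self, cols: np.ndarray, generation: int) -> None:
        for c in cols:
            self.fixed.append(
                {
                    "id": int(self.mid[c]),
                    "site": int(self.site[c]),
                    "origin_generation": int(self.origin_generation[c]),
                    "fixed_generation": int(generation),
                    "s": float(self.s[c]),
                    "h": float(self.h[c]),
                }
            )


@dataclass(frozen=True)
class Individual:
    """Read-only view of one diploid: two haplotypes as frozensets of live
    mutation ids, plus the inbred (product-of-selfing) flag."""

    haplotype_1: frozenset
    haplotype_2: frozenset
    inbred: bool


class Population:
    """Diploid population: haplotype matrix ``haps`` of shape
    (n, 2, n_live_mutations), inbred flags, mutation registry and genome
    map. Columns are kept sorted by (site, id)."""

    def __init__(
        self,
        haps: np.ndarray,
        inbred: np.ndarray,
        registry: MutationRegistry,
        genome_map: GenomeMap,
        generation: int = 0,
    ):
        self.haps = np.asarray(haps, dtype=np.uint8)
        self.inbred = np.asarray(inbred, dtype=bool)
        self.registry = registry
        self.genome_map = genome_map
        self.generation = generation

    @classmethod
    def founding(cls, params: SimParams) -> "Population":
        """Mutation-free all-outbred founding population of size N."""
        gmap = params.genome_map()
        return cls(
            haps=np.zeros((params.N, 2, 0), dtype=np.uint8),
            inbred=np.zeros(params.N, dtype=bool),
            registry=MutationRegistry(),
            genome_map=gmap,
        )

    @property
    def size(self) -> int:
        return self.haps.shape[0]

    def allele_counts(self) -> np.ndarray:
        return self.haps.sum(axis=(0, 1)).astype(np.int64)

    def allele_frequencies(self) -> np.ndarray:
        if self.size == 0:
            return np.empty(0)
        return self.allele_counts() / (2.0 * self.size)

    def individual(self, i: int) -> Individual:
        mid = self.registry.mid
        return Individual(
            haplotype_1=frozenset(mid[self.haps[i, 0] == 1].tolist()),
            haplotype_2=frozenset(mid[self.haps[i, 1] == 1].tolist()),
            inbred=bool(self.inbred[i]),
        )

    def _sort_columns(self) -> None:
        reg = self.registry
        if reg.n_live <= 1:
            return
        order = np.lexsort((reg.mid, reg.site))
        if np.array_equal(order, np.arange(order.size)):
            return
        self.haps = self.haps[:, :, order]
        self.registry = reg.subset(order)

    def purge(self) -> None:
        """Drop lost and fixed columns; fixed mutations are logged as
        substitutions and removed from all individuals."""
        counts = self.allele_counts()
        lost = counts == 0
        fixed = counts == 2 * self.size
        if fixed.any():
            self.registry.log_fixed(np.flatnonzero(fixed), self.generation)
        keep = ~(lost | fixed)
        if not keep.all():
            self.haps = self.haps[:, :, keep]
            self.registry = self.registry.subset(keep)


def _global_genetic_positions(gmap: GenomeMap, sites: np.ndarray) -> np.ndarray:
    """Genetic position of each site on the concatenated map, in Morgans."""
    return (
        gmap.chromosome_of(sites) * gmap.chrom_length_morgans
        + gmap.genetic_position(sites)
    )


def _strand_parity(
    pop: Population, G: int, rng: np.random.Generator
) -> np.ndarray:
    """(G, S) matrix of parental-strand choices for each gamete at each
    live column.

    Crossovers form a Poisson process of total rate ``n_chromosomes *
    chrom_length_morgans`` per gamete; each crossover at genetic position x
    toggles the strand of every column beyond x. Each chromosome
    additionally starts on a random strand, implemented as a fair toggle at
    its first column (chromosomes assort independently because every
    boundary re-randomizes the parity). Events are scattered as parity
    toggles and propagated with one cumulative-sum pass, which reproduces
    Poisson crossover counts with uniform breakpoints exactly at the level
    of site inheritance.
    """
    reg = pop.registry
    gmap = pop.genome_map
    S = reg.n_live
    colpos = _global_genetic_positions(gmap, reg.site)
    total_map = gmap.n_chromosomes * gmap.chrom_length_morgans
    toggles = np.zeros((G, S), dtype=np.uint8)

    n_xo = rng.poisson(total_map * G)
    if n_xo > 0:
        xo_gam = rng.integers(0, G, n_xo)
        xo_pos = rng.random(n_xo) * total_map
        col = np.searchsorted(colpos, xo_pos, side="left")
        inside = col < S
        # XOR semantics: a (gamete, column) cell hit an even number of
        # times is unchanged, so scatter only odd-multiplicity cells
        flat = xo_gam[inside] * np.int64(S) + col[inside]
        uniq, counts = np.unique(flat, return_counts=True)
        odd = uniq[(counts & 1) == 1]
        toggles.ravel()[odd] = 1

    # random starting strand per (gamete, chromosome)
    chrom_starts = np.arange(gmap.n_chromosomes) * gmap.chrom_length_morgans
    first_col = np.searchsorted(colpos, chrom_starts, side="left")
    first_col = np.unique(first_col[first_col < S])
    if first_col.size:
        start_flip = (rng.random((G, first_col.size)) < 0.5).astype(np.uint8)
        toggles[:, first_col] ^= start_flip
    return np.cumsum(toggles, axis=1, dtype=np.uint8) & 1


def _draw_gamete_matrix(
    pop: Population, parents: np.ndarray, mu: float, rng: np.random.Generator
):
    """Vectorized meiosis for every requested gamete.

    Returns ``(gametes, new_sites, new_gidx)``: inherited alleles over the
    live columns for each gamete, plus the genomic sites and gamete indices
    of de-novo mutations (left to the caller to register as columns).
    """
    G = parents.size
    S = pop.registry.n_live
    if S > 0:
        parity = _strand_parity(pop, G, rng)
        h0 = pop.haps[parents, 0, :]
        h1 = pop.haps[parents, 1, :]
        # parity 1 -> take strand 2; equal strands are unaffected
        h1 ^= h0
        h1 &= parity
        h0 ^= h1
        gam = h0
    else:
        gam = np.zeros((G, 0), dtype=np.uint8)
    gmap = pop.genome_map
    n_new = rng.poisson(mu * gmap.n_sites * G)
    if n_new > 0:
        new_gidx = rng.integers(0, G, n_new)
        new_sites = rng.integers(0, gmap.n_sites, n_new)
    else:
        new_gidx = np.empty(0, dtype=np.int64)
        new_sites = np.empty(0, dtype=np.int64)
    return gam, new_sites, new_gidx


def draw_gamete(
    pop: Population, parent: int, mu: float, rng: np.random.Generator
):
    """Draw one gamete from individual ``parent``.

    Returns ``(inherited_ids, new_sites)``: the frozenset of live mutation
    ids transmitted, and the genomic sites of de-novo mutations on this
    gamete (not yet registered; :func:`generation_step` registers new
    mutations for the whole generation at once).
    """
    gam, new_sites, _ = _draw_gamete_matrix(
        pop, np.array([parent]), mu, rng
    )
    ids = frozenset(pop.registry.mid[gam[0] == 1].tolist())
    return ids, new_sites.tolist()


def embryo_viability(
    hap_a: np.ndarray, hap_b: np.ndarray, s: np.ndarray, h: np.ndarray
) -> np.ndarray:
    """Early survival probability of each embryo, multiplicative across
    loci: prod(1 - s_i) over homozygous mutations times prod(1 - h_i s_i)
    over heterozygous ones, floored at 0."""
    if hap_a.ndim == 1:
        hap_a = hap_a[None, :]
        hap_b = hap_b[None, :]
    if hap_a.shape[1] == 0:
        return np.ones(hap_a.shape[0])
    s = np.asarray(s, dtype=float)
    h = np.asarray(h, dtype=float)
    hom = hap_a & hap_b
    het = hap_a ^ hap_b
    if s.size and np.ptp(s) == 0.0 and np.ptp(h) == 0.0:
        # uniform coefficients: only the per-embryo counts matter
        n_hom = hom.sum(axis=1, dtype=np.int64)
        n_het = het.sum(axis=1, dtype=np.int64)
        v_hom = max(1.0 - s.flat[0], 0.0)
        v_het = max(1.0 - h.flat[0] * s.flat[0], 0.0)
        return np.power(v_hom, n_hom) * np.power(v_het, n_het)
    # log-domain products; lethal terms floored so 0 * (-inf) never appears
    log_hom = np.log(np.maximum(1.0 - s, 1e-300))
    log_het = np.log(np.maximum(1.0 - h * s, 1e-300))
    return np.exp(
        hom.astype(np.float64) @ log_hom + het.astype(np.float64) @ log_het
    )


@dataclass
class GenerationStats:
    n_survivors: int
    n_seeds: int
    n_new_mutations: int


def generation_step(
    pop: Population, params: SimParams, rng: np.random.Generator
) -> tuple[Population, GenerationStats]:
    """Advance the population by one generation (see module docstring for
    the life cycle). Raises :class:`ExtinctionError` if no seed survives."""
    n = pop.size
    N = params.N
    if n == 0:
        raise ExtinctionError("no parents available")
    if n == 1 and params.sigma < 1.0:
        raise ExtinctionError("single survivor cannot outcross")
    gen = pop.generation + 1

    mothers = rng.integers(0, n, N)
    selfed = rng.random((N, 2)) < params.sigma  # per-embryo, i.i.d.
    # outcross fathers: uniform over survivors, excluding the mother;
    # the two embryos of a family have independent fathers (half-sibs)
    fathers = rng.integers(0, n, (N, 2))
    while True:
        clash = (fathers == mothers[:, None]) & ~selfed
        if not clash.any():
            break
        fathers[clash] = rng.integers(0, n, int(clash.sum()))

    E = 2 * N  # embryos, family-major order: embryo j of family i at 2i+j
    mother_of = np.repeat(mothers, 2)
    other_parent = np.where(selfed, mothers[:, None], fathers).reshape(E)
    parents_all = np.concatenate([mother_of, other_parent])
    gam, new_sites, new_gidx = _draw_gamete_matrix(
        pop, parents_all, params.mu, rng
    )

    # register de-novo mutations as new columns on the gamete matrix
    registry = pop.registry
    k = new_sites.size
    if k > 0:
        registry.add(new_sites, gen, params.s, params.h)
        new_cols = np.zeros((parents_all.size, k), dtype=np.uint8)
        new_cols[new_gidx, np.arange(k)] = 1
        gam = np.concatenate([gam, new_cols], axis=1)

    hap_a = gam[:E]
    hap_b = gam[E:]
    v = embryo_viability(hap_a, hap_b, registry.s, registry.h)
    alive = rng.random(E) < v
    embryo_selfed = selfed.reshape(E)

    mode = ReplacementMode(params.replacement_mode)
    if mode is ReplacementMode.SIBLING:
        pair_first = np.arange(0, E, 2)
    else:
        # control: replacement between random embryo pairs across families
        perm = rng.permutation(E)
        pair_first = np.arange(0, E, 2)
        alive = alive[perm]
        hap_a = hap_a[perm]
        hap_b = hap_b[perm]
        embryo_selfed = embryo_selfed[perm]
    a1 = alive[pair_first]
    a2 = alive[pair_first + 1]
    # of two viable embryos one is randomly the primary and becomes the
    # seed; with one viable embryo it is the seed; with none, no seed
    pick_second = np.where(a1 & a2, rng.random(N) < 0.5, ~a1)
    seed_idx = pair_first + pick_second.astype(np.int64)
    has_seed = a1 | a2

    seed_selfed = embryo_selfed[seed_idx]
    inbreeding_ok = ~seed_selfed | (rng.random(N) < params.w_inbred)
    keep = has_seed & inbreeding_ok
    if not keep.any():
        raise ExtinctionError(f"no surviving seeds in generation {gen}")
    chosen = seed_idx[keep]
    haps_next = np.stack([hap_a[chosen], hap_b[chosen]], axis=1)

    new_pop = Population(
        haps=haps_next,
        inbred=seed_selfed[keep],
        registry=registry,
        genome_map=pop.genome_map,
        generation=gen,
    )
    new_pop.purge()
    new_pop._sort_columns()
    stats = GenerationStats(
        n_survivors=new_pop.size, n_seeds=int(keep.sum()), n_new_mutations=k
    )
    return new_pop, stats


def seed_single_variant(
    pop: Population,
    site: int,
    freq: float,
    rng: np.random.Generator,
    s: float | None = None,
    h: float | None = None,
) -> Population:
    """Place a single mutation at ``site`` into the population at target
    frequency ``freq`` (each haplotype carries it independently, so the
    realized count is Binomial(2n, freq)). ``freq`` = 0 returns the
    population unchanged; ``freq`` >= 1 is an error."""
    if freq == 0:
        return pop
    if not 0.0 < freq < 1.0:
        raise ValueError(f"freq must lie in (0, 1), got {freq!r}")
    if s is None or h is None:
        raise ValueError("selection and dominance coefficients are required")
    registry = pop.registry
    registry.add([site], pop.generation, s, h)
    col = (rng.random((pop.size, 2)) < freq).astype(np.uint8)
    haps = np.concatenate([pop.haps, col[:, :, None]], axis=2)
    out = Population(
        haps=haps,
        inbred=pop.inbred.copy(),
        registry=registry,
        genome_map=pop.genome_map,
        generation=pop.generation,
    )
    out._sort_columns()
    return out


@dataclass
class BalanceResult:
    """Outcome of :func:`run_to_balance`: per-generation trajectory, final
    population, and a termination status ('stationary', 'generation_cap' or
    'extinct')."""

    trajectory: pd.DataFrame
    population: Population | None
    status: str
    params: SimParams

    def final_window(self, window: int | None = None) -> pd.DataFrame:
        w = window or self.params.balance_window
        return self.trajectory.iloc[-w:]


def _snapshot(pop: Population) -> dict:
    freqs = pop.allele_frequencies()
    n_seg = freqs.size
    mean_count = float(pop.haps.sum() / pop.size) if pop.size else 0.0
    return {
        "generation": pop.generation,
        "pop_size": pop.size,
        "mean_mutations_per_individual": mean_count,
        "mean_segregating_frequency": float(freqs.mean()) if n_seg else 0.0,
        "n_segregating": n_seg,
        "n_fixed": len(pop.registry.fixed),
    }


def run_to_balance(
    params: SimParams, rng: np.random.Generator | None = None
) -> BalanceResult:
    """Run the simulation until mutation-selection(-compensation) balance.

    Stationarity is declared when the mean mutation count per individual,
    averaged over two consecutive non-overlapping windows of
    ``balance_window`` generations, changes by less than 1% relative — but
    not before ``min_generations``. The run otherwise stops at the
    generation cap (default 20 N), or on extinction.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pop = Population.founding(params)
    rows = [_snapshot(pop)]
    status = "generation_cap"
    w = params.balance_window
    cap = params.generation_cap
    counts = []
    for _ in range(cap):
        try:
            pop, _stats = generation_step(pop, params, rng)
        except ExtinctionError:
            status = "extinct"
            pop = None
            break
        rows.append(_snapshot(pop))
        counts.append(rows[-1]["mean_mutations_per_individual"])
        g = pop.generation
        if g >= max(params.min_generations, 2 * w) and g % w == 0:
            recent = np.mean(counts[-w:])
            previous = np.mean(counts[-2 * w : -w])
            denom = max(abs(previous), 1e-12)
            if abs(recent - previous) / denom < 1e-2:
                status = "stationary"
                break
    trajectory = pd.DataFrame(rows)
    return BalanceResult(
        trajectory=trajectory, population=pop, status=status, params=params
    )
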