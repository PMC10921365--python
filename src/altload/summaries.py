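"""Load summaries, frequency spectra, allele ages, and the experiment-grid
driver that turns raw simulator output into comparative quantities
(treatment versus control load, its dependence on selfing and mutation
rates, and the age signature of balancing selection)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ReplacementMode, SimParams
from .simulate import BalanceResult, Population, run_to_balance

__all__ = [
    "SimSummary",
    "summarize_load",
    "summarize_from_table",
    "mutation_table",
    "site_frequency_spectrum",
    "allele_age_summary",
    "AgeSummary",
    "GridConfig",
    "run_grid",
]


@dataclass(frozen=True)
class SimSummary:
    """Point-in-time load summary of a population.

    ``mean_mutations_per_individual`` counts mutated alleles per diploid
    (homozygotes count twice); ``mean_segregating_frequency`` is the
    unweighted mean population frequency over segregating mutations, and
    ``freq_weighted_mean_frequency`` the frequency-weighted alternative
    (both are reported because genome-wide load figures can be aggregated
    either way); ``sfs`` is the histogram of derived-allele counts
    1..2n-1.
    """

    pop_size: int
    generation: int
    n_segregating: int
    mean_mutations_per_individual: float
    mean_segregating_frequency: float
    freq_weighted_mean_frequency: float
    sfs: np.ndarray
    mean_allele_age: float
    median_allele_age: float

    def as_dict(self) -> dict:
        d = {
            "pop_size": self.pop_size,
            "generation": self.generation,
            "n_segregating": self.n_segregating,
            "mean_mutations_per_individual": self.mean_mutations_per_individual,
            "mean_segregating_frequency": self.mean_segregating_frequency,
            "freq_weighted_mean_frequency": self.freq_weighted_mean_frequency,
            "mean_allele_age": self.mean_allele_age,
            "median_allele_age": self.median_allele_age,
        }
        return d


def _summary_from_counts(
    counts: np.ndarray,
    ages: np.ndarray,
    pop_size: int,
    generation: int,
) -> SimSummary:
    if pop_size <= 0:
        raise ValueError("population is empty")
    two_n = 2 * pop_size
    seg = (counts > 0) & (counts < two_n)
    counts = counts[seg]
    ages = ages[seg]
    n_seg = counts.size
    freqs = counts / two_n
    mean_count = float(counts.sum() / pop_size)
    sfs = np.bincount(counts, minlength=two_n)[1:two_n] if n_seg else np.zeros(
        max(two_n - 1, 0), dtype=np.int64
    )
    return SimSummary(
        pop_size=pop_size,
        generation=generation,
        n_segregating=int(n_seg),
        mean_mutations_per_individual=mean_count,
        mean_segregating_frequency=float(freqs.mean()) if n_seg else 0.0,
        freq_weighted_mean_frequency=(
            float((freqs * freqs).sum() / freqs.sum()) if n_seg else 0.0
        ),
        sfs=sfs,
        mean_allele_age=float(ages.mean()) if n_seg else 0.0,
        median_allele_age=float(np.median(ages)) if n_seg else 0.0,
    )


def summarize_load(pop: Population) -> SimSummary:
    """Compute the full load summary from genotypes and the mutation
    registry. Fixed mutations are excluded by construction (the population
    purges them), and the identity

        mean_mutations_per_individual = sum over segregating records of
        2 * frequency

    holds exactly because both sides count the same allele copies.
    """
    counts = pop.allele_counts()
    ages = pop.generation - pop.registry.origin_generation
    return _summary_from_counts(counts, ages, pop.size, pop.generation)


def mutation_table(pop: Population) -> pd.DataFrame:
    """Per-mutation table (site, chromosome, frequency, count,
    origin_generation, s, h) for the currently segregating records."""
    reg = pop.registry
    counts = pop.allele_counts()
    return pd.DataFrame(
        {
            "id": reg.mid,
            "site": reg.site,
            "chromosome": pop.genome_map.chromosome_of(reg.site),
            "count": counts,
            "frequency": counts / (2.0 * pop.size),
            "origin_generation": reg.origin_generation,
            "s": reg.s,
            "h": reg.h,
        }
    )


def summarize_from_table(
    table: pd.DataFrame, pop_size: int, generation: int
) -> SimSummary:
    """Recompute the load summary from an emitted mutation table alone
    (round-trip identity with :func:`summarize_load`)."""
    counts = table["count"].to_numpy(dtype=np.int64)
    ages = generation - table["origin_generation"].to_numpy(dtype=np.int64)
    return _summary_from_counts(counts, ages, pop_size, generation)


def site_frequency_spectrum(pop: Population) -> np.ndarray:
    """Histogram of derived-allele counts over segregating records; entry
    k-1 holds the number of mutations carried by exactly k allele copies
    (k = 1 .. 2n-1). The histogram total equals the number of segregating
    records."""
    return summarize_load(pop).sfs


@dataclass(frozen=True)
class AgeSummary:
    mean: float
    median: float
    ages: np.ndarray


def allele_age_summary(pop: Population) -> AgeSummary:
    """Ages (generations since origin) of segregating mutations.

    Under plain mutation-selection balance recessive deleterious alleles
    are young; under the self-sacrificial balanced polymorphism they are
    kept segregating and should be old — the age contrast between sibling
    replacement and the non-sibling control is the testable signature.
    """
    counts = pop.allele_counts()
    seg = (counts > 0) & (counts < 2 * pop.size)
    ages = (pop.generation - pop.registry.origin_generation)[seg]
    if ages.size == 0:
        return AgeSummary(mean=0.0, median=0.0, ages=ages.astype(float))
    return AgeSummary(
        mean=float(ages.mean()), median=float(np.median(ages)), ages=ages
    )


GRID_COLUMNS = [
    "sigma", "mu", "s", "h", "w_inbred", "N", "mode", "replicate", "seed",
    "generations_run", "status", "n_segregating",
    "mean_mutations_per_individual", "mean_segregating_frequency",
    "freq_weighted_mean_frequency", "mean_allele_age",
]


@dataclass(frozen=True)
class GridConfig:
    """Factorial experiment grid: every combination of the listed selfing
    rates, mutation rates, selection coefficients and inbred-seed fitness
    values is run ``replicates`` times under both replacement modes, with
    per-run seeds derived deterministically from (base_seed, cell,
    replicate, mode)."""

    sigmas: tuple = (0.1, 0.2, 0.3)
    mus: tuple = (5e-8, 5e-6)
    ss: tuple = (0.2, 0.6, 1.0)
    w_inbreds: tuple = (0.0, 0.25)
    h: float = 0.0
    N: int = 10_000
    n_sites: int = 100_000
    n_chromosomes: int = 10
    replicates: int = 1
    base_seed: int = 0
    modes: tuple = (ReplacementMode.SIBLING, ReplacementMode.RANDOM_PAIR)
    generations: int | None = None
    balance_window: int = 500
    min_generations: int = 2000

    def cells(self):
        idx = 0
        for sigma in self.sigmas:
            for mu in self.mus:
                for s in self.ss:
                    for w in self.w_inbreds:
                        yield idx, dict(sigma=sigma, mu=mu, s=s, w_inbred=w)
                        idx += 1


def _cell_seed(base_seed: int, cell: int, replicate: int, mode_idx: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), cell, replicate, mode_idx])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_grid(grid: GridConfig, averaging_window: int | None = None) -> pd.DataFrame:
    """Execute the grid and return one long-format row per run.

    Final-run summaries average the trajectory over the last
    ``averaging_window`` generations (default: the balance window) to damp
    Monte-Carlo noise; allele ages come from the final population.
    Individual-cell failures (e.g. extinction) are recorded as rows with
    their status rather than aborting the grid.
    """
    rows = []
    for cell_idx, cell in grid.cells():
        for rep in range(grid.replicates):
            for mode_idx, mode in enumerate(grid.modes):
                mode = ReplacementMode(mode)
                seed = _cell_seed(grid.base_seed, cell_idx, rep, mode_idx)
                params = SimParams(
                    s=cell["s"], h=grid.h, sigma=cell["sigma"],
                    w_inbred=cell["w_inbred"], mu=cell["mu"], N=grid.N,
                    n_sites=grid.n_sites, n_chromosomes=grid.n_chromosomes,
                    replacement_mode=mode, generations=grid.generations,
                    balance_window=grid.balance_window,
                    min_generations=grid.min_generations, seed=seed,
                )
                row = {
                    "sigma": cell["sigma"], "mu": cell["mu"], "s": cell["s"],
                    "h": grid.h, "w_inbred": cell["w_inbred"], "N": grid.N,
                    "mode": mode.value, "replicate": rep, "seed": seed,
                }
                try:
                    res = run_to_balance(params)
                    w = averaging_window or grid.balance_window
                    win = res.trajectory.iloc[-w:]
                    row["generations_run"] = int(
                        res.trajectory["generation"].iloc[-1]
                    )
                    row["status"] = res.status
                    row["n_segregating"] = float(win["n_segregating"].mean())
                    row["mean_mutations_per_individual"] = float(
                        win["mean_mutations_per_individual"].mean()
                    )
                    row["mean_segregating_frequency"] = float(
                        win["mean_segregating_frequency"].mean()
                    )
                    if res.population is not None:
                        summ = summarize_load(res.population)
                        row["freq_weighted_mean_frequency"] = (
                            summ.freq_weighted_mean_frequency
                        )
                        row["mean_allele_age"] = summ.mean_allele_age
                    else:
                        row["freq_weighted_mean_frequency"] = np.nan
                        row["mean_allele_age"] = np.nan
                except Exception as exc:  # cell failures never abort the grid
                    row.setdefault("generations_run", 0)
                    row["status"] = f"error: {exc}"
                    for c in GRID_COLUMNS:
                        row.setdefault(c, np.nan)
                rows.append(row)
    return pd.DataFrame(rows, columns=GRID_COLUMNS)
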