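"""Parameter containers shared by the analytic, recursion and simulation layers.

All rates and probabilities are validated eagerly: values outside their domain
raise :class:`ValueError` rather than being clamped, so that mistakes in
parameter sweeps surface at construction time instead of silently distorting
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from enum import Enum


class CompensationModel(str, Enum):
    """How a mother recovers fitness lost to early embryo death.

    ``BACKUP_EMBRYO``: each seed holds a primary and a backup embryo; the
    backup matures only if the primary dies early. ``CHARLESWORTH``: maternal
    fitness equals (1 - p_m)^(1 - C), where p_m is the per-embryo early death
    probability and C the extent of compensation.
    """

    BACKUP_EMBRYO = "backup_embryo"
    CHARLESWORTH = "charlesworth"


class ReplacementMode(str, Enum):
    """Who replaces a dead embryo in the forward simulator.

    ``SIBLING`` is the treatment (replacement within a maternal family, i.e.
    reproductive compensation); ``RANDOM_PAIR`` is the matched control in
    which embryos are paired at random across the population, removing the
    kin-selected benefit of self-sacrifice.
    """

    SIBLING = "sibling"
    RANDOM_PAIR = "random_pair"


def _require_unit(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the single-locus model of a self-sacrificial allele A.

    Parameters
    ----------
    s : float
        Selection coefficient against AA homozygous embryos (early survival
        1 - s).
    h : float
        Dominance coefficient; heterozygous embryo survival is 1 - h*s.
    sigma : float
        Primary selfing rate: the probability an ovule is self-fertilized
        before any embryo selection.
    w_inbred : float
        Relative fitness of a viable selfed seed after development; 0 means
        lethal inbreeding depression.
    comp_model : CompensationModel
        Reproductive-compensation model. ``C`` is used only under the
        Charlesworth parameterization and ignored otherwise.
    C : float
        Extent of reproductive compensation in the Charlesworth model.
    p_A : float
        Current frequency of the focal allele A (used by the invasion-limit
        expressions).
    """

    s: float
    h: float = 0.0
    sigma: float = 0.0
    w_inbred: float = 0.0
    comp_model: CompensationModel = CompensationModel.BACKUP_EMBRYO
    C: float = 0.9
    p_A: float = 0.0

    def __post_init__(self) -> None:
        for name in ("s", "h", "sigma", "w_inbred", "C", "p_A"):
            object.__setattr__(self, name, _require_unit(name, getattr(self, name)))
        object.__setattr__(self, "comp_model", CompensationModel(self.comp_model))

    def with_(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class GenomeMap:
    """Discrete site grid split into equal chromosome blocks.

    Sites are 0-based and partition exactly into ``n_chromosomes`` contiguous
    half-open blocks; each chromosome has genetic length
    ``chrom_length_morgans`` with a uniform recombination map.
    """

    n_sites: int = 100_000
    n_chromosomes: int = 10
    chrom_length_morgans: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.n_chromosomes <= 0:
            raise ValueError("n_sites and n_chromosomes must be positive")
        if self.n_sites % self.n_chromosomes != 0:
            raise ValueError(
                f"n_sites ({self.n_sites}) must divide evenly into "
                f"n_chromosomes ({self.n_chromosomes}) blocks"
            )
        if self.chrom_length_morgans < 0:
            raise ValueError("chrom_length_morgans must be >= 0")

    @property
    def sites_per_chromosome(self) -> int:
        return self.n_sites // self.n_chromosomes

    def chromosome_of(self, sites):
        import numpy as np

        return np.asarray(sites) // self.sites_per_chromosome

    def block_bounds(self):
        """Half-open [start, end) site bounds per chromosome."""
        b = self.sites_per_chromosome
        return [(c * b, (c + 1) * b) for c in range(self.n_chromosomes)]

    def genetic_position(self, sites):
        """Within-chromosome genetic position in Morgans (site midpoints)."""
        import numpy as np

        sites = np.asarray(sites)
        b = self.sites_per_chromosome
        within = sites % b
        return (within + 0.5) / b * self.chrom_length_morgans


@dataclass(frozen=True)
class SimParams:
    """Parameters of the genome-scale individual-based forward simulation.

    In addition to the single-locus fields, ``mu`` is the per-site per-gamete
    mutation rate, ``N`` the number of mother draws per generation, and
    ``replacement_mode`` selects treatment (sibling replacement) versus the
    non-sibling control. ``generations`` caps the run; ``balance_window`` is
    the window length (generations) for the stationarity check and
    ``min_generations`` the earliest generation at which stationarity may be
    declared.
    """

    s: float = 1.0
    h: float = 0.0
    sigma: float = 0.1
    w_inbred: float = 0.0
    mu: float = 5e-8
    N: int = 10_000
    n_sites: int = 100_000
    n_chromosomes: int = 10
    chrom_length_morgans: float = 1.0
    replacement_mode: ReplacementMode = ReplacementMode.SIBLING
    generations: int | None = None
    balance_window: int = 500
    min_generations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("s", "h", "sigma", "w_inbred"):
            object.__setattr__(self, name, _require_unit(name, getattr(self, name)))
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu!r}")
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N!r}")
        object.__setattr__(
            self, "replacement_mode", ReplacementMode(self.replacement_mode)
        )
        # construct to validate divisibility
        self.genome_map()

    def genome_map(self) -> GenomeMap:
        return GenomeMap(self.n_sites, self.n_chromosomes, self.chrom_length_morgans)

    @property
    def generation_cap(self) -> int:
        return self.generations if self.generations is not None else 20 * self.N

    def model_params(self) -> ModelParams:
        return ModelParams(
            s=self.s, h=self.h, sigma=self.sigma, w_inbred=self.w_inbred
        )

    def with_(self, **changes) -> "SimParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.value if isinstance(v, Enum) else v
        return out


class ExtinctionError(RuntimeError):
    """Raised when a population (deterministic seed mass or simulated
    survivor pool) has no survivors under the supplied parameters."""
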