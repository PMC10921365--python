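"""Exact deterministic genotype-frequency recursions at a single locus.

The state is the joint distribution of (genotype in {aa, Aa, AA}) x
(inbred status in {outbred, inbred}) among reproducing adults in an infinite
population. One generation comprises:

1. mothers drawn in proportion to the adult state; each embryo is
   independently selfed with probability sigma, otherwise outcrossed with the
   paternal allele drawn from the adult pollen pool;
2. early viability selection on embryos (survival 1, 1-h*s, 1-s for aa, Aa,
   AA) combined with reproductive compensation — either the backup-embryo
   rule (two i.i.d. embryos per seed; the backup matures only if the primary
   dies) or the Charlesworth maternal-fitness rule (1 - p_m)^(1 - C);
3. seed-stage selection on inbreeding status: outbred seeds survive with
   probability 1, selfed seeds with probability w_inbred.

The recursion is validated against a direct Monte-Carlo event oracle
(:func:`oracle_step_montecarlo`) and, in the rare-allele limit, against the
closed forms in :mod:`altload.analytic`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import CompensationModel, ExtinctionError, ModelParams

GENOTYPES = ("aa", "Aa", "AA")
STATUSES = ("outbred", "inbred")

# Mendelian selfing tables: offspring genotype distribution of a selfed ovule.
_SELF_TABLE = ((1.0, 0.0, 0.0), (0.25, 0.5, 0.25), (0.0, 0.0, 1.0))
# probability a maternal gamete carries A, per maternal genotype
_MATERNAL_A = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class LocusState:
    """Joint (genotype x inbred-status) frequency vector among adults.

    ``freq`` has shape (3, 2): rows aa, Aa, AA; columns outbred, inbred.
    Components are nonnegative and sum to one (tolerance 1e-12).
    """

    freq: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.shape != (3, 2):
            raise ValueError(f"freq must have shape (3, 2), got {f.shape}")
        if np.any(f < -1e-12):
            raise ValueError("state components must be nonnegative")
        total = f.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state must sum to 1, got {total}")
        f = np.clip(f, 0.0, None)
        f = f / f.sum()
        object.__setattr__(self, "freq", f)
        self.freq.setflags(write=False)

    @property
    def p_A(self) -> float:
        """Derived allele frequency: half the Aa mass plus the AA mass."""
        f = self.freq
        return float(f[1].sum() / 2.0 + f[2].sum())

    @property
    def genotype_freq(self) -> np.ndarray:
        return self.freq.sum(axis=1)

    @classmethod
    def from_allele_frequency(
        cls, p: float, sigma: float = 0.0, inbred_fraction: float = 0.0
    ) -> "LocusState":
        """Genotype proportions at inbreeding equilibrium F = sigma/(2-sigma)
        for allele frequency ``p``; inbred status defaults to all-outbred
        (adult inbred status has no effect on the dynamics)."""
        F = sigma / (2.0 - sigma) if sigma > 0 else 0.0
        q = 1.0 - p
        g = np.array(
            [q * q + F * p * q, 2.0 * p * q * (1.0 - F), p * p + F * p * q]
        )
        f = np.zeros((3, 2))
        f[:, 0] = g * (1.0 - inbred_fraction)
        f[:, 1] = g * inbred_fraction
        return cls(f)


def offspring_distribution(
    mother_genotype: str | int, pollen_freq: float, sigma: float
) -> np.ndarray:
    """Per-embryo distribution over (offspring genotype, origin) for one
    mother.

    Returns a (3, 2) array (rows aa/Aa/AA, columns outcrossed/selfed) summing
    to 1. Selfed embryos (probability sigma) follow Mendelian selfing ratios;
    outcrossed embryos combine a maternal gamete with a pollen allele carrying
    A at frequency ``pollen_freq``.
    """
    if isinstance(mother_genotype, str):
        mother_genotype = GENOTYPES.index(mother_genotype)
    if not 0.0 <= pollen_freq <= 1.0 or not 0.0 <= sigma <= 1.0:
        raise ValueError("pollen_freq and sigma must lie in [0, 1]")
    d6 = _offspring6(mother_genotype, pollen_freq, sigma)
    return np.array(d6).reshape(3, 2)


def _offspring6(g: int, p: float, sigma: float):
    """Flat per-embryo distribution d[g2*2 + origin], origin 1 = selfed."""
    st = _SELF_TABLE[g]
    m = _MATERNAL_A[g]
    out = 1.0 - sigma
    return [
        out * (1.0 - m) * (1.0 - p),  # aa, outcrossed
        sigma * st[0],                # aa, selfed
        out * (m * (1.0 - p) + (1.0 - m) * p),  # Aa, outcrossed
        sigma * st[1],                # Aa, selfed
        out * m * p,                  # AA, outcrossed
        sigma * st[2],                # AA, selfed
    ]


def _step6(f6, s, h, sigma, w_inbred, charlesworth, C):
    """One-generation kernel on the flat 6-vector f[g*2 + status].

    Kept in plain floats: equilibrium solving iterates this up to millions of
    times and numpy overhead would dominate.
    """
    # adult genotype marginals and pollen-pool allele frequency
    g_aa = f6[0] + f6[1]
    g_Aa = f6[2] + f6[3]
    g_AA = f6[4] + f6[5]
    p = g_Aa / 2.0 + g_AA
    v = (1.0, 1.0 - h * s, 1.0 - s)
    out = [0.0] * 6
    for g, fg in enumerate((g_aa, g_Aa, g_AA)):
        if fg == 0.0:
            continue
        d = _offspring6(g, p, sigma)
        V = (
            d[0] * v[0] + d[1] * v[0]
            + d[2] * v[1] + d[3] * v[1]
            + d[4] * v[2] + d[5] * v[2]
        )
        if charlesworth:
            if V <= 0.0:
                continue  # all embryos die; mother weight (1-p_m)^(1-C) = 0
            fac = fg * V ** (-C)
        else:
            fac = fg * (2.0 - V)  # seed = primary if viable, else backup
        for i in range(6):
            w = w_inbred if (i & 1) else 1.0
            out[i] += fac * d[i] * v[i >> 1] * w
    W = sum(out)
    if W <= 0.0:
        raise ExtinctionError(
            "zero seed mass: no surviving seeds under these parameters"
        )
    inv = 1.0 / W
    return [x * inv for x in out], W


def _flat(state: LocusState):
    f = state.freq
    return [f[0, 0], f[0, 1], f[1, 0], f[1, 1], f[2, 0], f[2, 1]]


def _unflat(f6) -> LocusState:
    return LocusState(np.array(f6).reshape(3, 2))


def step_backup(state: LocusState, params: ModelParams) -> LocusState:
    """One generation of the backup-embryo model.

    Each mother forms two i.i.d. embryos; the primary becomes the seed if it
    survives early selection, otherwise the backup does (if it survives);
    the per-class seed probability is d * v * (2 - V), where V is the
    mother's per-embryo viability. Selfed seeds then survive with probability
    w_inbred. Raises :class:`ExtinctionError` if total seed mass is zero.
    """
    f6, _ = _step6(
        _flat(state), params.s, params.h, params.sigma, params.w_inbred,
        charlesworth=False, C=0.0,
    )
    return _unflat(f6)


def step_charlesworth(state: LocusState, params: ModelParams) -> LocusState:
    """One generation under the Charlesworth compensation rule.

    Mothers of genotype G contribute with weight (1 - p_m(G))^(1 - C), where
    p_m(G) = 1 - V(G) is their expected embryo early-death probability; the
    embryo reaching the seed stage is drawn from the conditional distribution
    given early survival. Seed-stage selection on inbreeding status follows
    as in :func:`step_backup`.
    """
    f6, _ = _step6(
        _flat(state), params.s, params.h, params.sigma, params.w_inbred,
        charlesworth=True, C=params.C,
    )
    return _unflat(f6)


def _step_for(model) -> bool:
    model = CompensationModel(model)
    return model is CompensationModel.CHARLESWORTH


def invasion_growth_rate(
    params: ModelParams,
    model: CompensationModel | str = CompensationModel.BACKUP_EMBRYO,
    eps: float = 1e-8,
    sensitivity_check: bool = True,
    tol: float = 1e-13,
    max_rounds: int = 5000,
) -> float:
    """Per-generation growth factor lambda of a rare allele A.

    Power iteration on the recursion linearized at p_A = ``eps``: starting
    from all-outbred Hardy-Weinberg proportions (AA mass O(eps^2), the
    dynamically consistent rare-allele structure — under lethal inbreeding no
    selfed seed reaches adulthood, so AA adults are O(p^2)), one recursion
    step is applied and the A-carrying classes are rescaled back to allele
    frequency ``eps`` while the residents relax to their own background
    equilibrium. The per-round frequency ratio converges to the dominant
    eigenvalue of the invasion linearization regardless of the rare-class
    start. lambda > 1 means A invades.

    Warns if halving ``eps`` moves lambda by more than 1e-4 (nonlinear terms
    are not negligible at this ``eps``).
    """
    charlesworth = _step_for(model)
    s, h, sigma, w, C = params.s, params.h, params.sigma, params.w_inbred, params.C

    def lam(e: float) -> float:
        f6 = _flat(LocusState.from_allele_frequency(e, sigma=0.0))
        lam_prev = None
        for _ in range(max_rounds):
            nf6, _ = _step6(f6, s, h, sigma, w, charlesworth, C)
            p1 = nf6[2] / 2.0 + nf6[3] / 2.0 + nf6[4] + nf6[5]
            lam_t = p1 / e
            if p1 <= 0.0:
                return lam_t
            # rescale A-carrying classes to frequency e, keep their internal
            # structure; residents keep theirs and absorb the remainder
            scale = e / p1
            rare = [x * scale for x in nf6[2:]]
            res_mass = nf6[0] + nf6[1]
            res_scale = (1.0 - sum(rare)) / res_mass
            f6 = [nf6[0] * res_scale, nf6[1] * res_scale, *rare]
            if lam_prev is not None and abs(lam_t - lam_prev) < tol:
                return lam_t
            lam_prev = lam_t
        return lam_prev

    lam0 = lam(eps)
    if sensitivity_check:
        lam1 = lam(eps / 2.0)
        if abs(lam1 - lam0) > 1e-4:
            warnings.warn(
                f"invasion growth rate changed by {abs(lam1 - lam0):.2e} when "
                f"eps was halved; decrease eps",
                RuntimeWarning,
                stacklevel=2,
            )
    return lam0


@dataclass(frozen=True)
class EquilibriumResult:
    """Outcome of equilibrium iteration from low and high starting
    frequencies."""

    p_star: float
    state: LocusState
    iterations: int
    converged: bool
    p_star_low: float
    p_star_high: float
    bistable: bool

    @property
    def roots_agree(self) -> bool:
        return not self.bistable


def _iterate(
    f6, s, h, sigma, w_inbred, charlesworth, C, tol, max_iter
):
    for it in range(1, max_iter + 1):
        nf6, _ = _step6(f6, s, h, sigma, w_inbred, charlesworth, C)
        delta = max(abs(a - b) for a, b in zip(nf6, f6))
        f6 = nf6
        if delta < tol:
            return f6, it, True
    return f6, max_iter, False


def find_equilibrium(
    params: ModelParams,
    model: CompensationModel | str = CompensationModel.BACKUP_EMBRYO,
    tol: float = 1e-12,
    max_iter: int = 10_000_000,
    starts: tuple[float, float] = (1e-3, 0.999),
) -> EquilibriumResult:
    """Iterate the genotype-frequency recursion to its stable fixed point.

    Runs from a low and a high initial allele frequency to detect
    bistability; the reported ``p_star`` is the low-start root (the
    biologically relevant one for an allele entering at low frequency), and
    ``bistable`` flags roots differing by more than 1e-6. Non-convergence
    within ``max_iter`` iterations is reported via ``converged`` (the last
    state is still returned).
    """
    charlesworth = _step_for(model)
    # when a rare A cannot invade (lambda <= 1), the low-start trajectory
    # decays to 0; for a fully recessive allele the decay is algebraic in p
    # (through AA exposure only), so iterating to the state-change tolerance
    # would stall at a spurious tiny frequency — report the exact root
    lam = invasion_growth_rate(params, model, sensitivity_check=False)
    cannot_invade = lam <= 1.0 + 1e-12
    roots = []
    states = []
    its = []
    ok = True
    for k, p0 in enumerate(starts):
        if k == 0 and cannot_invade:
            p0 = 0.0  # iterate the resident background only
        state0 = LocusState.from_allele_frequency(p0, sigma=params.sigma)
        f6, it, conv = _iterate(
            _flat(state0), params.s, params.h, params.sigma, params.w_inbred,
            charlesworth, params.C, tol, max_iter,
        )
        st = _unflat(f6)
        roots.append(st.p_A)
        states.append(st)
        its.append(it)
        ok = ok and conv
    # frequencies below iteration tolerance scale are numerically extinct;
    # a non-invading allele's algebraic tail (see above) likewise reads 0
    floor = 1e-4 if cannot_invade else 1e-9
    p_low = roots[0] if roots[0] > floor else 0.0
    p_high = roots[1] if roots[1] > floor else 0.0
    bistable = abs(p_low - p_high) > 1e-6
    return EquilibriumResult(
        p_star=p_low,
        state=states[0],
        iterations=max(its),
        converged=ok,
        p_star_low=p_low,
        p_star_high=p_high,
        bistable=bistable,
    )


@dataclass(frozen=True)
class OracleEstimate:
    """Empirical next-generation state from direct event sampling."""

    freq: np.ndarray        # (3, 2) empirical frequencies among seeds
    se: np.ndarray          # (3, 2) binomial standard errors
    n_seeds: int

    @property
    def p_A(self) -> float:
        return float(self.freq[1].sum() / 2.0 + self.freq[2].sum())

    @property
    def p_A_se(self) -> float:
        # allele-count SE among surviving seeds (binomial on 2*n_seeds copies)
        p = self.p_A
        return float(np.sqrt(max(p * (1 - p), 1e-300) / (2 * self.n_seeds)))


def oracle_step_montecarlo(
    state: LocusState,
    params: ModelParams,
    n_families: int,
    seed: int,
) -> OracleEstimate:
    """Monte-Carlo oracle for :func:`step_backup`: simulates ``n_families``
    i.i.d. maternal families by sampling every event of the backup-embryo
    life cycle directly (mother genotype, per-embryo origin and genotype,
    early viability, primary choice and replacement, seed-stage inbreeding
    survival) and tallies surviving seeds.

    Independent of the deterministic kernel by construction: no shared
    arithmetic beyond the model definition itself.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    s, h, sigma, w = params.s, params.h, params.sigma, params.w_inbred
    g_marg = state.genotype_freq
    p = state.p_A
    v = np.array([1.0, 1.0 - h * s, 1.0 - s])
    mothers = rng.choice(3, size=n_families, p=g_marg)

    def draw_embryos():
        selfed = rng.random(n_families) < sigma
        geno = np.empty(n_families, dtype=np.int64)
        # selfed: Mendelian selfing of the mother's genotype
        u = rng.random(n_families)
        table = np.array(_SELF_TABLE)
        cum = table.cumsum(axis=1)
        sg = (u[:, None] > cum[mothers]).sum(axis=1)
        # outcrossed: maternal gamete + pollen allele
        mat = rng.random(n_families) < np.array(_MATERNAL_A)[mothers]
        pat = rng.random(n_families) < p
        og = mat.astype(np.int64) + pat.astype(np.int64)
        geno = np.where(selfed, sg, og)
        alive = rng.random(n_families) < v[geno]
        return geno, selfed, alive

    g1, s1, a1 = draw_embryos()
    g2, s2, a2 = draw_embryos()
    primary_is_first = rng.random(n_families) < 0.5
    # seed = surviving primary, else surviving backup, else none
    pg = np.where(primary_is_first, g1, g2)
    ps = np.where(primary_is_first, s1, s2)
    pa = np.where(primary_is_first, a1, a2)
    bg = np.where(primary_is_first, g2, g1)
    bs = np.where(primary_is_first, s2, s1)
    ba = np.where(primary_is_first, a2, a1)
    has_seed = pa | ba
    seed_geno = np.where(pa, pg, bg)
    seed_selfed = np.where(pa, ps, bs)
    # seed-stage inbreeding selection
    survives = has_seed & (
        ~seed_selfed | (rng.random(n_families) < w)
    )
    n_seeds = int(survives.sum())
    if n_seeds == 0:
        raise ExtinctionError("Monte-Carlo oracle produced no surviving seeds")
    idx = seed_geno[survives] * 2 + seed_selfed[survives].astype(np.int64)
    counts = np.bincount(idx, minlength=6).astype(float).reshape(3, 2)
    freq = counts / n_seeds
    se = np.sqrt(freq * (1.0 - freq) / n_seeds)
    return OracleEstimate(freq=freq, se=se, n_seeds=n_seeds)
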