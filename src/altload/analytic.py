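"""Closed-form invasion analytics for a self-sacrificial recessive allele.

The focal allele A lowers early embryo survival (1 - h*s in heterozygotes,
1 - s in homozygotes) in a population with primary selfing rate sigma and
reproductive compensation: a dead primary embryo is replaced by an
independently formed half-sib backup. Because a rare recessive is almost only
exposed as a homozygote in selfed embryos, its early expression sacrifices
inbred embryos that were largely doomed anyway (selfed-seed fitness
w_inbred), letting the mother trade them for a likely-outbred backup — so
selection can *favour* the allele.

These expressions are exact in the rare-allele limit (p_A -> 0) and double as
the oracle layer against which the full genotype-frequency recursion in
:mod:`altload.recursion` is validated.
"""

from __future__ import annotations

import math

from .params import ModelParams, _require_unit

__all__ = [
    "psi_replacement",
    "family_mean_fitness_at_invasion",
    "invasion_growth_rate_closed_form",
    "delta_p_invasion",
    "critical_selfing",
    "inbred_survival_threshold",
    "posterior_inbred_given_homozygous",
    "charlesworth_maternal_fitness",
]


def psi_replacement(mother_genotype: str, params: ModelParams) -> float:
    """Probability that the primary embryo of a maternal family dies early
    (and is therefore replaced by the backup), in the invasion-limit family
    structure.

    For aa mothers the only inviable embryos are outcrossed heterozygotes, so
    psi_aa = h*s*p_A*(1 - sigma). For Aa mothers,
    psi_Aa = (s/2)*(h + sigma/2 + p_A*(1 - sigma)), collecting selfed AA
    (sigma/4, dies with probability s), heterozygous (h*s) and outcrossed AA
    embryos.
    """
    s, h, sigma, p = params.s, params.h, params.sigma, params.p_A
    if mother_genotype == "aa":
        return h * s * p * (1.0 - sigma)
    if mother_genotype == "Aa":
        return (s / 2.0) * (h + sigma / 2.0 + p * (1.0 - sigma))
    raise ValueError(
        f"mother_genotype must be 'aa' or 'Aa' at invasion, got {mother_genotype!r}"
    )


def family_mean_fitness_at_invasion(params: ModelParams) -> float:
    """Mean fitness of rare Aa maternal families in the p_A -> 0 limit with
    lethal inbreeding (w_inbred = 0), per transmitted A copy:

        w_fam = (1 - h s)(1 - sigma)(1 + (s/4)(h + sigma/2)).

    At h = 0 this is (1/8)(1 - sigma)(8 + s*sigma), which exceeds the
    population mean fitness 1 - sigma whenever s*sigma > 0: a fully recessive
    self-sacrificial allele is never disfavoured when rare.
    """
    s, h, sigma = params.s, params.h, params.sigma
    return (1.0 - h * s) * (1.0 - sigma) * (1.0 + (s / 4.0) * (h + sigma / 2.0))


def invasion_growth_rate_closed_form(params: ModelParams) -> float:
    """Per-generation growth factor of a rare allele A under the backup-embryo
    model with lethal inbreeding:

        lambda = (1 - h s) (1 + (s/4)(h + sigma/2)) = w_fam / (1 - sigma).

    lambda > 1 means invasion. Setting lambda = 1 and solving for sigma
    recovers :func:`critical_selfing` exactly.
    """
    return family_mean_fitness_at_invasion(params) / (1.0 - params.sigma)


def delta_p_invasion(params: ModelParams) -> float:
    """Expected one-generation increase in frequency of a rare fully
    recessive (h = 0) self-sacrificial allele under lethal inbreeding:

        delta_p = p_A (lambda - 1) = p_A (1 - sigma) s sigma / (8 w_bar),

    with population mean fitness w_bar = 1 - sigma, i.e. p_A * s * sigma / 8.
    Half of each rare Aa mother's seeds carry A, so the allele-frequency gain
    is half the family-fitness excess s*sigma/4.
    """
    if params.h != 0.0:
        raise ValueError("delta_p_invasion assumes full recessivity (h = 0)")
    s, sigma, p = params.s, params.sigma, params.p_A
    w_bar = 1.0 - sigma
    if w_bar == 0.0:
        raise ValueError("sigma = 1 gives zero mean fitness; delta_p undefined")
    return p * (1.0 - sigma) * s * sigma / (8.0 * w_bar)


def critical_selfing(h: float, s: float) -> float:
    """Minimum primary selfing rate at which a partially recessive
    self-sacrificial allele invades (lethal inbreeding):

        crit_self = 2 h (3 + h s) / (1 - h s).

    The first derivative with respect to h at h = 0 is 6, so for small h the
    allele spreads when sigma exceeds roughly 6 h. Values above 1 mean the
    allele cannot invade at any selfing rate; they are returned unchanged so
    callers can inspect the raw expression (flagging is left to the caller).
    """
    h = _require_unit("h", h)
    s = _require_unit("s", s)
    hs = h * s
    if hs >= 1.0:
        raise ValueError(f"h*s must be < 1 for crit_self to be defined, got {hs}")
    return 2.0 * h * (3.0 + hs) / (1.0 - hs)


def inbred_survival_threshold(s: float, sigma: float) -> float:
    """Upper bound on selfed-seed fitness for invasion of a fully recessive
    self-sacrificial allele: the allele invades iff

        w_inbred < s (1 - sigma) / (4 - s sigma).

    At s = 1, sigma -> 0 the bound is 1/4: even a rare lethal recessive
    invades provided inbred seeds are worth less than a quarter of an outbred
    seed.
    """
    s = _require_unit("s", s)
    sigma = _require_unit("sigma", sigma)
    return s * (1.0 - sigma) / (4.0 - s * sigma)


def posterior_inbred_given_homozygous(p_A: float, sigma: float) -> float:
    """Posterior probability that an embryo is inbred given that it is
    homozygous for A (complete recessivity and lethality assumed):

        P(inbred | AA) = (sigma p_A / 2) / (sigma p_A / 2 + p_A^2 (1 - sigma)).

    Strictly decreasing in p_A for 0 < sigma < 1: as A becomes common it is
    increasingly exposed allozygously and stops being a reliable signal of
    inbreeding — the source of the frequency dependence that stabilizes an
    interior equilibrium. The p_A -> 0 limit is 1 for sigma > 0.
    """
    p_A = _require_unit("p_A", p_A)
    sigma = _require_unit("sigma", sigma)
    if p_A == 0.0:
        if sigma == 0.0:
            raise ValueError("posterior undefined at sigma = 0, p_A = 0")
        return 1.0
    num = sigma * p_A / 2.0
    den = num + p_A * p_A * (1.0 - sigma)
    if den == 0.0:
        raise ValueError("posterior undefined: both selfed and outcrossed "
                         "homozygote paths have zero probability")
    return num / den


def charlesworth_maternal_fitness(p_m: float, C: float) -> float:
    """Maternal fitness under the Charlesworth parameterization of
    reproductive compensation: (1 - p_m)^(1 - C), where p_m is the
    probability an embryo dies early and C the extent of compensation.

    C = 0 gives fitness 1 - p_m (no compensation); C = 1 gives 1 (every lost
    embryo fully replaced).
    """
    C = _require_unit("C", C)
    p_m = float(p_m)
    if not 0.0 <= p_m < 1.0:
        raise ValueError(f"p_m must lie in [0, 1), got {p_m!r}")
    return math.pow(1.0 - p_m, 1.0 - C)
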