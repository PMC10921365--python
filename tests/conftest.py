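"""Shared fixtures; the session-scoped simulation panel backs the
genome-scale comparative checks (treatment vs control load, its mutation-
rate and selfing-rate dependence, and allele ages)."""

import numpy as np
import pytest

from altload.params import SimParams
from altload.simulate import run_to_balance
from altload.summaries import summarize_load

PANEL_BASE_SEED = 20240306


def _seed(*key) -> int:
    ss = np.random.SeedSequence([PANEL_BASE_SEED, *key])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _run_cell(sigma, mu, w, mode, rep, **gen_kw):
    params = SimParams(
        s=1.0, h=0.0, sigma=sigma, w_inbred=w, mu=mu, N=1000,
        n_sites=100_000, n_chromosomes=10, replacement_mode=mode,
        balance_window=500,
        seed=_seed(int(sigma * 100), int(mu * 1e9), int(w * 100),
                   0 if mode == "sibling" else 1, rep),
        **gen_kw,
    )
    res = run_to_balance(params)
    win = res.trajectory.iloc[-500:]
    out = {
        "status": res.status,
        "generations": int(res.trajectory["generation"].iloc[-1]),
        "count": float(win["mean_mutations_per_individual"].mean()),
        "freq": float(win["mean_segregating_frequency"].mean()),
        "n_segregating": float(win["n_segregating"].mean()),
    }
    if res.population is not None:
        summ = summarize_load(res.population)
        out["age_mean"] = summ.mean_allele_age
        out["final_count"] = summ.mean_mutations_per_individual
    return out


@pytest.fixture(scope="session")
def balance_panel():
    """Balanced (or fixed-horizon, for the high-mutation-rate cells)
    N = 1000 runs of the genome-scale simulator over the comparative panel:
    recessive lethals (s = 1, h = 0), both replacement modes.

    Problem sizes are the package's desk-scale choices: lethal-inbreeding
    low-mutation cells run to stationarity (cap 8000 generations; two
    replicate pairs at sigma = 0.1), the high-mutation comparison uses a
    fixed 250-generation horizon for both arms (mutation input dominates
    long before balance), and sublethal cells run to stationarity with a
    6000-generation cap.
    """
    panel = {}
    low = dict(mu=5e-8, w=0.0)
    # sigma = 0.1: replicate pairs, equal horizons for the age comparison
    for rep in range(2):
        for mode in ("sibling", "random_pair"):
            panel[("low", 0.1, mode, rep)] = _run_cell(
                0.1, low["mu"], low["w"], mode, rep,
                min_generations=4000, generations=8000,
            )
    for sigma in (0.2, 0.3):
        panel[("low", sigma, "sibling", 0)] = _run_cell(
            sigma, low["mu"], low["w"], "sibling", 0,
            min_generations=4000, generations=8000,
        )
        panel[("low", sigma, "random_pair", 0)] = _run_cell(
            sigma, low["mu"], low["w"], "random_pair", 0,
            min_generations=2500, generations=5000,
        )
    # high mutation rate: fixed-horizon paired comparison
    for mode in ("sibling", "random_pair"):
        panel[("high", 0.3, mode, 0)] = _run_cell(
            0.3, 5e-6, 0.0, mode, 0,
            min_generations=10**9, generations=250,
        )
    # sublethal inbreeding depression
    for sigma in (0.1, 0.3):
        for mode in ("sibling", "random_pair"):
            panel[("sub", sigma, mode, 0)] = _run_cell(
                sigma, 5e-8, 0.25, mode, 0,
                min_generations=2500, generations=6000,
            )
    return panel
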