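from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import apmsnet as a

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_experiment():
    """One strong-effect synthetic experiment shared across tests."""
    cfg = a.SimConfig(
        proteome_size=400, n_baits=2, partners_per_bait=10,
        effect_log2fc=(4.0, 6.0), undetectable_fraction=0.0, seed=11,
    )
    counts, sheet, truth = a.simulate_experiment(cfg)
    return cfg, counts, sheet, truth


@pytest.fixture(scope="session")
def fitted(small_experiment):
    _, counts, sheet, _ = small_experiment
    return a.Interactome(counts, sheet).fit()


def _null_sim(seed: int):
    cfg = a.SimConfig(
        proteome_size=400, n_baits=1, partners_per_bait=0,
        conditions=(a.Condition(sulfur=True),), seed=seed,
    )
    counts, sheet, _ = a.simulate_experiment(cfg)
    res = a.Interactome(counts, sheet).fit()
    sticky_mean = cfg.background_mean * cfg.sticky_boost
    return res, sticky_mean


@pytest.fixture(scope="session")
def null_calibration():
    """Significant-call fractions over 50 partner-free simulations.

    Returns (per-sim fraction of tested non-self proteins called
    significant, per-sim sticky-protein call counts as (called, tested)).
    """
    fractions = []
    sticky = []
    for seed in range(50):
        res, sticky_mean = _null_sim(seed)
        recs = [r for r in res.records if not r.is_self]
        n_sig = sum(r.significant for r in recs)
        fractions.append(n_sig / len(recs) if recs else 0.0)
        sticky_recs = [r for r in recs if r.mean_ctrl > sticky_mean / 2]
        sticky.append((sum(r.significant for r in sticky_recs), len(sticky_recs)))
    return np.array(fractions), sticky


@pytest.fixture(scope="session")
def recovery_rates():
    """Per-seed planted-partner recovery at rank >= 4 for strong effects."""
    rates = []
    for seed in range(25):
        cfg = a.SimConfig(
            proteome_size=500, n_baits=1, partners_per_bait=30,
            effect_log2fc=(4.0, 6.0), background_mean=10.0,
            detectability=1.0, undetectable_fraction=0.0,
            conditions=(a.Condition(sulfur=True),), seed=1000 + seed,
        )
        counts, sheet, truth = a.simulate_experiment(cfg)
        res = a.Interactome(counts, sheet).fit()
        net = res.network(min_rank=4)
        planted = truth.pairs(a.Condition(sulfur=True), detectable_only=True)
        recovered = {(e.bait_gene, e.prey_protein) for e in net.edges}
        rates.append(len(planted & recovered) / len(planted))
    return np.array(rates)
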