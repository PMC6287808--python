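"""Shared fixtures: small simulated populations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from conifergs.genome import GenomeSpec
from conifergs.simulate import RecentConfig, run_extended, run_historical, run_recent
from conifergs.trait import sample_qtl_effects


@pytest.fixture(scope="session")
def small_spec() -> GenomeSpec:
    rng = np.random.default_rng(11)
    return GenomeSpec.random(n_markers=120, n_qtl=40, rng=rng)


@pytest.fixture(scope="session")
def burnin_pop(small_spec):
    """A drifted population with accrued LD (reduced-scale burn-in)."""
    hist = run_historical(
        small_spec, n_generations=60, n_female=50, n_male=50, pop_size=200, seed=21
    )
    return run_extended(
        hist, small_spec, seed=22, n_generations=5, n_female=30, n_male=30, pop_size=120
    )


@pytest.fixture(scope="session")
def small_trait(small_spec, burnin_pop):
    rng = np.random.default_rng(31)
    return sample_qtl_effects(
        burnin_pop, rng, qtl_idx=small_spec.qtl_idx, h2=0.5, target_variance=300.0
    )


@pytest.fixture(scope="session")
def small_recent(small_spec, burnin_pop, small_trait):
    """A reduced breeding program: 8+8 parents, 6 offspring, 3 ramets, 4 gens."""
    cfg = RecentConfig(n_female=8, n_male=8, n_offspring=6, n_ramets=3, n_generations=4)
    return run_recent(burnin_pop, small_spec, small_trait, seed=41, config=cfg)
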