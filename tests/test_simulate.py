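"""Forward simulator: demography, drift neutrality, breeding-phase structure."""

import numpy as np
import pytest

from conifergs.genome import GenomeSpec
from conifergs.population import FOUNDER
from conifergs.simulate import RecentConfig, run_extended, run_historical, run_recent
from conifergs.trait import TraitModel


def _one_locus_spec(mutation_rate=0.0):
    return GenomeSpec(
        marker_positions=np.array([75.0]),
        qtl_positions=np.empty(0),
        mutation_rate=mutation_rate,
    )


def test_zero_generations_returns_founders_unchanged():
    spec = _one_locus_spec()
    pop = run_historical(spec, n_generations=0, n_female=10, n_male=10, pop_size=50, seed=0)
    assert pop.size == 50
    assert np.all(pop.sire == FOUNDER)


def test_historical_population_size_constant():
    rng = np.random.default_rng(0)
    spec = GenomeSpec.random(n_markers=30, n_qtl=10, rng=rng)
    pop = run_historical(spec, n_generations=5, n_female=30, n_male=30, pop_size=100, seed=1)
    assert pop.size == 100
    assert pop.generation == 5


def test_invalid_demography_rejected():
    spec = _one_locus_spec()
    with pytest.raises(ValueError):
        run_historical(spec, n_generations=1, n_female=0, n_male=10, pop_size=50, seed=0)
    with pytest.raises(ValueError):
        run_historical(spec, n_generations=1, n_female=40, n_male=40, pop_size=50, seed=0)


def test_drift_is_neutral_on_average():
    """Wright-Fisher neutrality: zero expected allele-frequency change.

    Single biallelic locus, 20 replicate seeds; the mean final frequency
    stays within 3 standard errors of the mean initial frequency.
    """
    spec = _one_locus_spec(mutation_rate=0.0)
    init, final = [], []
    for seed in range(20):
        pop0 = run_historical(spec, n_generations=0, n_female=50, n_male=50,
                              pop_size=300, seed=seed)
        init.append(pop0.allele_frequencies()[0])
        pop = run_historical(spec, n_generations=40, n_female=50, n_male=50,
                             pop_size=300, seed=seed)
        final.append(pop.allele_frequencies()[0])
    diff = np.array(final) - np.array(init)
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    assert abs(diff.mean()) < 3 * max(se, 1e-3)


def test_extended_size_and_bottleneck_heterozygosity():
    """Drift through the bottleneck reduces expected heterozygosity."""
    rng = np.random.default_rng(1)
    spec = GenomeSpec.random(n_markers=60, n_qtl=0, rng=rng, mutation_rate=0.0)
    het_before, het_after = [], []
    for seed in range(20):
        pop = run_historical(spec, n_generations=2, n_female=40, n_male=40,
                             pop_size=150, seed=seed)
        ext = run_extended(pop, spec, seed=seed + 100, n_generations=5,
                           n_female=10, n_male=10, pop_size=60)
        p0 = pop.allele_frequencies()
        p1 = ext.allele_frequencies()
        het_before.append((2 * p0 * (1 - p0)).mean())
        het_after.append((2 * p1 * (1 - p1)).mean())
    assert np.mean(het_after) < np.mean(het_before)


def test_extended_requires_both_sexes():
    spec = _one_locus_spec()
    pop = run_historical(spec, n_generations=0, n_female=10, n_male=10, pop_size=40, seed=3)
    pop.sex[:] = 0  # all female
    with pytest.raises(ValueError):
        run_extended(pop, spec, seed=0, n_generations=1, n_female=5, n_male=5, pop_size=20)


def test_recent_counts_default_structure(small_spec, burnin_pop, small_trait):
    """One default-structure generation: 64 crosses x 15 offspring = 960 clones."""
    cfg = RecentConfig(n_generations=1)
    rp = run_recent(burnin_pop, small_spec, small_trait, seed=5, config=cfg)
    pop = rp.populations[1]
    assert pop.size == 960
    # each parent used exactly twice
    sire_counts = np.unique(pop.sire, return_counts=True)[1]
    dam_counts = np.unique(pop.dam, return_counts=True)[1]
    assert np.all(sire_counts == 2 * cfg.n_offspring)
    assert np.all(dam_counts == 2 * cfg.n_offspring)
    assert len(np.unique(pop.sire)) == 32 and len(np.unique(pop.dam)) == 32
    # 4 phenotype records per clone
    counts = rp.phenotypes[1].groupby("clone_id").size()
    assert (counts == 4).all() and len(counts) == 960


def test_recent_pedigree_closure_and_family_sizes(small_recent):
    cfg = small_recent.config
    for gen, pop in small_recent.populations.items():
        fams = set(zip(pop.sire.tolist(), pop.dam.tolist()))
        assert len(fams) == cfg.n_crosses
        assert pop.size == cfg.n_clones
        if gen > 1:
            prev = small_recent.populations[gen - 1]
            known = set(prev.ids.tolist())
            assert set(pop.sire.tolist()) <= known and set(pop.dam.tolist()) <= known


def test_recent_selection_response():
    """Truncation selection on EBVs yields positive response in >= 18/20 seeds.

    Uses a reduced breeding structure so 20 replicates stay cheap; the
    response mechanism (BLUP ranking, circular mating) is identical to the
    default structure.
    """
    rng = np.random.default_rng(7)
    spec = GenomeSpec.random(n_markers=40, n_qtl=30, rng=rng)
    cfg = RecentConfig(n_female=6, n_male=6, n_offspring=5, n_ramets=3, n_generations=4)
    wins = 0
    for seed in range(20):
        pop = run_historical(spec, n_generations=3, n_female=30, n_male=30,
                             pop_size=100, seed=seed)
        from conifergs.trait import sample_qtl_effects

        trait = sample_qtl_effects(pop, np.random.default_rng(seed + 500),
                                   qtl_idx=spec.qtl_idx, h2=0.5)
        rp = run_recent(pop, spec, trait, seed=seed + 900, config=cfg)
        if rp.tbv[4].mean() > rp.tbv[1].mean():
            wins += 1
    assert wins >= 18


def test_allele_conservation_without_mutation_or_selection():
    """Expected allele-frequency change is zero over replicate seeds."""
    rng = np.random.default_rng(8)
    spec = GenomeSpec.random(n_markers=40, n_qtl=0, rng=rng, mutation_rate=0.0)
    deltas = []
    for seed in range(10):
        pop0 = run_historical(spec, n_generations=0, n_female=30, n_male=30,
                              pop_size=120, seed=seed)
        pop1 = run_historical(spec, n_generations=10, n_female=30, n_male=30,
                              pop_size=120, seed=seed)
        deltas.append(pop1.allele_frequencies() - pop0.allele_frequencies())
    mean_delta = np.concatenate(deltas).mean()
    assert abs(mean_delta) < 0.01


def test_trend_base_tracks_true_genetic_gain(small_recent):
    """The per-generation trend offsets approximate the realised TBV trend."""
    gens = sorted(small_recent.populations)
    tbv_trend = [small_recent.tbv[g].mean() for g in gens]
    base = [small_recent.generation_base[g] for g in gens]
    # both increase under selection, and the base tracks the trend loosely
    assert base[-1] > base[0]
    assert np.corrcoef(tbv_trend, base)[0, 1] > 0.8
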