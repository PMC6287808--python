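"""Three-phase forward-in-time population simulation.

Phase 1 ("historical", 500 generations, 300 female + 300 male parents,
constant size 1000) and phase 2 ("extended", 10 generations, 100 + 100
parents, size 500) are neutral random-mating drift phases with recurrent
mutation; together they establish mutation-drift equilibrium and the LD
a genomic-selection scheme exploits. Phase 3 ("recent", 10 discrete
generations) emulates an elite conifer breeding population: 32 female and
32 male parents selected on pedigree-BLUP EBVs, circular mating with each
parent crossed twice (64 crosses), 15 offspring per family (960 clones),
4 ramets per clone, no mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .blup import EvaluationResult, build_A_from_arrays, solve_collapsed_clone_model
from .genome import GenomeSpec, make_gametes, sample_founder_haplotypes
from .population import FOUNDER, Population
from .trait import TraitModel, simulate_phenotypes, true_breeding_value

__all__ = [
    "RecentConfig",
    "RecentPhase",
    "run_historical",
    "run_extended",
    "run_recent",
    "simulate_burn_in",
]


def _founders(spec: GenomeSpec, n: int, rng: np.random.Generator, phase: str) -> Population:
    hap = sample_founder_haplotypes(spec, n, rng)
    return Population(
        ids=np.arange(n, dtype=np.int64),
        haplotypes=hap,
        sire=np.full(n, FOUNDER, dtype=np.int64),
        dam=np.full(n, FOUNDER, dtype=np.int64),
        sex=rng.integers(0, 2, size=n).astype(np.uint8),
        generation=0,
        phase=phase,
    )


def _advance_random_mating(
    pop: Population,
    spec: GenomeSpec,
    n_female: int,
    n_male: int,
    pop_size: int,
    rng: np.random.Generator,
    mutation_rate: float,
    next_id: int,
) -> Population:
    """One generation of random union of gametes among sampled parents."""
    females = np.flatnonzero(pop.sex == 0)
    males = np.flatnonzero(pop.sex == 1)
    if len(females) < n_female or len(males) < n_male:
        raise ValueError(
            f"demography needs {n_female}F+{n_male}M parents, "
            f"population has {len(females)}F/{len(males)}M"
        )
    dams_pool = rng.choice(females, size=n_female, replace=False)
    sires_pool = rng.choice(males, size=n_male, replace=False)
    dam_idx = rng.choice(dams_pool, size=pop_size, replace=True)
    sire_idx = rng.choice(sires_pool, size=pop_size, replace=True)
    pos = spec.positions
    hap = np.stack(
        [
            make_gametes(pop.haplotypes[dam_idx], pos, rng, mutation_rate, spec.chromosome_length),
            make_gametes(pop.haplotypes[sire_idx], pos, rng, mutation_rate, spec.chromosome_length),
        ],
        axis=1,
    )
    return Population(
        ids=np.arange(next_id, next_id + pop_size, dtype=np.int64),
        haplotypes=hap,
        sire=pop.ids[sire_idx],
        dam=pop.ids[dam_idx],
        sex=rng.integers(0, 2, size=pop_size).astype(np.uint8),
        generation=pop.generation + 1,
        phase=pop.phase,
    )


def run_historical(
    spec: GenomeSpec,
    n_generations: int = 500,
    n_female: int = 300,
    n_male: int = 300,
    pop_size: int = 1000,
    seed: int = 0,
) -> Population:
    """Neutral burn-in from linkage-equilibrium founders.

    Returns the final generation (constant size ``pop_size``). With
    ``n_generations=0`` the founder population is returned unchanged.
    """
    if n_female <= 0 or n_male <= 0 or pop_size <= 0:
        raise ValueError("parent and population counts must be positive")
    if n_female + n_male > pop_size:
        raise ValueError("n_female + n_male must not exceed pop_size")
    rng = np.random.default_rng(seed)
    pop = _founders(spec, pop_size, rng, "historical")
    for _ in range(n_generations):
        pop = _advance_random_mating(
            pop, spec, n_female, n_male, pop_size, rng,
            spec.mutation_rate, next_id=int(pop.ids.max()) + 1,
        )
    return pop


def run_extended(
    pop: Population,
    spec: GenomeSpec,
    seed: int = 0,
    n_generations: int = 10,
    n_female: int = 100,
    n_male: int = 100,
    pop_size: int = 500,
) -> Population:
    """Bottleneck drift phase (default 10 generations at size 500)."""
    if pop.size == 0 or (pop.sex == 0).sum() == 0 or (pop.sex == 1).sum() == 0:
        raise ValueError("input population must be nonempty with both sexes")
    rng = np.random.default_rng(seed)
    out = pop
    for g in range(n_generations):
        if g == 0:
            out = Population(**{**out.__dict__, "phase": "extended", "generation": 0})
        out = _advance_random_mating(
            out, spec, n_female, n_male, pop_size, rng,
            spec.mutation_rate, next_id=int(out.ids.max()) + 1,
        )
    return out


def simulate_burn_in(spec: GenomeSpec, seed: int, n_historical: int = 500, **kwargs) -> Population:
    """Historical + extended phases with stage-split seeds."""
    hist = run_historical(spec, n_generations=n_historical, seed=seed, **kwargs)
    return run_extended(hist, spec, seed=seed + 1)


# --------------------------------------------------------------------------
# Recent discrete generations (the breeding program proper)


@dataclass(frozen=True)
class RecentConfig:
    """Structure of one recent breeding generation.

    Defaults are the elite-population design: 32 + 32 parents, circular
    mating with each parent crossed twice, 15 offspring per family
    (-> 960 clones) and 4 ramets per clone.
    """

    n_female: int = 32
    n_male: int = 32
    n_offspring: int = 15
    n_ramets: int = 4
    n_generations: int = 10
    #: generations of records entering each BLUP evaluation (the current one
    #: plus eval_window - 1 preceding ones, whose clones include the parents)
    eval_window: int = 2

    @property
    def n_crosses(self) -> int:
        return self.n_female + self.n_male

    @property
    def n_clones(self) -> int:
        return self.n_crosses * self.n_offspring


@dataclass
class RecentPhase:
    """Per-generation populations, phenotypes and BLUP evaluations."""

    config: RecentConfig
    trait: TraitModel
    populations: dict[int, Population] = field(default_factory=dict)
    phenotypes: dict[int, pd.DataFrame] = field(default_factory=dict)
    evaluations: dict[int, EvaluationResult] = field(default_factory=dict)
    tbv: dict[int, np.ndarray] = field(default_factory=dict)
    parent_ids: dict[int, np.ndarray] = field(default_factory=dict)
    #: estimated genetic-trend offset per generation: each generation's EBVs
    #: are deviations from its own mean; adding the offset puts EBVs of
    #: different generations on one base (offset_t = offset_{t-1} + mean
    #: selected-parent EBV deviation, the realised selection differential).
    generation_base: dict[int, float] = field(default_factory=dict)

    def absolute_ebv(self, generation: int) -> np.ndarray:
        """EBVs of one generation on the common (trend-inclusive) base."""
        return self.evaluations[generation].ebv + self.generation_base[generation]

    @property
    def final(self) -> Population:
        return self.populations[max(self.populations)]

    def pedigree_frame(self) -> pd.DataFrame:
        frames = [p.pedigree_frame(self.config.n_ramets) for p in self.populations.values()]
        return pd.concat(frames, ignore_index=True)


def _circular_crosses(
    fem_idx: np.ndarray, male_idx: np.ndarray, order: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ring of alternating F/M parents; each parent mated to both neighbours.

    ``fem_idx``/``male_idx`` are assumed rank-ordered (best first); the ring
    alternates F1, M1, F2, M2, ... so each cross is a female x male pair and
    each parent appears in exactly two crosses.
    """
    if len(fem_idx) != len(male_idx):
        raise ValueError("circular design needs equal numbers of each sex")
    k = len(fem_idx)
    ring = np.empty(2 * k, dtype=fem_idx.dtype)
    ring[0::2] = fem_idx
    ring[1::2] = male_idx
    left = ring
    right = np.roll(ring, -1)
    dams = np.where(np.arange(2 * k) % 2 == 0, left, right)
    sires = np.where(np.arange(2 * k) % 2 == 0, right, left)
    return dams, sires


def _evaluate_window(
    window: list[tuple[Population, pd.DataFrame]],
    lineage: dict[int, tuple[int, int]],
    trait: TraitModel,
    with_accuracy: bool,
) -> EvaluationResult:
    """Pedigree BLUP of the newest generation from a window of records.

    Records of the windowed generations (the current clones plus their
    parents' generation(s)) enter one mixed model. The numerator
    relationship matrix is built over the windowed clones' full recent-phase
    lineage (ancestors first) and marginalised to the recorded clones —
    exact for BLUP because only recorded clones carry data. The clone-level
    non-additive effect is absorbed into the clone-mean residual (exact;
    see :func:`conifergs.blup.solve_collapsed_clone_model`). Recent-phase
    founders are treated as an unrelated base. Returned EBVs are deviations
    from the newest generation's mean EBV.
    """
    ids: list[int] = []
    parent_of: dict[int, tuple[int, int]] = {}
    for pop, _ in window:
        for j in range(pop.size):
            v = int(pop.ids[j])
            ids.append(v)
            parent_of[v] = (int(pop.sire[j]), int(pop.dam[j]))
    known = set(ids)
    frontier = {
        p
        for v in ids
        for p in parent_of[v]
        if p != FOUNDER and p not in known
    }
    ancestors: list[int] = []
    while frontier:
        ancestors.extend(sorted(frontier))
        nxt = set()
        for a in frontier:
            for p in lineage.get(a, (FOUNDER, FOUNDER)):
                if p != FOUNDER:
                    nxt.add(p)
        frontier = nxt - set(ancestors) - known
    ordered = ancestors[::-1] + ids  # oldest first; parents precede offspring
    index = {v: i for i, v in enumerate(ordered)}
    sire_arr = np.full(len(ordered), -1, dtype=np.int64)
    dam_arr = np.full(len(ordered), -1, dtype=np.int64)
    for i, v in enumerate(ordered):
        sa, da = parent_of.get(v) or lineage.get(v, (FOUNDER, FOUNDER))
        sire_arr[i] = index.get(sa, -1)
        dam_arr[i] = index.get(da, -1)
    A_full = build_A_from_arrays(sire_arr, dam_arr)
    clone_rows = np.array([index[v] for v in ids])
    A = A_full[np.ix_(clone_rows, clone_rows)]

    means = pd.concat([ph for _, ph in window]).groupby("clone_id")["phenotype"].agg(
        ["mean", "size"]
    )
    means = means.loc[ids]  # align with clone order
    ebv_all, acc_all = solve_collapsed_clone_model(
        y_clone_mean=means["mean"].to_numpy(),
        n_records=means["size"].to_numpy(),
        A=A,
        sigma2_a=trait.sigma2_a,
        sigma2_d=trait.sigma2_d,
        sigma2_e=trait.sigma2_e,
        with_accuracy=with_accuracy,
    )
    newest = window[-1][0]
    sl = slice(len(ids) - newest.size, len(ids))
    ebv = ebv_all[sl] - ebv_all[sl].mean()
    acc = acc_all[sl] if acc_all is not None else None
    return EvaluationResult(clone_ids=newest.ids.copy(), ebv=ebv, accuracy_r=acc, method="BLUP")


def run_recent(
    pop: Population,
    spec: GenomeSpec,
    trait: TraitModel,
    n_generations: int | None = None,
    seed: int = 0,
    config: RecentConfig = RecentConfig(),
    accuracy_generations: set[int] | None = None,
    evaluator: Callable[..., EvaluationResult] | None = None,
) -> RecentPhase:
    """Run the recent discrete breeding generations.

    Generation-1 parents are drawn at random from ``pop`` (no phenotypes
    exist before the first recent generation); thereafter the top
    ``n_female``/``n_male`` clones by BLUP EBV within sex are selected and
    mated circularly. No mutation occurs in this phase.
    """
    if n_generations is None:
        n_generations = config.n_generations
    rng = np.random.default_rng(seed)
    result = RecentPhase(config=config, trait=trait)
    lineage: dict[int, tuple[int, int]] = {}
    evaluate = evaluator or _evaluate_window
    window: list[tuple[Population, pd.DataFrame]] = []

    current = pop
    ebv_rank: np.ndarray | None = None  # EBVs aligned with `current` clones
    base = 0.0  # genetic-trend offset of the current offspring generation
    next_id = int(pop.ids.max()) + 1
    for gen in range(1, n_generations + 1):
        females = np.flatnonzero(current.sex == 0)
        males = np.flatnonzero(current.sex == 1)
        if len(females) < config.n_female or len(males) < config.n_male:
            raise ValueError(
                f"generation {gen}: need {config.n_female}F+{config.n_male}M parents"
            )
        if ebv_rank is None:
            fem = rng.choice(females, size=config.n_female, replace=False)
            male = rng.choice(males, size=config.n_male, replace=False)
        else:
            fem = females[np.argsort(-ebv_rank[females], kind="stable")][: config.n_female]
            male = males[np.argsort(-ebv_rank[males], kind="stable")][: config.n_male]
            # offspring mean ≈ midparent: advance the trend base by the
            # realised selection differential on EBVs
            base += float(ebv_rank[np.concatenate([fem, male])].mean())
        dams, sires = _circular_crosses(fem, male)
        dam_idx = np.repeat(dams, config.n_offspring)
        sire_idx = np.repeat(sires, config.n_offspring)
        n_new = len(dam_idx)
        pos = spec.positions
        hap = np.stack(
            [
                make_gametes(current.haplotypes[dam_idx], pos, rng,
                             0.0, spec.chromosome_length),
                make_gametes(current.haplotypes[sire_idx], pos, rng,
                             0.0, spec.chromosome_length),
            ],
            axis=1,
        )
        offspring = Population(
            ids=np.arange(next_id, next_id + n_new, dtype=np.int64),
            haplotypes=hap,
            sire=current.ids[sire_idx],
            dam=current.ids[dam_idx],
            sex=rng.integers(0, 2, size=n_new).astype(np.uint8),
            generation=gen,
            phase="recent",
        )
        next_id += n_new
        for i in range(n_new):
            lineage[int(offspring.ids[i])] = (int(offspring.sire[i]), int(offspring.dam[i]))

        tbv = true_breeding_value(offspring.genotypes(spec.qtl_idx), trait)
        phenos = simulate_phenotypes(offspring, trait, config.n_ramets, rng, tbv=tbv)
        window.append((offspring, phenos))
        if len(window) > config.eval_window:
            window.pop(0)
        with_acc = accuracy_generations is None or gen in accuracy_generations
        try:
            ev = evaluate(window, lineage, trait, with_acc)
        except Exception as exc:  # annotate where the evaluator failed
            raise RuntimeError(f"evaluation failed at recent generation {gen}") from exc

        result.populations[gen] = offspring
        result.phenotypes[gen] = phenos
        result.evaluations[gen] = ev
        result.tbv[gen] = tbv
        result.parent_ids[gen] = np.unique(np.concatenate([current.ids[dams], current.ids[sires]]))
        result.generation_base[gen] = base

        current = offspring
        ebv_rank = ev.ebv
    return result
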