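"""End-to-end experiment driver: simulate -> BLUP -> BayesC -> gain -> deploy.

A ``RunConfig`` fixes genome, demography, trait, sampler and factorial
settings; every random draw flows from the master seed through named stage
streams, so a run's resolved config plus seed reproduces its outputs
exactly. Two presets are provided: ``full`` mirrors the published design
(500-generation burn-in, panels up to 8,000 SNPs, training populations up
to 3,000, 40,000 MCMC iterations); ``desk`` is a scaled-down configuration
(100-generation burn-in, panels up to 1,200 SNPs, training up to 500,
2,000 iterations) for tests and exploratory runs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._streams import stage_rng, stage_seed
from .bayesc import (
    BayesCConfig,
    TrainingSet,
    deregression_weights,
    filter_markers,
    gebv_accuracy,
    predict_gebv,
    run_bayesc,
)
from .blup import ebv_accuracy_summary
from .datasets import example_gains
from .deploy import deployment_table
from .gain import gain_per_year_table, select_top
from .genome import GenomeSpec, select_panel
from .io import dump_config
from .simulate import RecentConfig, run_extended, run_historical, run_recent
from .trait import sample_qtl_effects

__all__ = ["RunConfig", "run_replicate", "run_experiment", "summarize"]


@dataclass(frozen=True)
class RunConfig:
    # genome
    n_markers: int = 1200
    n_qtl: int = 350
    chromosome_length: float = 150.0
    mutation_rate: float = 1e-5
    min_initial_maf: float = 0.10
    #: burn-in runs on surplus candidate loci; the working panel is chosen
    #: from loci still segregating (markers: MAF > min_initial_maf) at the
    #: end of the burn-in, as forward simulators assemble SNP panels
    candidate_surplus: float = 2.5
    # demography
    n_historical: int = 100
    historical_parents: tuple[int, int] = (300, 300)
    historical_size: int = 1000
    n_extended: int = 10
    extended_parents: tuple[int, int] = (100, 100)
    extended_size: int = 500
    recent: RecentConfig = RecentConfig()
    # trait
    sigma2_a: float = 300.0
    d_fraction: float = 0.15
    h2_values: tuple[float, ...] = (0.2, 0.5)
    qtl_shape: float = 0.50
    qtl_scale: float = 26.0
    # factorial
    panels: tuple[int, ...] = (600, 1200)
    training_sizes: tuple[int, ...] = (200, 500)
    training_generations: tuple[int, ...] = (4, 5, 6, 7, 8)
    prediction_generation: int = 10
    n_select: int = 9
    # sampler
    pi: float = 0.95
    nu_a: float = 4.2
    n_iter: int = 2000
    burn_in: int | None = None
    c_weight: float = 0.5
    min_train_maf: float = 0.01
    # run
    replicates: int = 5
    seed: int = 1
    scale: str = "desk"

    @classmethod
    def preset(cls, scale: str = "desk", **overrides) -> "RunConfig":
        if scale == "full":
            base = cls(
                n_markers=8000,
                n_historical=500,
                panels=(600, 1200, 2500, 4900, 8000),
                training_sizes=(800, 1000, 2000, 3000),
                n_iter=40_000,
                replicates=10,
                scale="full",
            )
        elif scale == "desk":
            base = cls()
        else:
            raise ValueError(f"unknown scale preset {scale!r}")
        return replace(base, **overrides)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["recent"] = asdict(self.recent)
        return d


def _simulate_base(config: RunConfig, replicate: int):
    """Genome spec + burn-in population for one replicate.

    Drift runs on a surplus of candidate loci; the working marker panel and
    QTL set are then drawn from loci still segregating at the end of the
    burn-in (markers above the MAF floor), so the panel composition matches
    the population the breeding program starts from.
    """
    import dataclasses

    rng = stage_rng(config.seed, "genome", replicate)
    candidate_spec = GenomeSpec.random(
        n_markers=int(config.n_markers * config.candidate_surplus),
        n_qtl=int(config.n_qtl * config.candidate_surplus),
        chromosome_length=config.chromosome_length,
        rng=rng,
        mutation_rate=config.mutation_rate,
        min_initial_maf=config.min_initial_maf,
    )
    hist = run_historical(
        candidate_spec,
        n_generations=config.n_historical,
        n_female=config.historical_parents[0],
        n_male=config.historical_parents[1],
        pop_size=config.historical_size,
        seed=stage_seed(config.seed, "historical", replicate),
    )
    base = run_extended(
        hist,
        candidate_spec,
        seed=stage_seed(config.seed, "extended", replicate),
        n_generations=config.n_extended,
        n_female=config.extended_parents[0],
        n_male=config.extended_parents[1],
        pop_size=config.extended_size,
    )
    spec, hap = select_panel(
        base.haplotypes,
        candidate_spec,
        n_markers=config.n_markers,
        n_qtl=config.n_qtl,
        rng=stage_rng(config.seed, "panel_select", replicate),
    )
    base = dataclasses.replace(base, haplotypes=hap)
    return spec, base


def _panel_markers(spec: GenomeSpec, panel: int, rng: np.random.Generator) -> np.ndarray:
    """Locus indices of a panel subset (all markers if panel covers them)."""
    markers = spec.marker_idx
    if panel >= len(markers):
        return markers
    keep = np.sort(rng.choice(len(markers), size=panel, replace=False))
    return markers[keep]


def run_replicate(config: RunConfig, replicate: int = 0) -> pd.DataFrame:
    """One replicate of the full factorial; returns tidy per-cell rows."""
    spec, base = _simulate_base(config, replicate)
    trait_rng = stage_rng(config.seed, "trait", replicate)
    trait0 = sample_qtl_effects(
        base,
        trait_rng,
        shape=config.qtl_shape,
        scale=config.qtl_scale,
        target_variance=config.sigma2_a,
        h2=config.h2_values[0],
        d_fraction=config.d_fraction,
        qtl_idx=spec.qtl_idx,
    )
    acc_gens = set(config.training_generations) | {config.prediction_generation}
    rows = []
    for h2 in config.h2_values:
        trait = trait0.with_h2(h2)
        recent = run_recent(
            base,
            spec,
            trait,
            n_generations=config.recent.n_generations,
            seed=stage_seed(config.seed, f"recent_h{h2}", replicate),
            config=config.recent,
            accuracy_generations=acc_gens,
        )
        pred_gen = config.prediction_generation
        pred_pop = recent.populations[pred_gen]
        pred_tbv = recent.tbv[pred_gen]
        pred_ev = recent.evaluations[pred_gen]
        ebv_acc = ebv_accuracy_summary(pred_ev.ebv, pred_tbv)
        fs = select_top(
            pred_ev.ebv, pred_tbv, pred_pop.ids, n=config.n_select, scheme="FS"
        )

        # pooled training candidates (generations 4-8)
        cand_parts = []
        for g in config.training_generations:
            ev = recent.evaluations[g]
            cand_parts.append(
                (recent.populations[g].genotypes(), recent.absolute_ebv(g),
                 ev.accuracy_r, ev.clone_ids)
            )
        cand_X = np.vstack([p[0] for p in cand_parts])
        cand_y = np.concatenate([p[1] for p in cand_parts])
        cand_r = np.concatenate([p[2] for p in cand_parts])
        cand_ids = np.concatenate([p[3] for p in cand_parts])

        sample_rng = stage_rng(config.seed, f"training_h{h2}", replicate)
        panel_rng = stage_rng(config.seed, "panel_subset", replicate)
        panel_loci = {p: _panel_markers(spec, p, panel_rng) for p in config.panels}
        for tp in config.training_sizes:
            pick = sample_rng.choice(len(cand_y), size=tp, replace=False)
            w = deregression_weights(h2, cand_r[pick], config.c_weight)
            ok = np.isfinite(w)
            for panel in config.panels:
                loci = panel_loci[panel]
                X_train = cand_X[pick][ok][:, loci]
                keep = filter_markers(X_train, config.min_train_maf)
                train = TrainingSet(
                    X=X_train[:, keep],
                    y_response=cand_y[pick][ok],
                    w=w[ok],
                    clone_ids=cand_ids[pick][ok],
                )
                bc = BayesCConfig(
                    pi=config.pi,
                    nu_a=config.nu_a,
                    n_iter=config.n_iter,
                    burn_in=config.burn_in,
                    c_weight=config.c_weight,
                    seed=stage_seed(config.seed, f"bayesc_h{h2}_tp{tp}_p{panel}", replicate),
                )
                res = run_bayesc(train, bc)
                gebv = predict_gebv(res, pred_pop.genotypes()[:, loci][:, keep])
                gs = select_top(
                    gebv, pred_tbv, pred_pop.ids, n=config.n_select, scheme="GS"
                )
                rows.append(
                    {
                        "replicate": replicate,
                        "h2": h2,
                        "training_size": tp,
                        "panel": panel,
                        "n_snps_used": len(keep),
                        "accuracy_gebv": gebv_accuracy(gebv, pred_tbv),
                        "accuracy_ebv": ebv_acc,
                        "gain_fs": fs.gain_per_generation,
                        "gain_gs": gs.gain_per_generation,
                    }
                )
    return pd.DataFrame(rows)


def summarize(cells: pd.DataFrame) -> pd.DataFrame:
    """Replicate means with standard errors for every factorial cell."""
    metrics = ["accuracy_gebv", "accuracy_ebv", "gain_fs", "gain_gs"]
    grp = cells.groupby(["h2", "training_size", "panel"])[metrics]
    mean = grp.mean().add_suffix("_mean")
    se = grp.sem().add_suffix("_se")
    return mean.join(se).reset_index()


def run_experiment(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """All replicates plus summary tables and export artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(config.to_dict(), outdir / "resolved_config.yaml")
    manifest = {"stages": [], "seed": config.seed}
    all_cells = []
    for rep in range(config.replicates):
        t0 = time.time()
        cells = run_replicate(config, rep)
        cells.to_csv(outdir / f"replicate_{rep}_cells.csv", index=False)
        all_cells.append(cells)
        manifest["stages"].append(
            {"replicate": rep, "seconds": round(time.time() - t0, 2)}
        )
    cells = pd.concat(all_cells, ignore_index=True)
    summary = summarize(cells)
    summary.to_csv(outdir / "summary.csv", index=False)

    # per-year and deployment renderings from the replicate-mean gains
    gains = (
        cells.groupby(["h2", "training_size"])[["gain_fs", "gain_gs"]]
        .mean()
        .reset_index()
        .rename(columns={"gain_fs": "FS", "gain_gs": "GS"})
    )
    gain_per_year_table(gains).to_csv(outdir / "gain_per_year.csv", index=False)
    deployment_table(gains).to_csv(outdir / "deployment_gain.csv", index=False)
    # reference rendering from the bundled worked-example gains
    deployment_table(example_gains()).to_csv(
        outdir / "deployment_gain_reference.csv", index=False
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary
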