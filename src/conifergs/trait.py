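"""Quantitative trait model: QTL effects, breeding values, phenotypes.

The trait is controlled by 350 bi-allelic QTL whose allele-substitution
effect magnitudes are gamma(shape 0.5, scale 26) draws with random sign,
rescaled by one constant so the realised additive variance in a reference
population equals sigma2_a (300, emulating DBH in mm or wood density in
kg/m^3). Non-additive genetic variation is modelled as a clone-level
deviation with variance 0.15 * sigma2_a = 45, shared by the ramets of a
clone. Narrow-sense heritability h2 refers to total phenotypic variance
sigma2_a + sigma2_d + sigma2_e, from which the residual variance is solved:
h2 = 0.5 -> sigma2_e = 255, h2 = 0.2 -> sigma2_e = 1155.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .population import Population

__all__ = [
    "TraitModel",
    "residual_variance",
    "sample_qtl_effects",
    "true_breeding_value",
    "simulate_phenotypes",
]


def residual_variance(h2: float, sigma2_a: float, sigma2_d: float) -> float:
    """Solve sigma2_e from h2 = sigma2_a / (sigma2_a + sigma2_d + sigma2_e)."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("heritability must lie in (0, 1)")
    s2e = sigma2_a / h2 - sigma2_a - sigma2_d
    if s2e <= 0:
        raise ValueError(f"h2={h2} implies non-positive residual variance")
    return s2e


@dataclass(frozen=True)
class TraitModel:
    qtl_effects: np.ndarray  # allele-substitution effects, trait units
    sigma2_a: float = 300.0
    h2: float = 0.5
    d_fraction: float = 0.15  # sigma2_d as a fraction of sigma2_a
    tbv_offset: float = 0.0  # reference-population mean of raw genotypic values
    sigma2_e_override: float | None = None  # e.g. 0.0 for noise-free phenotypes

    @property
    def sigma2_d(self) -> float:
        return self.d_fraction * self.sigma2_a

    @property
    def sigma2_e(self) -> float:
        if self.sigma2_e_override is not None:
            return self.sigma2_e_override
        return residual_variance(self.h2, self.sigma2_a, self.sigma2_d)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_effects)

    def with_h2(self, h2: float) -> "TraitModel":
        """Same genetic architecture, different heritability (residual only)."""
        return replace(self, h2=h2)


def sample_qtl_effects(
    qtl_genotypes: np.ndarray | Population,
    rng: np.random.Generator,
    n_qtl: int | None = None,
    shape: float = 0.50,
    scale: float = 26.0,
    target_variance: float = 300.0,
    h2: float = 0.5,
    d_fraction: float = 0.15,
    qtl_idx: np.ndarray | None = None,
) -> TraitModel:
    """Draw QTL effects and scale them to the target additive variance.

    Magnitudes are gamma(shape, scale) with signs +/- at probability 1/2
    (the gamma is positive; sign assignment is a modelling choice). A single
    multiplicative constant then sets the realised variance of breeding
    values over the reference population's clones to ``target_variance``
    exactly (in-sample, by construction). TBVs are centred on the reference
    mean, so the reference population has mean breeding value zero.
    """
    if isinstance(qtl_genotypes, Population):
        if qtl_idx is None:
            raise ValueError("pass qtl_idx when scaling on a Population")
        qtl_genotypes = qtl_genotypes.genotypes(qtl_idx)
    g = np.asarray(qtl_genotypes, dtype=float)
    if n_qtl is None:
        n_qtl = g.shape[1]
    mags = rng.gamma(shape, scale, size=n_qtl)
    signs = rng.choice([-1.0, 1.0], size=n_qtl)
    eff = mags * signs
    raw = g @ eff
    sd = raw.std(ddof=0)
    # guard against numerically-zero variance (e.g. all QTL monomorphic)
    if sd <= 1e-9 * max(1.0, abs(raw.mean())):
        raise ValueError("all QTL monomorphic in reference population; cannot scale")
    eff *= np.sqrt(target_variance) / sd
    raw = g @ eff
    return TraitModel(
        qtl_effects=eff,
        sigma2_a=target_variance,
        h2=h2,
        d_fraction=d_fraction,
        tbv_offset=float(raw.mean()),
    )


def true_breeding_value(qtl_genotypes: np.ndarray, trait: TraitModel) -> np.ndarray:
    """TBV = sum of QTL allele counts times effects, centred on the reference mean."""
    g = np.asarray(qtl_genotypes, dtype=float)
    return g @ trait.qtl_effects - trait.tbv_offset


def simulate_phenotypes(
    pop: Population,
    trait: TraitModel,
    n_ramets: int,
    rng: np.random.Generator,
    tbv: np.ndarray | None = None,
    qtl_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Ramet-level phenotype records.

    phenotype = TBV + clone non-additive deviation N(0, sigma2_d)
    + ramet residual N(0, sigma2_e); the decomposition columns satisfy the
    identity exactly. The non-additive deviation is shared by all ramets of
    a clone.
    """
    if tbv is None:
        if qtl_idx is None:
            raise ValueError("pass tbv or qtl_idx")
        tbv = true_breeding_value(pop.genotypes(qtl_idx), trait)
    n = pop.size
    sd_d = np.sqrt(trait.sigma2_d)
    sd_e = np.sqrt(trait.sigma2_e)
    nonadd = rng.normal(0.0, sd_d, size=n) if sd_d > 0 else np.zeros(n)
    resid = rng.normal(0.0, sd_e, size=(n, n_ramets)) if sd_e > 0 else np.zeros((n, n_ramets))
    tbv_rep = np.repeat(tbv, n_ramets)
    nonadd_rep = np.repeat(nonadd, n_ramets)
    resid_flat = resid.reshape(-1)
    return pd.DataFrame(
        {
            "clone_id": np.repeat(pop.ids, n_ramets),
            "ramet_index": np.tile(np.arange(1, n_ramets + 1), n),
            "phenotype": tbv_rep + nonadd_rep + resid_flat,
            "tbv": tbv_rep,
            "nonadditive_effect": nonadd_rep,
            "residual": resid_flat,
        }
    )
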