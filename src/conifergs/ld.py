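"""Linkage disequilibrium: pairwise R^2 and its decay with map distance.

R^2 between two loci is the squared correlation of allele indicators over
haplotypes, equivalently D^2 / (P_A P_a P_B P_b) with D = P_AB - P_A P_B.
The burn-in phases of the simulator are designed so that R^2 decays rapidly
within ~1 cM, emulating the low, short-range LD of conifer genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .population import Population

__all__ = ["LDEstimate", "LDDecay", "compute_ld_r2", "r2_matrix", "ld_decay_profile"]


@dataclass(frozen=True)
class LDEstimate:
    r_squared: float
    D_ld: float
    P_AB: float
    P_A: float
    P_B: float
    pair_distance: float = float("nan")

    @property
    def P_a(self) -> float:
        return 1.0 - self.P_A

    @property
    def P_b(self) -> float:
        return 1.0 - self.P_B


def compute_ld_r2(p_ab: float, p_a: float, p_b: float, pair_distance: float = float("nan")) -> LDEstimate:
    """LD from observed haplotype frequency P_AB and allele frequencies P_A, P_B.

    Raises on a monomorphic locus (any allele frequency zero), where R^2 is
    undefined; callers exclude such pairs from averages.
    """
    for name, p in (("P_AB", p_ab), ("P_A", p_a), ("P_B", p_b)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0.0:
        raise ValueError("monomorphic locus: R^2 undefined")
    d = p_ab - p_a * p_b
    r2 = d * d / denom
    return LDEstimate(r_squared=float(r2), D_ld=float(d), P_AB=p_ab, P_A=p_a, P_B=p_b,
                      pair_distance=pair_distance)


def r2_matrix(haplotype_alleles: np.ndarray) -> np.ndarray:
    """Pairwise R^2 over loci from a (haplotypes x loci) 0/1 matrix.

    Monomorphic loci yield NaN rows/columns (flagged, never averaged).
    The squared Pearson correlation of allele indicators equals the
    haplotype-frequency formula exactly.
    """
    h = np.asarray(haplotype_alleles, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(h, rowvar=False)
    return c * c


@dataclass
class LDDecay:
    bins: pd.DataFrame  # columns: bin_left, bin_right, mean_r2 (NaN if empty), n_pairs
    adjacent_mean_r2: float  # mean R^2 over adjacent polymorphic marker pairs
    n_monomorphic: int


def ld_decay_profile(
    pop: Population,
    spec: GenomeSpec,
    max_distance: float = 10.0,
    bin_width: float = 0.5,
) -> LDDecay:
    """Binned mean R^2 by pair distance, plus the adjacent-pair LD summary.

    Uses all polymorphic marker pairs within ``max_distance`` cM. Empty bins
    are reported with NaN mean (missing, not zero).
    """
    markers = spec.marker_idx
    pos = spec.marker_positions
    hap = pop.haplotypes[:, :, markers].reshape(-1, len(markers))
    poly = hap.std(axis=0) > 0
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic markers")
    r2 = r2_matrix(hap[:, poly])
    p = pos[poly]
    iu, ju = np.triu_indices(len(p), k=1)
    dist = p[ju] - p[iu]
    keep = dist <= max_distance
    dist, vals = dist[keep], r2[iu[keep], ju[keep]]
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    which = np.digitize(dist, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "mean_r2": float(vals[sel].mean()) if sel.any() else float("nan"),
                "n_pairs": int(sel.sum()),
            }
        )
    adj = r2[np.arange(len(p) - 1), np.arange(1, len(p))]
    return LDDecay(
        bins=pd.DataFrame(rows),
        adjacent_mean_r2=float(np.nanmean(adj)),
        n_monomorphic=int((~poly).sum()),
    )
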