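"""Population container: haplotypes, pedigree links, sexes, clone identity.

One row per *clone* (distinct genotype). Ramets of a clone are vegetative
copies with identical haplotypes, so they are represented as repeated
phenotype records (see :mod:`conifergs.trait`), not as repeated genotype
rows. ``clone_id`` equals the individual id; ids are globally unique across
the phases of one simulation run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["Population", "FOUNDER"]

FOUNDER = -1  # sire/dam code for individuals without recorded parents


@dataclass
class Population:
    ids: np.ndarray  # (n,) int64
    haplotypes: np.ndarray  # (n, 2, L) uint8
    sire: np.ndarray  # (n,) int64, FOUNDER if unrecorded
    dam: np.ndarray  # (n,) int64
    sex: np.ndarray  # (n,) uint8: 0 female, 1 male
    generation: int = 0
    phase: str = "historical"

    def __post_init__(self):
        n = len(self.ids)
        for name in ("haplotypes", "sire", "dam", "sex"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch with ids")

    @property
    def size(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def genotypes(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Allele counts 0/1/2 per clone, optionally restricted to loci."""
        g = self.haplotypes.sum(axis=1, dtype=np.int16)
        return g if loci is None else g[:, loci]

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        return self.genotypes(loci).mean(axis=0) / 2.0

    def subset(self, index: np.ndarray) -> "Population":
        return replace(
            self,
            ids=self.ids[index],
            haplotypes=self.haplotypes[index],
            sire=self.sire[index],
            dam=self.dam[index],
            sex=self.sex[index],
        )

    def pedigree_frame(self, n_ramets: int | None = None) -> pd.DataFrame:
        """Pedigree table; with ``n_ramets`` one row per ramet."""
        base = pd.DataFrame(
            {
                "id": self.ids,
                "sire": self.sire,
                "dam": self.dam,
                "sex": np.where(self.sex == 0, "F", "M"),
                "generation": self.generation,
                "clone_id": self.ids,
            }
        )
        if n_ramets is None:
            base["ramet_index"] = 1
            return base
        rep = base.loc[base.index.repeat(n_ramets)].reset_index(drop=True)
        rep["ramet_index"] = np.tile(np.arange(1, n_ramets + 1), self.size)
        return rep
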