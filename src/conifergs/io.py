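"""File I/O: genotype (VCF, PLINK), pedigree/phenotype/EBV/effects CSV, config.

cM positions are scaled to integer base pairs at 1 cM = 1,000,000 bp on one
pseudo-chromosome. Writers emit plain text; the VCF is VCFv4.2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeSpec
from .population import Population

__all__ = [
    "write_vcf",
    "write_plink",
    "write_pedigree_csv",
    "write_phenotypes_csv",
    "load_config",
    "dump_config",
]

BP_PER_CM = 1_000_000


def _marker_table(spec: GenomeSpec) -> pd.DataFrame:
    pos_cm = spec.marker_positions
    return pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(len(pos_cm))],
            "pos_bp": np.maximum(1, (pos_cm * BP_PER_CM).round().astype(int)),
        }
    )


def write_vcf(path: str | Path, pop: Population, spec: GenomeSpec) -> Path:
    """Phased marker genotypes as a plain-text VCFv4.2 file."""
    path = Path(path)
    markers = _marker_table(spec)
    hap = pop.haplotypes[:, :, spec.marker_idx]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={int(spec.chromosome_length * BP_PER_CM)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"clone{i}" for i in pop.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(len(markers)):
            gts = "\t".join(f"{hap[i, 0, j]}|{hap[i, 1, j]}" for i in range(pop.size))
            fh.write(
                f"chr1\t{markers.pos_bp[j]}\t{markers.id[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def write_plink(prefix: str | Path, pop: Population, spec: GenomeSpec) -> tuple[Path, Path]:
    """PLINK-style .ped/.map pair (alleles A/G, one pseudo-chromosome)."""
    prefix = Path(prefix)
    markers = _marker_table(spec)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for j in range(len(markers)):
            fh.write(f"1 {markers.id[j]} {spec.marker_positions[j]:.6f} {markers.pos_bp[j]}\n")
    allele = np.array(["A", "G"])
    hap = pop.haplotypes[:, :, spec.marker_idx]
    with open(ped_path, "w") as fh:
        for i in range(pop.size):
            sire = pop.sire[i] if pop.sire[i] >= 0 else 0
            dam = pop.dam[i] if pop.dam[i] >= 0 else 0
            sex = 2 if pop.sex[i] == 0 else 1  # PLINK: 1=male, 2=female
            geno = " ".join(
                f"{allele[hap[i, 0, j]]} {allele[hap[i, 1, j]]}" for j in range(hap.shape[2])
            )
            fh.write(f"FAM1 {pop.ids[i]} {sire} {dam} {sex} -9 {geno}\n")
    return ped_path, map_path


def write_pedigree_csv(path: str | Path, pedigree: pd.DataFrame) -> Path:
    path = Path(path)
    cols = ["id", "sire", "dam", "sex", "generation", "clone_id", "ramet_index"]
    pedigree[cols].to_csv(path, index=False)
    return path


def write_phenotypes_csv(path: str | Path, phenotypes: pd.DataFrame, blind: bool = False) -> Path:
    """Phenotype export; ``blind=True`` withholds the simulation-truth TBV."""
    path = Path(path)
    cols = ["clone_id", "ramet_index", "phenotype"] + ([] if blind else ["tbv"])
    phenotypes[cols].to_csv(path, index=False)
    return path


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return path
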