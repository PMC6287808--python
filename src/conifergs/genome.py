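"""Genome model: marker/QTL map, founder haplotypes, meiosis and mutation.

The simulated genome is a single chromosome of 150 cM carrying a panel of
neutral SNP markers (600-8,000, emulating 7K-90K genome-wide densities on a
12-chromosome conifer genome) and 350 bi-allelic QTL. Meiosis follows the
Haldane model: crossover count per gamete is Poisson with mean equal to the
map length in Morgans, crossover points uniform on the map, no interference.
Mutation is recurrent (allele flip) at a per-locus per-gamete rate and is
active only in the burn-in phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeSpec",
    "sample_founder_haplotypes",
    "make_gametes",
    "select_panel",
    "recombine",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Map and locus layout of the simulated chromosome.

    Loci are stored sorted by position; ``marker_idx`` / ``qtl_idx`` index
    into that merged order. Marker and QTL position sets are disjoint.
    """

    chromosome_length: float = 150.0  # cM
    marker_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    qtl_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    mutation_rate: float = 1e-5  # per locus per gamete
    min_initial_maf: float = 0.10

    def __post_init__(self):
        m = np.sort(np.asarray(self.marker_positions, dtype=float))
        q = np.sort(np.asarray(self.qtl_positions, dtype=float))
        for arr, label in ((m, "marker"), (q, "QTL")):
            if arr.size and (arr.min() < 0 or arr.max() > self.chromosome_length):
                raise ValueError(f"{label} positions outside [0, {self.chromosome_length}] cM")
        if np.intersect1d(m, q).size:
            raise ValueError("marker and QTL positions must be disjoint")
        object.__setattr__(self, "marker_positions", m)
        object.__setattr__(self, "qtl_positions", q)

    @property
    def n_markers(self) -> int:
        return self.marker_positions.size

    @property
    def n_qtl(self) -> int:
        return self.qtl_positions.size

    @property
    def n_loci(self) -> int:
        return self.n_markers + self.n_qtl

    @property
    def positions(self) -> np.ndarray:
        """All locus positions (cM), sorted."""
        return np.sort(np.concatenate([self.marker_positions, self.qtl_positions]))

    @property
    def marker_idx(self) -> np.ndarray:
        """Indices of markers in the merged, sorted locus order."""
        pos = self.positions
        return np.searchsorted(pos, self.marker_positions)

    @property
    def qtl_idx(self) -> np.ndarray:
        pos = self.positions
        return np.searchsorted(pos, self.qtl_positions)

    @classmethod
    def random(
        cls,
        n_markers: int,
        n_qtl: int = 350,
        chromosome_length: float = 150.0,
        rng: np.random.Generator | None = None,
        **kwargs,
    ) -> "GenomeSpec":
        """Draw marker and QTL positions uniformly on the map (disjoint)."""
        rng = np.random.default_rng() if rng is None else rng
        while True:
            pos = rng.uniform(0.0, chromosome_length, size=n_markers + n_qtl)
            if np.unique(pos).size == pos.size:
                break
        pos = rng.permutation(pos)
        return cls(
            chromosome_length=chromosome_length,
            marker_positions=pos[:n_markers],
            qtl_positions=pos[n_markers:],
            **kwargs,
        )


def sample_founder_haplotypes(
    spec: GenomeSpec, n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """Founder haplotypes at linkage equilibrium, shape (n, 2, n_loci), uint8.

    Marker allele frequencies are uniform on (min_initial_maf, 1 -
    min_initial_maf), so founder MAF exceeds the panel threshold; QTL
    frequencies are uniform on (0.05, 0.95). Loci are independent at time
    zero; LD accrues through the burn-in drift phases.
    """
    freqs = np.empty(spec.n_loci)
    freqs[spec.marker_idx] = rng.uniform(
        spec.min_initial_maf, 1.0 - spec.min_initial_maf, size=spec.n_markers
    )
    freqs[spec.qtl_idx] = rng.uniform(0.05, 0.95, size=spec.n_qtl)
    hap = (rng.random((n_individuals, 2, spec.n_loci)) < freqs).astype(np.uint8)
    return hap


def make_gametes(
    parent_haplotypes: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
    map_length: float | None = None,
) -> np.ndarray:
    """Form one gamete per parent row by Haldane meiosis, vectorised.

    parent_haplotypes: (G, 2, L) uint8 — one meiosis per row.
    Returns (G, L) uint8 gametes. Crossover counts ~ Poisson(map_length/100),
    points uniform on the map; the source haplotype at each locus is the
    parity of the crossover count to its left plus a random start strand.
    Recurrent mutation flips alleles at ``mutation_rate`` per locus per
    gamete. ``map_length`` defaults to the last locus position.
    """
    g, _, n_loci = parent_haplotypes.shape
    if map_length is None:
        map_length = float(positions.max()) if n_loci else 0.0
    n_xo = rng.poisson(map_length / 100.0, size=g)
    kmax = int(n_xo.max()) if g else 0
    start = rng.integers(0, 2, size=g)
    if kmax == 0:
        source = np.broadcast_to(start[:, None], (g, n_loci))
    else:
        # Padded crossover points; padding beyond each gamete's count sits
        # past the map end so it never flips parity.
        pts = rng.uniform(0.0, map_length, size=(g, kmax))
        pad = np.arange(kmax) >= n_xo[:, None]
        pts[pad] = np.inf
        pts.sort(axis=1)
        crossings = np.searchsorted(positions, pts.T, side="left")
        # crossings[k, g] = number of loci to the left of crossover k
        counts = np.zeros((g, n_loci + 1), dtype=np.int16)
        for k in range(kmax):
            np.add.at(counts, (np.arange(g), crossings[k]), 1)
        n_left = np.cumsum(counts[:, :-1], axis=1)
        source = (start[:, None] + n_left) % 2
    gam = np.take_along_axis(
        parent_haplotypes, source[:, None, :].astype(np.intp), axis=1
    )[:, 0, :]
    gam = np.ascontiguousarray(gam)
    if mutation_rate > 0.0:
        n_mut = rng.binomial(g * n_loci, mutation_rate)
        if n_mut:
            flat = rng.integers(0, g * n_loci, size=n_mut)
            gam.reshape(-1)[flat] ^= 1
    return gam


def select_panel(
    haplotypes: np.ndarray,
    spec: GenomeSpec,
    n_markers: int,
    n_qtl: int,
    rng: np.random.Generator,
    marker_maf: float | None = None,
    qtl_maf: float = 0.01,
) -> tuple["GenomeSpec", np.ndarray]:
    """Choose the working marker panel and QTL set after burn-in.

    Mirrors how forward simulators assemble SNP panels: the drift phases run
    on a surplus of candidate loci, and the panel is drawn from loci still
    segregating in the final burn-in population — markers with MAF above
    the panel floor (default ``spec.min_initial_maf``), QTL above
    ``qtl_maf``. Returns the reduced genome and the column-subsetted
    haplotypes (same individual order).
    """
    if marker_maf is None:
        marker_maf = spec.min_initial_maf
    freq = haplotypes.reshape(-1, spec.n_loci).mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    ok_m = spec.marker_idx[maf[spec.marker_idx] > marker_maf]
    ok_q = spec.qtl_idx[maf[spec.qtl_idx] > qtl_maf]
    if len(ok_m) < n_markers:
        raise ValueError(
            f"only {len(ok_m)} candidate markers exceed MAF {marker_maf}; "
            f"need {n_markers} — increase the candidate surplus"
        )
    if len(ok_q) < n_qtl:
        raise ValueError(
            f"only {len(ok_q)} segregating candidate QTL; need {n_qtl}"
        )
    pos = spec.positions
    markers = np.sort(rng.choice(ok_m, size=n_markers, replace=False))
    qtl = np.sort(rng.choice(ok_q, size=n_qtl, replace=False))
    keep = np.sort(np.concatenate([markers, qtl]))
    new_spec = GenomeSpec(
        chromosome_length=spec.chromosome_length,
        marker_positions=pos[markers],
        qtl_positions=pos[qtl],
        mutation_rate=spec.mutation_rate,
        min_initial_maf=spec.min_initial_maf,
    )
    return new_spec, np.ascontiguousarray(haplotypes[:, :, keep])


def recombine(
    parent_haplotypes: np.ndarray, spec: GenomeSpec, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from one parent's haplotype pair (2, L) -> (L,)."""
    pair = np.asarray(parent_haplotypes, dtype=np.uint8)
    if pair.shape != (2, spec.n_loci):
        raise ValueError(f"expected haplotype pair of shape (2, {spec.n_loci})")
    return make_gametes(pair[None], spec.positions, rng, map_length=spec.chromosome_length)[0]
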