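# Methods

`conifergs` simulates a conifer breeding program end to end — genome,
population history, field testing, pedigree BLUP, BayesC genomic
prediction, truncation selection and multi-rotation deployment — to
quantify what genomic selection (GS) buys over conventional forward
selection (FS) per generation, per year, and per hectare of deployed
forest. This note records the model, the parameter choices, and the
numerical and design decisions a maintainer would want to know.

## Genome and population history

The genome is one 150 cM chromosome. SNP panels of 600–8,000 markers stand
in for 7K–90K genome-wide densities on a ~1,800 cM, 12-chromosome conifer
genome; 350 bi-allelic QTL control the trait. Meiosis is Haldane: crossover
counts Poisson with mean 1.5 (the map length in Morgans), crossover points
uniform, no interference. Recurrent mutation (allele flip) runs at 1e-5 per
locus per gamete during the burn-in phases and is off in the breeding
phase.

Population history has three phases:

1. **Historical** — 500 generations, 300 female + 300 male parents, constant
   size 1,000, random union of gametes, no selection.
2. **Extended** — 10 generations, 100 + 100 parents, constant size 500.
3. **Recent** — 10 discrete breeding generations: 32 + 32 parents selected
   on BLUP EBVs, circular mating (parents ringed alternating female/male by
   EBV rank, each mated to its two neighbours → 64 crosses, each parent
   used exactly twice), 15 offspring per family (960 clones), 4 ramets per
   clone, no mutation.

Founder haplotypes start at linkage equilibrium with marker frequencies
uniform on (0.10, 0.90); LD accrues through drift. The burn-in runs on a
2.5× surplus of candidate loci, and the working panel is selected **after**
burn-in from loci still segregating (markers with MAF > 0.10, QTL
segregating) — the way forward simulators assemble panels, and the only
reading consistent with ~96% of panel markers surviving to GEBV derivation.
With the 600-SNP panel this yields adjacent-pair mean R² ≈ 0.17–0.22,
matching the low, rapidly-decaying LD reported for conifer populations.

Conifers are monoecious, but parents are sexed in this design: sex labels
are assigned 50:50 at birth and selection operates within label.
Generation-1 parents of the recent phase are drawn at random from the final
extended generation (no phenotypes exist yet); EBV-based selection starts
at generation 2.

## Trait model

QTL substitution-effect magnitudes are gamma(shape 0.5, scale 26) with
random sign (the gamma is positive; the sign convention is ours), rescaled
by a single constant so the variance of breeding values over the final
burn-in population equals σ²_a = 300 exactly (matching typical additive
variances for diameter at breast height in mm, and wood density in kg/m³).
TBVs are centred on that reference population's mean.

Phenotype of ramet *j* of clone *i*:

    y_ij = TBV_i + d_i + e_ij,   d_i ~ N(0, σ²_d),  e_ij ~ N(0, σ²_e)

with σ²_d = 0.15 σ²_a = 45 shared by a clone's ramets. Narrow-sense h² is
defined against total phenotypic variance σ²_a + σ²_d + σ²_e, so σ²_e is
solved from h²: 255 at h² = 0.5, 1,155 at h² = 0.2. The two study traits
share one genetic architecture and differ only in residual noise; each h²
scenario runs its own recent phase, selected on its own EBVs.

## Pedigree BLUP

Evaluation fits y = 1μ + Z_a a + Z_d d + e with var(a) = A σ²_a (numerator
relationship matrix, tabular method with full inbreeding recursion),
var(d) = I σ²_d over clones, var(e) = I σ²_e. Variance components are fixed
at simulation truth (no REML). Because d is clone-level with D = I, the
system collapses exactly onto clone means: ȳ_i = μ + a_i + ε_i with
var(ε_i) = σ²_d + σ²_e/n_i; the collapsed MME yields identical EBVs and
PEV accuracies at half the dimension (property-tested against the full
system and against direct GLS).

Each breeding generation is evaluated from a sliding window of records —
the current clones plus the previous generation's (which contains all
parents) — with A built over the window's full recent-phase lineage and
marginalised to the recorded clones (exact for BLUP; ancestors carry no
records). Recent-phase founders are treated as an unrelated base; a full
cumulative multi-generation evaluation would be the ideal but scales as the
cube of ~10,000 clones and is out of budget. Per-clone accuracy is
r_i = sqrt(1 − PEV_i/(A_ii σ²_a)); realized accuracy (the reported one) is
the Pearson correlation of EBV with TBV.

EBVs within an evaluation are deviations from the generation mean. For
cross-generation training sets the package tracks a per-generation trend
offset — advanced each cycle by the realised selection differential on
EBVs (offspring mean ≈ midparent) — and trains BayesC on the
offset-adjusted ("absolute") EBVs. Without this, pooling generations 4–8
as training data erases the genetic-trend signal the genotypes carry and
collapses prediction accuracy (we measured it; it roughly halves).

## BayesC

SNP effects are estimated from the training clones' EBVs, weighted by
Garrick-style weights w_i = [(1−h²)/h²]/[c + (1−r_i²)/r_i²] entering the
sampler as residual-variance scalers (Var(e_i) = σ²_e/w_i), with c = 0.5
as the conventional value for the genetic-variance fraction not captured by
markers (the study leaves it unstated; it is configurable). A record with
r_i = 0 is excluded; the degenerate r_i = 1, c = 0 corner is capped at the
maximal weight (1−h²)/h².

The prior: each SNP has zero effect with probability π = 0.95; nonzero
effects share a variance σ²_snp with a scaled inverse-χ² prior, ν_a = 4.2
and scale set from the expected per-SNP variance var(y)/((1−π)·Σ_j 2p_j q_j)
at chain start. The residual variance gets a weak scaled inverse-χ²
(ν_e = 4). Gibbs updates cycle μ, per-SNP indicator+effect (marginal
Bayes-factor form), σ²_snp and σ²_e; markers monomorphic or with training
MAF < 0.01 are dropped beforehand. Chains are bitwise reproducible given a
seed (numba kernel with its own seeded RNG). Default chain lengths: 40,000
iterations at full scale (10% burn-in), 2,000 in the desk preset, 10,000 in
the acceptance script — accuracy estimates are stable well before 40,000.

GEBV = X'â centred on the training mean; reported accuracy is the
correlation between GEBV and TBV in the 960-clone prediction population
(generation 10). Training clones are drawn uniformly without replacement
from generations 4–8.

## Gain and deployment accounting

Nine of 960 clones (1%) are selected on EBV (FS) or GEBV (GS); gain per
generation is the selected clones' mean TBV minus the candidate mean —
always measured on true values, never the criterion. Gain per year divides
by the generation interval: FS 17, FSCA 14, GS 9, GSTG 7. FSCA and GSTG
share FS's and GS's per-generation gain engines; they differ only in
calendar. In the per-year table the "benefit over FS" percentages are
computed from the rates rounded to 2 decimals, which is how the published
versions of such tables are internally consistent (e.g. 1.58/1.13 → 40%,
where unrounded arithmetic gives 41%).

Deployment: 8 back-to-back rotations of 25 years, starting with the
breeding program. Selection in cycle i happens at B_i = T_s + G(i−1);
material is usable in the T_d-th year counted inclusively (seedlings:
D_i = B_i + T_d − 1; clones via somatic embryogenesis: T_d = 1, the
selection year). Each rotation start deploys the newest available cycle;
cycle-i material carries merit i·g. This inclusive-year convention is the
unique simple one reproducing the published totals (37g for FS seedlings,
72g for GS seedlings) and percentages (8.11 / 21.62 / 24.32), and it is
locked by regression tests plus an independent year-by-year simulation
oracle. Two published inconsistencies are resolved deliberately: the
cycle-merit formula "g(b_i − 1)" contradicts the worked example (merit i·g
is used), and the GS-clone calendar's printed 7-year crossing-to-selection
contradicts its own deployment percentages (an effective 9 is used).

## What the generator does and does not emulate

The synthetic world captures: drift-generated LD with realistic decay,
panel ascertainment, family structure under circular mating, clone/ramet
phenotype replication, selection response and its feedback on variance.
It does not model: multiple chromosomes (one 150 cM chromosome stands in),
genotype-by-environment interaction, dominance/epistasis at QTL (the
non-additive term is a clone-level deviation), missing data, or genotyping
error. A green stochastic test therefore establishes internal consistency
of the method chain at reduced scale, not field-level forecast accuracy.

One emergent property deserves note: recurrent truncation selection on an
exhaustible QTL architecture depletes additive variance across the 10
breeding generations (strongly so for the accurately-selected h² = 0.5
trait), so generation-10 accuracies and gains sit below what base-variance
arithmetic would suggest. The published study's constant per-row EBV
accuracies suggest its evaluation did not experience (or did not measure)
this depletion; ours is reported as simulated.

## Numerical choices

- Relationship matrices are built by the tabular method (O(n²), exact
  inbreeding); MME solved by Cholesky, PEVs from the factor inverse.
- Ties in truncation selection break by clone id for determinism.
- All randomness flows from one master seed through named, CRC-tagged
  stage streams (`_streams.py`); replicate r of stage s is independent of
  every other (stage, replicate) pair.
- Degenerate inputs raise: monomorphic LD pairs, zero-variance accuracy
  correlations, cyclic/unordered pedigrees, singular MME, diverged chains
  (reported with the iteration index).
- The desk preset (100-generation burn-in, ≤1,200-SNP panels, training
  ≤500, 2,000-iteration chains) exists so the full factorial runs in
  minutes; the full preset mirrors the study design.
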