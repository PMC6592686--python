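# Methods

This note documents the models implemented in `cenhap`, the parameter
choices that matter, and what the synthetic-data tests do and do not
establish about real data.

## The setting

Crossing over is suppressed in and around centromeric α-satellite
arrays, so the SNPs flanking a centromeric assembly gap are inherited as
extended haplotypes (cenhaps) whose genealogy is essentially that of a
single non-recombining locus. The package's components mirror the
stages of a cenhap study: clean the phased calls, cluster haplotypes,
quantify archaic allele sharing, date lineages from coding divergence,
and relate cenhap genotypes to array-size estimates.

## Linkage disequilibrium

LD between two biallelic sites is summarized by the Pearson χ² statistic
for independence on the 2×2 gamete table (1 df, no continuity
correction), computed in closed form,
χ² = H(n₀₀n₁₁ − n₀₁n₁₀)²/(r₁r₂c₁c₂), with the p-value from the χ²(1)
upper tail. Pairs with a zero marginal (a monomorphic column) are
reported as undefined rather than given an arbitrary statistic.
−log₁₀(p) is capped at the float64 tail (~308); the cap is recorded in
the output's metadata rather than pretending p = 0.

## The 4gt_dco filter

Under an infinite-sites model with no exchange, any two SNP columns show
at most three of the four gametotypes 00/01/10/11. A genotyping or
imputation error at one haplotype creates an allele island that — when
placed against informative neighbours — completes the fourth gamete on
*both* sides, while a genuine crossover completes it on one side only.
The filter therefore tests each focal SNP against pairs of flanking
SNPs (one from each side): a pair *fails* when the focal SNP shows four
gametes with **each** flank while the flanks show at most three gametes
between themselves. This both-sides (AND) rule is what distinguishes a
double-crossover-like island from ordinary recombination; the package
also exposes `or` and `xor` variants via `FilterConfig.flank_rule` for
comparison, and measurements on the error simulations show the `or`
variant removes several times more clean sites at equal recall.

Mechanics, all configurable:

- Sweep direction 5′→3′; windows are the nearest `half_window`
  *surviving* SNPs on each side (fewer near edges; a focal SNP with an
  empty side is never removed). All left×right combinations are tested.
- A focal SNP is removed as soon as its failing-pair count exceeds
  `tolerance` (strictly greater, so `tolerance=0` permits zero
  failures); removal is immediate, so downstream windows re-form over
  the surviving set.
- The schedule repeats at half-windows 10, 20, 30, 40, threading the
  surviving set between passes.

A deliberately naive triple-loop restatement
(`fourgt_dco_reference`) is kept alongside the vectorized production
path and the two are asserted equal on random matrices; pairwise gamete
tables are memoized in the reference, which is safe because removing a
column never changes the table of another pair.

Performance on scattered errors (200 haplotypes × 1000 SNPs from a
recombination-free genealogy, 0.3% per-allele flips — conditions under
which ~46% of columns carry at least one error): recall of error-bearing
sites is ~75–85% at tolerance 0, but 9–16% of clean sites are also
removed. The false positives arise when two error-bearing flanks each
complete a fourth gamete with a clean focal SNP while remaining mutually
consistent, and they carry small failing-pair counts (1–3) compared with
tens-to-hundreds for true errors — which is precisely why a tolerance of
3 is the recommended production setting for autosomes (clean-site
removal drops to ~6–8%). Scattered-error precision at tolerance 0 is a
known limitation of presence-based four-gamete screening and is asserted
honestly in the acceptance suite.

## Cenhap clustering

Haplotypes are clustered by UPGMA (average linkage) on raw hamming
mismatch counts over the central SNP subset flanking the gap. The
production path delegates the agglomeration to
`scipy.cluster.hierarchy.linkage(method="average")` (needed for
~5000-leaf inputs); node heights are merge distance / 2, so the tree is
ultrametric in units of mismatches-per-pair/2, the convention the TMRCA
scaling consumes. A naive O(n³) UPGMA with lexicographic tie-breaking
(`upgma_reference`) serves as an independent cross-check; equivalence is
asserted on continuous (tie-free) random matrices, and scipy's
deterministic ordering governs ties in production. Cuts at a height or
a group count give the cenhap partition; labels are canonicalized by
decreasing group size (ties by smallest member id) so the partition is
invariant to input order. Nested re-cuts re-cluster a named group's
distance submatrix — equivalent in spirit to cutting its subtree at a
lower height and simpler to specify.

Apparent inter-cenhap recombinants are not defined operationally in the
literature; the package's rule (flagged as such in output metadata)
clusters the left and right flanks separately into k groups, pairs each
left group with its majority right group, and flags haplotypes whose own
right group disagrees. Downstream divergence/TMRCA analyses drop the
flagged haplotypes when more than 10 are observed.

Unphased diploid genotypes (e.g. a reference individual's calls) are
placed by counting, against every phased individual, sites with
two-allele mismatches (0/0 vs 1/1), one-allele mismatches (hom vs het)
and matches; the individual minimizing total mismatching alleles
provides the diploid's most probable cenhap genotype.

## Archaic affinity

Each usable site is polarized by the outgroup allele (derived =
different from chimpanzee) and each haplotype allele is classified
against each archaic source as DM, DN, AM or AN (archaic
derived/ancestral × haplotype match/non-match). Usability requires
defined single-base outgroup and archaic states, with the outgroup
allele equal to REF or ALT; archaic states come from a homozygous
table, heterozygous or missing archaic calls being unusable. For every
haplotype DM+DN+AM+AN equals the usable site count — asserted always.
Cenhap summaries report group means with normal-approximation 95% CIs
(mean ± 1.96 SE; groups of size <2 carry NaN CIs, and the CI method is
recorded in metadata), the ratios DM/(DM+DN) and DM/(DM+AN) computed
from group means, and log₂(count+1) display columns.

## Coding divergence, diversity and TMRCAs

Synonymous/nonsynonymous sites and differences follow Nei–Gojobori
method I: per codon position the synonymous fraction of the three
possible single-base changes (changes to stops count as nonsynonymous;
alignments containing in-frame stops are rejected, never edited);
multi-difference codons resolved by averaging over the orderings of
single steps, excluding pathways through stop codons and falling back to
all pathways in the rare case every pathway is blocked. dS and dN apply
the Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3); p ≥ 3/4 is flagged
saturated. Diversity π_s/π_n is the average pairwise *uncorrected*
proportion (expected heterozygosity), following convention. Confidence
intervals across genes use the bias-corrected (BC) percentile bootstrap
(z₀ correction, no acceleration term).

TMRCAs are read off UPGMA node heights on synonymous divergence,
calibrated so the human–outgroup node sits at 6.5 MY. Because per-gene
topologies differ under noise, the combined tree is built from the
cross-gene mean dS matrix, and each node of that topology is dated per
gene as `calibration × (between-clade mean dS/2) / (gene's
group-to-outgroup mean dS/2)`; the reported age is the across-gene mean
with ±2 SD bands from the across-gene spread. Genes with zero outgroup
divergence are excluded with a warning. A divergence-ratio shortcut
(`tmrca_by_ratio`) scales an anchored TMRCA linearly, e.g. a lineage
twice as diverged as a 575 KY anchor dates to 1.15 MY.

Amino-acid replacements on a lineage are counted per gene as codon
columns where a group-internal codon at frequency ≥90% encodes a
different amino acid than the consensus of all other groups (the
assignment rule is a package choice; the threshold is configurable).

## Array sizes

Stage 1 divides each chromosome's centromeric read count by the sample's
mean coverage over chr1 unique regions (removing depth); stage 2 divides
by the sample's sum of stage-1 sizes over chromosomes (absorbing
library/technology batch effects — the motivation is documented, no
explicit batch covariates are modeled). Stage-2 proportions sum to 1
per sample by construction. Summaries are ecdfs and means by cenhap
genotype; on chrX, female two-array values are multiplied by 0.5 to plot
with hemizygous males. Stage-1 estimates in the lowest decile carry a
warning flag: small estimates may reflect divergence from the CEN
reference model rather than a truly small array, and no correction is
attempted.

## Synthetic data: what it emulates

The generator realizes the structure the analyses assume: a single
non-recombining central locus (structured Kingman coalescent) with an
archaic population, optional introgression (tips join the archaic
population at the admixture time), two archaic sample tips (NEA, DEN)
and an outgroup tip at the calibration age; infinite-sites mutations
placed on branches in proportion to length; crossovers confined to
flanks by splicing donor haplotypes outward from a breakpoint;
independent per-allele flips for genotyping error; contiguous donor
tracts for gene conversion; codon sequences evolved along the same
genealogy (uniform point mutations, stop-creating changes discarded,
nonsynonymous changes accepted with probability ω); Poisson read counts
for array sizes. Identical seeds give bit-identical outputs.

Default study conditions, chosen once: 200 haplotypes; modern diploid
N = 3000 and archaic N = 300, so the 575 KY archaic split is
genealogically deep relative to modern diversity (modern expected TMRCA
4N·29 ≈ 0.35 MY < 0.575 MY), matching the basal position archaic cenhaps
occupy in real data; admixture at 50 KY; introgression fraction 5%;
genotyping error 0.3% per allele; generation time 29 y; calibration
6.5 MY. For TMRCA recovery studies the three-lineage generator uses
N = 500 within groups (ancestral coalescence then biases node depths by
only ~2N ≈ 29 KY) with 12 genes of 300 codons at mutation rate 3×10⁻⁷
per site per generation — chosen so each gene carries ~25–30 synonymous
differences to the outgroup, the information content of the multi-kb CDS
sets used at full scale, on desk-scale gene lengths. Problem sizes in
the test and acceptance runs (e.g. 20 replicates, 1000-SNP matrices) are
the package's chosen standard study sizes.

What the simulations do **not** emulate: recurrent mutation, CpG rate
heterogeneity, imputation's correlated (haplotype-copying) error
structure — real imputation errors concentrate in specific bad SNPs,
which is friendlier to the 4gt filter than independent flips —
population growth and structure within the modern sample, selection,
and α-satellite sequence evolution itself (array sizes are latent true
values, not sequences). Passing tests therefore establish the
correctness and calibration of the algorithms under the stated model,
not the error profile of any particular cohort.

## Numerical choices

- All coordinates are 1-based inclusive at user surfaces (VCF
  convention) and 0-based half-open internally; masks merge on
  construction.
- Missing or unphased genotypes are hard errors naming the site; inputs
  are expected to be imputed and phased upstream.
- UPGMA ties: scipy's deterministic ordering (production),
  lexicographic smallest pair (reference); equivalence is asserted on
  tie-free inputs.
- Bootstrap z₀ uses the fraction of bootstrap means below the observed
  mean, clipped to (1/B, 1−1/B) to keep the normal quantile finite.
- The pipeline derives per-stage seeds from the run seed
  (seed·1000+offset, mod 2³¹−1) so stages are independently reproducible.

## Known limitations

- 4gt_dco precision at tolerance 0 under dense scattered errors (above).
- `count_archaic` matches annotation rows by exact (chrom, pos); no
  liftover or allele harmonization is attempted.
- The recombinant-detection rule assumes the two flanks individually
  cluster into the same k groups; heavily admixed flanks violate this.
- TMRCA calibration inherits the molecular-clock and 6.5 MY assumptions;
  the ±2 SD bands reflect across-gene spread only, not calibration
  uncertainty.
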