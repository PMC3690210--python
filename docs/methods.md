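# Methods

This note documents the models, estimators, numerical choices and known
limitations of `famevol`, in the order the pipeline runs them.

## Gene sets and the inclusion filter

A gene copy is a `GeneRecord`: species tag (one of Hsa, Ptr, Ggo, Ppy,
Nle, Mmu, Cja), CDS, protein, and the half-open amino-acid span of the
conserved domain within the protein. The CDS must translate exactly to
the protein (standard code, trailing stop ignored); an internal stop is
rejected as pseudogene-like input. Species tags come from a metadata TSV
rather than FASTA headers, so no header dialect is assumed.

Copies whose conserved domain is shorter than **160 aa** are excluded
before analysis; the inequality is strict (a 160 aa domain is retained)
and the threshold is configurable. Codons containing ambiguous bases
translate to `X` and are excluded site-wise downstream rather than
discarding the record.

## Codon alignment

Alignment is protein-first: a guide protein alignment (an input; any
aligner can produce it — the simulator emits true alignments, so the
test suite needs no aligner) is back-translated onto the CDSs, each
residue expanding to its source codon and each gap to `---`. All
comparative statistics are computed on the alignment restricted to the
domain span, where homology is reliable.

## Divergence and Ka/Ks

* **p-distance** uses pairwise deletion: a column contributes only when
  both sequences carry an unambiguous base.
* **Jukes–Cantor**: d = −(3/4)·ln(1 − (4/3)p), defined for p < 3/4.
  Saturated pairs are reported as missing, never clamped; group averages
  skip missing pairs and expose the skip count.
* **Nei–Gojobori (1986)**: per codon, each position's synonymous
  fraction is computed over its non-stop single-base mutants (stop
  mutants are excluded from that position's denominator — the MEGA
  convention; the alternative of counting them as nonsynonymous shifts
  Ks by several percent, which is why the Biopython cross-check in the
  tests runs at a coarse tolerance while the exact oracle is an
  independent exhaustive enumerator). Site counts are averaged over the
  two sequences. Codon pairs differing at k positions average their
  synonymous/nonsynonymous difference counts over all k! single-step
  orderings, excluding orderings that pass through a stop codon (if
  every ordering is blocked — possible only for some triple differences —
  all orderings are used so the differences still count). pS = Sd/S and
  pN = Nd/N are Jukes–Cantor corrected to Ks and Ka. Codons with gaps,
  ambiguity or stops in either sequence are skipped.

## Trees

Neighbor joining (Saitou & Nei) with the standard Q criterion; ties are
broken by the lexicographically smallest index pair (the Q matrix is
symmetrised with an elementwise minimum first, since floating-point
addition order otherwise breaks exact symmetry). Negative branch
lengths are clamped to zero with the deficit logged. The unrooted result
is **midpoint-rooted** for traversal: with tight groups (diameter
≤ 0.1) separated by deep splits (≈ 0.4–0.7), the midpoint always falls
on a between-group edge, so every true group is a clade of the rooted
tree — an arbitrary root (e.g. the final NJ join) occasionally lands
inside a group and silently fragments it.

Bootstrap: codon columns (nucleotide columns for plain alignments) are
resampled with replacement; each internal edge of the original tree is
annotated with the percentage of replicate trees containing its
bipartition. Replicate r draws from an RNG substream keyed by
(seed, r), so runs are reproducible and replicate order is immaterial.
Replicates with saturated distances are dropped and counted.

## Grouping and classification

Groups are accepted top-down as maximal clades satisfying: bootstrap
support strictly greater than 80, maximum pairwise divergence among
members strictly below 0.30, and at least 2 members. "Maximum pairwise"
is the stricter, deterministic reading of within-clade divergence; a
mean-based variant is available. Edges without a support value (the
root) pass the support criterion vacuously — the divergence ceiling
still gates them. Leaves in no accepted clade are singletons.

A group with exactly one member per species is **orthologous**;
anything else is **complex**, subtyped as *recent duplication* (some
species has ≥ 2 copies), *high divergence* (mean d ≥ 0.10; the
threshold separates the two deeply divergent reference groups at d
0.2291/0.1455 from all others, max 0.0945), else *lineage loss*.

Group statistics are arithmetic means over unordered member pairs; the
group Ka/Ks is the **ratio of means**, not the mean of per-pair ratios,
which keeps pairs with Ks = 0 well-defined and matches how the
reference ratios were evidently computed (0.0364/0.0305 = 1.1935).
Per-species paralog statistics are the same means over all
within-species pairs, and "average for all species" is the plain mean
of the per-species rows. Rounding (4 decimals for statistics, 3 for
P-values) happens only at serialisation.

## Codon usage

RSCU for codon j of amino acid i is x_ij·n_i / Σ_k x_ik, over the 59
informative codons (sense codons minus ATG and TGG). Amino acids absent
from a gene yield *missing* values, not zeros — a zero would fabricate
bias where there is no signal. "Variation" within a partition cell is
the sample variance (ddof 1; sample SD available), missing for cells
with fewer than two present values. The group-vs-species contrast is a
per-codon two-tailed Welch test of the per-species variation values
(7 cells) against the per-group values (one per group), the literal
reading of comparing "groups" with "genomes"; both the measure and the
unit choice are configurable because the contrast's direction is robust
to either.

## Expression

A gene's expression in a tissue is the mean over all probe × sample
values. The ortholog/paralog contrast compares, per tissue, the CVs
(sample SD / mean) across each group's members with the CVs across each
species' gene complement, by two-tailed Welch test. With expression
data for only two species — the study design this emulates — the
paralog side has two cells and the Welch degrees of freedom are ≈ 1, so
per-tissue P-values are limited (≈ 0.002–0.13 at a tenfold mean
contrast) no matter how large the effect; the direction of the contrast
is the robust statistic, and pooling the CV collections across tissues
gives a well-powered overall test. Conventional descriptive cut-offs
(0.4 for ortholog CVs, 1.5 for paralog CVs) are reported as counts,
never used as logic.

## Pseudogene calling

Homology hits are dropped if they overlap any live gene locus by ≥ 1 bp
(strand-ignored: processed pseudogenes can lie antisense to annotation)
or are shorter than 450 bp (strict; a 450 bp hit passes). Surviving
hits are merged per strand into maximal loci so multi-query hits are not
double-counted; abutting intervals stay separate. Coordinates are
0-based half-open internally, emitted as BED natively and as 1-based
inclusive tables on request. Disablement screening reports premature
stops in all three forward frames, the best (fewest-stops) frame, and a
frameshift flag when sequence length is incongruent modulo 3 with the
query; the flags are descriptive and never remove a call.

## Statistics

All contrasts use Welch's unequal-variance two-sample t-test,
two-tailed, with Welch–Satterthwaite degrees of freedom. Welch was
chosen over the pooled-variance variant because replaying the reference
per-group columns reproduces the published P-values (0.028, 0.021,
0.108, 0.003) under Welch and not under pooling. When both samples are
degenerate (zero variance, equal means), P = 1 is returned rather than
dividing by zero.

## The simulator

The generator creates families with the statistical structure the
analysis assumes, with truth recorded for scoring:

* **Species tree**: fixed seven-taxon primate topology
  `((((((Hsa,Ptr),Ggo),Ppy),Nle),Mmu),Cja)`. Branch lengths are in
  *mutation-opportunity units* (expected proposed mutations per site) —
  rough primate divergence proportions, configurable, not biology
  claims. Depths (0.015–0.08 to the root) keep realised within-group
  divergence below d ≈ 0.1.
* **Sequence evolution**: proposal/acceptance. A proposal picks a
  uniform site and an alternative base (transitions weighted κ, default
  1.0 — the pathway-uniform null that matches the Nei–Gojobori
  estimator's assumptions; raise κ for sensitivity runs). Stop-creating
  proposals are rejected; synonymous ones accepted; nonsynonymous ones
  accepted with probability ω. This is deliberately not a full
  codon-model (MG94) simulator: it is the minimal process under which
  Ka/Ks should estimate ω, which is exactly what the recovery tests
  require.
* **Groups**: ortho groups evolve one lineage per species (ω = 0.1);
  complex groups run a per-lineage birth–death process (duplication
  λ = 8, loss μ = 4 per unit branch length, retried until the realised
  family is genuinely complex) with ω = 0.4. Each group's root descends
  from one shared family ancestor: the ancestral protein is recoded with
  group-specific synonymous-codon preferences (Dirichlet α = 0.3 per
  amino-acid family — the group-structured RSCU signal) and then
  diverged along a deep branch (0.25 opportunity units, ω = 0.8),
  placing between-group divergence at d ≈ 0.4–0.7: above the 0.30
  grouping ceiling, below Jukes–Cantor saturation.
* **Pseudogenes**: complex-group tips are pseudogenised with
  probability 0.15 — removed from the live set, lesioned with a 1–2 bp
  deletion or an internal stop, and planted in the homology hit table
  together with self-hits at live loci and sub-450 bp spurious
  fragments, on one synthetic contig per species.
* **Expression**: for the two array species (Hsa, Ptr), log-normal
  group × tissue baselines (σ = 1.5, log scale) with small within-group
  scatter (σ = 0.15) and measurement noise (σ = 0.05), 1–2 probes × 3
  samples per tissue. This yields ortholog CVs ≈ 0.15 and paralog CVs
  ≈ 2 — the magnitudes the study design reports.
* **Reproducibility**: one seed, with named RNG substreams per stage
  (trees / sequences / pseudogenes / expression), so equal seeds give
  byte-identical families.

What the generator does **not** emulate: indels in live genes (the true
protein alignment is therefore ungapped), rate heterogeneity along the
sequence, gene conversion, intron structure, genome coordinates beyond
synthetic contigs, and array normalisation artifacts. Passing recovery
tests therefore demonstrate estimator and pipeline correctness under
the model's assumptions, not robustness to alignment error or
concerted evolution.

## Problem sizes used in validation

The default validation family is 5 orthologous + 5 complex groups
(≈ 70–90 live genes of 376 codons); recovery and contrast directions
are scored over 20 seeds with 100 bootstrap replicates per tree. ω
recovery uses 10 replicate pairs of 10,000 codons per ω. NJ is checked
for exact reconstruction on 100 random additive matrices of 6–10
leaves, and RSCU normalisation on 1,000 random CDSs. The pathway
counter is checked against exhaustive enumeration on all 3,721 sense
codon pairs.

## Known limitations

* Jukes–Cantor (not K2P/GTR) throughout, matching the analysis this
  package reimplements; saturated pairs become missing data.
* NG86 (not ML) Ka/Ks; known to be slightly conservative at high
  divergence and biased under strong transition/transversion skew.
* Group acceptance is hard-thresholded; clades hovering at support ≈ 80
  or divergence ≈ 0.30 flip with bootstrap noise.
* The per-tissue expression contrast is power-limited by the number of
  species with expression data (see above).
* The 160 aa domain filter, 450 bp pseudogene floor, and 0.10
  high-divergence subtype threshold are study conventions exposed as
  parameters, not derived quantities.
* In simulated families the within-species paralog *Ks* (between-group
  pairs) frequently saturates (pS beyond the Jukes–Cantor domain) and is
  reported missing rather than clamped; the paralog-vs-ortholog contrast
  is therefore scored on *d*, which stays estimable.
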