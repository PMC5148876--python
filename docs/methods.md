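# Methods

This note documents the statistical models behind each analysis stage, the
synthetic-data generator that drives the test suite, the parameter defaults
and the design decisions taken where the procedure was genuinely open.

## Species panel

The default panel holds 14 species: five plant pathogens (Bc, Ssc, Bg, Mb,
Fo), six saprotrophs (Af, Tr, Chg, Pc, Gl, Om), two ectomycorrhizal species
(Tm, Ceg) and the focal root endophyte (Ps). *Oidiodendron maius* (Om) is
both a peat saprotroph and an ericoid-mycorrhizal fungus; it is counted
with the saprotrophs, which is what makes the six-species saprotroph group
the enrichment rules assume. Exactly one species is focal; all
"comparison" statistics exclude it.

## RIP dinucleotide analysis (`ripscan`)

Repeat-induced point mutation introduces C→T transitions at CpA sites in
repeats; on the forward strand this depletes CpA and its
reverse-complement image TpG while enriching TpA. The analysis counts
overlapping dinucleotides on the forward strand only, within each sequence
and never across sequence boundaries; pairs containing N are skipped so
assembly gaps do not dilute frequencies. The headline statistic is the
per-dinucleotide fold change f(d) = p_repeat(d)/p_control(d); the
difference p_repeat − p_control is reported alongside. Frequencies are
normalized within each region class (repeats, controls) separately.

Controls are not specified by the procedure this emulates, so the package
defaults to length-matched sampling: one uniformly placed non-repeat
segment per repeat, of the same length, non-overlapping with repeats and
with each other, seeded. This matches the control set to the repeat set in
total mass and length distribution.

Calling a dinucleotide significantly over/underrepresented needs a test
the procedure never names; the package uses a per-dinucleotide chi-square
goodness-of-fit of the repeat count against the control frequency with
Bonferroni correction over the 16 dinucleotides at α = 0.05. This choice
only affects the `significant` column, never the folds.

Window tracks tile each scaffold with 1 kb windows at 1 kb steps
(defaults; both configurable). Covered-base fractions use half-open
interval arithmetic on the *union* of annotation intervals, so overlapping
or split intervals give identical tracks; a final short window is emitted
truncated and flagged partial. GC content ignores N.

Repeat-candidate filtering removes candidates shorter than 50 bp or with
fewer than 10 genomic hits, then collapses redundancy by greedy clustering
(longest first) requiring global-alignment identity ≥ 0.90 over ≥ 0.90 of
the shorter sequence's length; one representative (longest, ties by id)
survives per cluster.

## HGT screening (`hgt`)

Input is a per-gene homolog hit table (taxon, fungal/non-fungal flag, bit
score, identity, query coverage), load-filtered at coverage ≥ 0.40,
identity ≥ 0.20, best 1,000 hits by bit score. The candidate call uses two
criteria joined by OR, with the triggering reasons reported: taxonomic
skew (fungal hit fraction < 0.15) and bit-score dominance (best fungal bit
< best non-fungal bit; mean-vs-mean available as an option — max-vs-max is
the default because it is robust to hit-list truncation). A gene with no
fungal hits triggers both reasons; a gene with no hits is not-evaluable
rather than a candidate. The call is invariant to rescaling all bit scores.

Pairwise identity comes from global alignment (match +1, mismatch −1, gap
open −2, gap extend −1), identity = identical aligned positions /
alignment length. The scoring values are fixed for reproducibility; any
reasonable global-alignment identity would serve. Greedy clustering visits
sequences longest-first (ties by id) and joins the first centroid with
identity ≥ threshold, uclust-style. The adaptive wrapper starts at 0.95
and steps down by 0.05 while more than 40 clusters remain, with a hard
floor at 0.50, so the threshold used always lies on the grid
{0.95, 0.90, …, 0.50}. Non-fungal homologs are clustered adaptively;
fungal homologs at 0.95 with the same downward adjustment only if needed.
A conserved-control preset (identity floor 0.75, clustering at 0.90)
mirrors the tighter settings appropriate for housekeeping genes such as
RNA polymerase II.

The tree stage replaces the full alignment/ML pipeline (out of scope) with
neighbor joining on one-minus-identity distances over the focal sequence
and cluster representatives, with deterministic tie-breaking (smallest
index pair). Because the source trees are unrooted, the origin call roots
at the leaf farthest from the focal gene (path length, ties by name) and
takes the smallest clade enclosing the focal leaf plus at least one other
leaf: all-non-fungal sister members support horizontal transfer,
all-fungal reject it, anything else is mixed.

## Ortholog lifestyle enrichment (`ortho`)

The pathogen preset selects clusters with ≥4 of 5 pathogens present, ≤1
saprotroph, ≤1 mycorrhizal species, focal present. The saprotroph rule is
only described as "the same strategy"; the package defaults to the
proportional analogue (≥5 of 6 saprotrophs, others capped at 1, focal
present) and exposes every threshold in `EnrichmentRule`. Over the 2^13
non-focal presence patterns the pathogen preset admits exactly
(C(5,4)+C(5,5))·(1+6)·(1+2) = 126 patterns, which the test suite verifies
by exhaustive enumeration.

PCA is centered and unscaled by default (correlation mode optional),
computed by SVD, with a deterministic sign convention (the largest-
magnitude loading of each component is positive). The focal species is
included as a row but excluded from the lifestyle centroids used for the
nearest-centroid readout in the PC1–PC2 plane. Presence/absence matrices
and count matrices are both accepted as features.

Functional-catalogue rollups count each (gene, category) pair once,
rank categories by distinct-gene count and break ties by category id.

## Domain enrichment (`domains`)

For each accession the focal count is compared against the mean μ̂ and
sample standard deviation σ̂ (n−1) of the 13 comparison species:
z = (x_focal − μ̂)/σ̂ with a two-sided normal p-value, no multiple-testing
correction by default (a Benjamini–Hochberg flag exists). With 13
comparison genomes the normal approximation is anticonservative: the null
flag rate of the default generator measures ≈ 0.076–0.079 rather than the
nominal 0.05, which the calibration tests treat as the expected behaviour
of this statistic, not an error. σ̂ = 0 cells are 'ns' when the focal
count equals the common value, otherwise 'degenerate_over/under' (counted
as significant, since the deviation is unambiguous but unmeasurable in sd
units). Fold screens use strict inequality (focal > k·μ̂); zero-mean
accessions need an absolute focal count ≥ 3 to qualify, so a single
focal-specific copy is not inflated into an infinite fold. Lifestyle
mining compares the target-lifestyle mean against the mean of all other
comparison species, focal excluded from both sides.

Power at the defaults: planted fold-4 accessions are recovered at recall
≈ 0.9; at fold 3 and baseline mean 5 recall is ≈ 0.72–0.79, which is the
information limit of count data at that mean (even the Poisson limit caps
near 0.93), not an implementation artifact.

## CAZyme profiling (`cazy`)

Counting is module-level, not gene-level: a gene carrying two GH5 modules
contributes two, because substrate capacity scales with catalytic modules.
The default substrate-class map is cellulose {GH6, GH7, GH45};
hemicellulose {GH10, GH11, GH26, GH31, GH67, GH115, GH134}; pectin {GH28,
GH53, GH78, GH79, GH88, GH105, GH106, GH127, PL1, PL3, PL4, PL9, PL11,
CE8, CE12}; cutin {CE5}; and a 'multiple substrates' class {GH12, GH30,
GH43, GH5, GH51, GH54, GH62, GH74, GH93}. Classes must be disjoint;
unmapped families are reported as an 'unassigned' total (conserving the
module sum) but excluded from PCA features. The 'multiple' class enters
the PCA as its own fifth feature.

## Secondary-metabolite classification (`smclass`)

Domain strings use the controlled vocabulary {SAT, KS, AT, DH, MT, ER, KR,
PT, T, TE, TH, C, A, R, DUF, Kinase, Acyltransferase}. The classifier is a
strict rule cascade:

1. KS with both C and A → PKS-NRPS hybrid. A true hybrid carries a full
   NRPS module; requiring the A domain keeps a reducing PKS with a stray
   terminal C domain out of the hybrid class.
2. KS or AT present → type I PKS; non-reducing iff neither KR nor ER is
   present, else reducing. Accepting AT alone covers PKS genes whose KS
   call is missing from the curated domain string.
3. C with A and T → NRPS.
4. A and T without C or KS → NRPS-like (A-T-R, A-T-TE, A-T-DUF cores and
   their variants).
5. Otherwise unclassified.

The cascade reproduces all 48 curated classes of the shipped reference
table (`endosig/data/sm_key_gene_architectures.tsv`), including the eight
non-reducing type I PKSs. Type III PKS, DMATS and terpene synthases are
identified by protein-family accessions rather than domain strings and are
treated as pass-through classes outside the cascade.

Cluster sketching scans 10 genes (configurable; the source procedure
states no window) up- and downstream of each key gene for tailoring
enzymes (acyl-/methyltransferases, oxidoreductases, cytochrome P450s);
two or more within the window define a cluster spanning the maximal run
from first to last qualifying gene. Flagging non-reducing PKSs with an
adjacent hydroxynaphthalene-reductase tag stands in for the full
cross-species orthology argument for melanin clusters, which is out of
scope.

Copy-number summaries take the median over all species columns including
the focal one (even n: mean of the central pair); ambiguous cells like
"2(3)" resolve to the first integer with a warning. In the shipped
RNAi/RIP table the recomputed medians are RdRP 3, Argonaute 2, Dicer 2;
the Dnmt1 row recomputes to 2 under every convention tried while the
published value is 1, so that row is flagged as a print inconsistency
rather than reproduced.

## Synthetic-data generator (`simulate`)

One global seed; each generator derives an independent stream from
(seed, stage-tag) so stages regenerate in isolation. All generators are
bit-reproducible under a fixed seed.

- **Cluster matrices**: 500 clusters by default, background presence
  i.i.d. Bernoulli(0.5); 20 planted pathogen rows and 20 planted
  saprotroph rows constructed to satisfy their enrichment rule exactly
  (target group at or above its minimum, at most one species of each
  other lifestyle, focal present).
- **Annotation counts**: negative binomial with mean 5 and dispersion 10
  (variance μ + μ²/10; Poisson is the dispersion→∞ limit), matching the
  overdispersion and the 3–5 instances-per-genome scale of real domain
  counts. 50 of 1,000 accessions planted with the focal mean multiplied
  by 4.
- **RIP genome**: 500 kb single scaffold at GC 0.46 with 50 non-overlapping
  2 kb repeats (100 kb of repeat sequence) and 100 gene intervals; within
  repeats every CpA and TpG site mutates independently with probability
  `rip_rate` (default 0.5), positions recorded in the ground truth.
- **Hit tables**: 200 genes × 100 hits; null genes are 75% fungal with
  fungal bit scores ~N(420, 25) dominating non-fungal ~N(280, 25); the 10
  planted HGT genes are forced below 15% fungal hits with a top non-fungal
  bit score (~N(450, 25) vs fungal ~N(250, 25)), and hit protein
  sequences are mutated copies of the focal protein (5% divergence on the
  near side, 40% on the far side) so trees place the focal gene with the
  non-fungal homologs.

What the generator does **not** emulate: real gene structure, codon
usage, phylogenetic correlation among the panel species, database biases
of homology searches, or repeat-family structure. Passing recovery tests
therefore demonstrates correctness of the decision rules and statistics
under their stated assumptions, not performance on real proteomes, where
taxon sampling and annotation error dominate.

## Numerical choices and problem sizes

Degenerate inputs: empty or all-N sequence sets raise an empty-profile
error; zero-control-frequency dinucleotides give an undefined (NaN) fold
with a flag rather than an exception; zero-variance PCA inputs return a
degenerate-result flag. Ties are broken deterministically everywhere
(bit-score ties by hit id, cluster ties by id, NJ joins by smallest index
pair, category ties by id).

The default test suite and the acceptance script run in well under a
minute on one CPU; the sizes above (500 kb genome, 200 genes × 100 hits,
1,000–20,000 accessions, 500 clusters) were chosen to keep Monte-Carlo
error small relative to the effects being measured while staying
desk-scale. The full end-to-end tree stage is exercised on a reduced set
(12 genes × 20 hits) because pairwise global alignment dominates its cost.

## Known limitations

- The published headline counts of the real study system (e.g. 963
  overrepresented accessions, 21 horizontally acquired genes, 998 CAZyme
  modules) depend on the real proteomes and a specific homology database
  and are not reproducible at desk scale; the package reproduces the
  *procedures* and the printed worked examples instead.
- The Z-test's normal approximation is anticonservative at 13 comparison
  genomes (see above); use the BH option when calibrated error rates
  matter.
- Greedy clustering depends on input order by construction; the
  longest-first rule makes it deterministic but not optimal — cluster
  counts upper-bound those of an optimal clustering.
- The neighbor-joining surrogate ignores alignment uncertainty and rate
  heterogeneity; its origin calls are meant for planted synthetic signals
  and triage, not publication-grade phylogenetics.
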