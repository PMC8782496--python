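# Methods

This note records the models, conventions and design choices behind
`multilesion`, in the spirit of a methods supplement: what each module
assumes, which knobs matter, and what the synthetic cohorts do and do
not establish about real data.

## Somatic-variant filtering and burden

A call passes when tumour and normal total depth are both >= 20 reads
(ties inclusive), at most 5 alternative reads support it in the
germline, at least 5 support it in the tumour, and the maximum
population frequency across databases is below 1%. Missing population
frequency is treated as 0: a variant absent from every database is
novel, which is the usual annotation convention. Synonymous calls are
kept in the table but excluded from burden. TMB divides the passed
nonsynonymous count by a 38 Mb exome footprint, so it is linear in the
mutation count by construction. A gene with two or more passed
nonsynonymous mutations in one lesion is flagged multi-hit.

Candidate drivers require catalog membership plus either a truncating
consequence (nonsense, frameshift, splice site) or a damaging missense
call: FATHMM-MKL > 0.5 alone, or any two concordant predictions among
SIFT <= 0.05, PolyPhen2 possibly/probably damaging, MutationAssessor
medium/high, and FATHMM-MKL > 0.5. Missing scores count as
non-damaging, so annotation gaps can only lose candidates, never
invent them. The built-in catalog is a convenience default;
analyses of real cohorts should pass their own.

## Copy number

Segments are compared against sample ploidy on the log2 scale:
`r = log2(CN / ploidy)`, gain at `r >= log2(2.5/2)`, loss at
`r <= log2(1.5/2)`. At ploidy 2 these cutoffs coincide exactly with
integer copy number >= 2.5 and <= 1.5, which is the property the tests
pin down. CNV burden is the percentage of covered genome length in
non-neutral segments — a single definition used consistently for both
the per-lesion value and the per-patient average; its range on the
packaged clinical fixture (2.8–53.7) is consistent with this reading.
wGII asks, per autosome, what fraction of the chromosome's length has
rounded copy number different from rounded ploidy, then averages over
autosomes; rounding avoids float equality against non-integer ploidy.
Chromosomes without segments are excluded with a warning rather than
treated as neutral.

Arm boundaries ship as a data file derived from the standard hg19
cytoband/gap coordinates (autosomes only), plus a three-chromosome toy
genome for tests. Segments straddling an arm boundary are split at the
boundary before any length accounting, which makes burden and wGII
invariant to how a caller happened to segment the genome — splitting a
segment into adjacent pieces with the same copy number changes
nothing.

An arm event needs more than 98% of arm length in the same non-neutral
state. Across one patient's regions, an event seen in at least one
region is clonal when the same state recurs in more than 75% of the
*remaining* regions; single-region patients are clonal by convention
(the rule is vacuous) and emit a warning, and arms with both gain and
loss calls across regions are demoted to subclonal with a warning.
Genome doubling is called when more than half of the covered genome
has major allele copy number >= 2 — diploid heterozygous genomes sit
at 0% and doubled genomes near 100%, so the threshold is not
delicate.

## Cancer cell fraction, clonality, timing

With purity `rho`, local tumour total copy number `CNt` and
multiplicity `m` (mutated copies per tumour cell), the expected
variant allele fraction of a mutation carried by a fraction CCF of
tumour cells is

    VAF = CCF * rho * m / (rho * CNt + 2 * (1 - rho))

Multiplicity is estimated as `max(1, round(VAF/rho * (rho*CNt +
2(1-rho))))` and CCF by inverting the identity at that integer. CCF is
clipped to [0, 1.2] with values above 1 flagged; on noise-free input
the estimator inverts the generator's model to machine precision,
which the acceptance checks verify.

A mutation is clonal when present with CCF >= 0.9 in *every* region of
the patient; 0.9 operationalises "close to 1" and is configurable.
Timing relative to genome doubling uses multiplicity: in a doubled
region a mutation on >= 2 copies predates the doubling (early), one on
a single copy postdates it (late); without doubling a mutation is
early when its multiplicity reaches the major copy number (>= 2);
regions with major copy number 1 are uninformative. The aggregate
label needs a strict majority of timeable regions — ties and
no-information cases are "clonal untimed", and untimeable regions are
excluded from the denominator. Clonal arm gains are timed by the
median multiplicity of clonal mutations on the arm (>= 2 means the
mutations rode the gain, hence early); clonal losses by LOH (minor
copy number 0 in every region means early).

## Clone trees and trunk/branch statistics

Mutations are clustered by their presence pattern across regions, then
split within a pattern by one-dimensional k-means on mean CCF, taking
the smallest k whose within-cluster CCF range is <= 0.1. This replaces
Dirichlet-process clustering deliberately: it is deterministic,
desk-scale, and the downstream analysis consumes only cluster-level
CCFs. Clusters are ordered into a tree by CCF containment — the
truncal cluster must sit at ~1 in every region, and every other
cluster attaches to the smallest already-placed cluster that contains
it (parent CCF >= child CCF − 0.1 per region). Trunk mutations are the
truncal cluster's members; everything else is branch.

Clone trees are only identifiable up to what the CCFs can express:
clusters with near-identical small CCFs in the same regions cannot be
separated or ordered by any method, and the default synthetic cohorts
(6–10 clones over 2–4 regions) intentionally contain such clones.
Recovery guarantees are therefore stated on identifiable planted
trees, not on arbitrary deep trees.

The driver enrichment statistic subsamples 12 patients without
replacement per replicate (100 replicates), builds the 2x2 table of
driver status x trunk/branch with a Haldane–Anscombe 0.5 correction
when a cell is empty (odds ratio capped at 100 when still degenerate),
and records per-replicate fold enrichments — driver proportion in the
compartment over driver proportion overall — for trunk and branch.
The two distributions are compared with a two-sided rank-sum test; a
paired signed-rank p is also reported since the replicates are
paired by construction, but the unpaired test is the default.

## Replicate-free differential expression

For a single tumour/normal pair, each gene's count is Poisson; with a
flat prior the posterior of the normalised rate given count k and size
factor s is Gamma(k+1, rate s). The reported statistic is the 1%
posterior quantile of the log2 ratio when positive, the 99% quantile
when negative, else 0 — the fold change supported with 99% posterior
probability, which is conservative relative to the raw fold change by
construction. The default evaluation is Monte-Carlo with 10,000 seeded
draws; an analytic path via the exact Gamma-ratio (beta-prime)
quantile is available and is used as a cross-check (a large-sample
Monte-Carlo oracle agrees within 0.05). Size factors are library-size
ratios, since single-sample comparisons preclude median-of-ratios
normalisation. DEGs are genes with |statistic| > 2; a gene is a shared
DEG of a tumour only when it is a DEG *with the same sign* in every
lesion. Sample clustering operates on log2 fold-change profiles
(average linkage, Euclidean — the linkage and metric are configurable
since no single convention is canonical) and reports mean intra- vs
inter-patient distances plus the fraction of multi-lesion patients
whose lesions form a contiguous clade.

## Methylation

Peaks with FDR-adjusted q < 0.01 are merged (>= 1 bp overlap) into a
region universe; a region overlapped by exactly one sample's
significant peaks is a private DMR, by two or more a shared DMR. The
merged-union overlap rule is the simplest reproducible convention for
deciding that peaks in different samples are "the same" region.
Phyloepigenetic trees use Euclidean distances between enrichment-fold
vectors over the private-DMR universe (absent region = 0), built by
neighbour joining — exact on additive matrices — and rooted on the
matched normal's pendant edge when present (UPGMA available by flag).
Hypermethylation similarity takes each sample's top-k (default 2000)
regions by enrichment fold and reports pairwise Jaccard indices.

## Cross-omics integration

Expression (log2 fold change vs matched normal) is correlated per gene
with discretised copy-number or methylation state ({-1, 0, 1}) across
samples by Spearman rank correlation, skipping genes with under 5
complete pairs or a constant layer, with Benjamini–Hochberg adjustment
across genes per layer pair. The concordance screen flags genes whose
direction of alteration holds in all samples up to a tolerance
(default one exception) — the pattern of a cohort-wide biomarker such
as consistent expression loss or consistent copy-number deletion.
Gene-wise weighted integration scores of the kind produced by
dedicated multi-omics packages are intentionally not reproduced; rank
correlation plus the screen cover the package's integration claims.

## Clinical statistics

The packaged fixture is a 19-patient pancreatic-cancer cohort table
(per-patient demographics, metastasis, OS/DFS, average TMB, average
CNV burden). Derived variables: lymph-node metastasis is TNM
containing "N1" (NX counts as node-negative); the one non-disease
death (early post-operative, no usable follow-up) has missing survival
fields and is excluded from survival analyses while remaining in the
contingency tables.

The burden dichotomy is a strict median split (high iff burden >
median), which reproduces every cell of the published association
table from the fixture. Fisher tests are two-sided by the
probability-mass rule (summing hypergeometric probabilities no larger
than the observed table's); an exhaustive enumeration oracle confirms
the implementation on all small tables. The quartile split takes
burden strictly above the linear-interpolated 75th percentile. DFS
events are relapse/metastasis with deaths censored at death by
default; counting non-relapse death as a DFS event is available by
flag — on the fixture the two conventions give log-rank p = .0438 and
p = .0462 respectively (OS: p = .1884), so the flagged convention is
the one that matches the published analysis, and the acceptance script
reports it.

## Synthetic cohorts

The generator emulates the study design the analysis targets: 19
patients, 2–4 lesions each, a truncal clone present in every region
plus 5–9 branch clones with region-specific fractions from recursive
Dirichlet splits (clones absent from a region with probability 0.35),
200–400 mutations per patient with a trunk fraction drawn from
2–24% (branch-dominant, median near 90%), drivers planted on the
trunk at 4x odds, per-lesion purity uniform on 0.3–0.8 (no purity
values being available to copy, this is a choice of plausible WES
range), mean depth 150x, genome doubling in 30% of patients, 3–9
arm-level events per patient on the hg19 arm scaffold, 2000 expression
genes with 10% patient-shared DEGs at |log2 fold change| 3 plus
lesion-private DEGs, 1000 methylation regions with patient-shared and
lesion-private peaks, and survival with hazard proportional to
exp(0.08 x centred burden). One integer seed drives everything;
subsidiary generators derive from it by fixed offsets, so a
configuration and seed determine the cohort byte-for-byte.

What the generator does *not* emulate: mapping artifacts and strand
bias (read noise is purely binomial), realistic mutational spectra,
subclonal copy number within a lesion, batch effects in expression,
and peak-calling noise in methylation. Passing tests on these cohorts
therefore establish that the estimators invert the stated generative
models and detect planted signals at the stated sizes — not that they
are robust to artefacts real pipelines must handle upstream.

## Numerical conventions

Coordinates are 1-based inclusive in files (MAF, SEG) and 0-based
half-open internally and in BED. CCF clipping is at 1.2 with a flag
above 1. Tie rules are explicit everywhere: median and quartile splits
use strict inequality, timing majorities are strict with ties
untimed, and all-equal burdens put every patient in the low group.
Odds ratios use a 0.5 correction only when a cell is zero and are
capped at 100. Test and acceptance problem sizes (6-patient cohorts
for module tests, the 19-patient default for recoverability checks,
25–50 independent seeds for detection rates) were chosen as the
smallest sizes at which the binomial noise of the checked rates is
comfortably below the asserted margins.
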