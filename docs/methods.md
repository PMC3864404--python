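# Methods

## Scope and data model

The package analyses multi-region tumour sequencing data of the kind
produced by HGSC clonal-evolution studies: per patient ("case"), several
regional samples assayed at a shared panel of somatic mutations by deep
amplicon sequencing, allele-specific copy-number segment profiles per
sample, and optionally one plasma cfDNA sample. All statistics operate on
plain-text tables — counts as TSV (mutation, chromosome, 1-based position,
sample, reference reads, variant reads), segments as BED-like TSV (0-based
half-open, major ≥ minor ≥ 0) — so the stages compose through files as well
as in memory.

## Presence/absence calling

A site is scored against a global per-base error rate ε with the one-sided
exact binomial tail P(X ≥ v | n, ε). Defaults: ε = 0.001 (a typical
post-filter amplicon error floor), α = 0.01, depth floor 50, minimum 5
variant reads. The depth floor defines INCONCLUSIVE, mirroring assay
dropout; (mutation, sample) pairs absent from the table are treated as
depth 0. The minimum-variant-reads guard protects against significance at
extreme depth with biologically negligible support. All four thresholds
are exposed because their published analogues live in assay-specific
supplementary protocols rather than in any main text.

Conservation per group (case or tumour mass) is
100 × (#mutations PRESENT in every evaluable sample) / (#mutations PRESENT
in ≥ 1 sample). Two conventions matter and are fixed here: INCONCLUSIVE
cells are excluded from, not counted against, the "every sample"
requirement; and the denominator is the group's own detected-mutation
universe. The cross-group summary is the mean ± sample SD (ddof = 1).
Categories: ancestral = present in all evaluable samples, private = present
in exactly one, shared = otherwise, undetected reported separately.

## Mutational-profile phylogeny

Profiles are vectors over the case's mutation union — allelic ratios by
default (`mode="vaf"`), binary calls as a robustness alternative —
with INCONCLUSIVE set to 0. The distance is d = 1 − Pearson r, with r
defined as 0 when either vector has zero variance; that convention places
the appended all-zero control profile at distance exactly 1 from every
sample, giving it the root-like position rather than an undefined
correlation. Neighbour joining is the standard Saitou–Nei agglomeration:
join the pair minimising Q(i,j) = (n−2)d(i,j) − r_i − r_j, branch lengths
by the usual formulas with negatives clamped to 0, reduced distances
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. Ties on Q break by the
lexicographically smallest pair of cluster labels (a cluster is labelled by
its smallest leaf), so output is independent of input order. Newick output
is canonical: children sorted by smallest leaf label, 6 significant digits,
control leaf serialized as the outgroup.

On additive distance matrices NJ provably recovers the generating tree;
the test suite verifies exact recovery (path distances to 1e-9) against an
independent edge-graph oracle on random binary trees, and cross-checks
sisterhood judgments against scikit-bio's NJ.

A real limitation of the Pearson distance itself, documented rather than
patched: because 1 − r rewards co-absence, samples from unrelated subtrees
of the clone tree can correlate through the mutations both lack, and a
sample dominated by the direct ancestor of two sister clones sits exactly
on their joining node. Consequently sister clones are reliably recovered
as sisters only when the branch they share (below the universal ancestral
set) carries a clear mutation load — about twice the per-clone private
load in our simulations (99/100 seeds); with an empty shared branch their
sisterhood is invisible to mutation profiles in principle. Interpreting
fine structure in such trees should bear this in mind.

## Copy-number zygosity and doubling

Zygosity is a total function of (major, minor): HOMD (0,0), HEMD (1,0),
HET (1,1), NLOH (2,0), ALOH (m ≥ 3, 0), BCNA (m,m ≥ 2), else ASCNA.
Compound-event weights over genes are ALOH = NLOH = HOMD = 2, HEMD = 1,
HET = ASCNA = BCNA = 0: the weight-2 classes require (or, for HOMD, imply)
at least two sequential events with LOH, while balanced amplification is
amplification without LOH and scores 0. The compound *fraction* statistic
counts NLOH + ALOH length only (the named compound classes), over the
profile's covered length; it is invariant under segment splitting. Genes
take the state of the segment containing their midpoint — deterministic and
split-invariant; genes in coverage gaps are unassessed and dropped from
any gene universe shared across samples. When no gene model is supplied
the pipeline tiles a deterministic 10-Mb locus grid over the covered
genome. The architecture tree appends an all-zero control vector and runs
Euclidean distances through the same NJ engine.

Doubling of a test profile relative to a reference is assessed on the
intersected segmentation grid: a region is consistent iff
(test_major, test_minor) = (2·ref_major, 2·ref_minor) and the reference is
not (0,0) — covering the two diagnostic signatures HEMD → NLOH and
HET → 2+2 while excluding the vacuous doubling of nothing. A chromosome is
flagged when the consistent fraction of assessable length reaches the
threshold (default 0.5, exposed as a flag): a formalization of
per-chromosome doubling calls that published analyses report without a
stated rule. Post-doubling segmental events erode consistency, so deeply
diverged doubled genomes legitimately flag fewer than 22/22 autosomes.

## ctDNA detection

Detection uses the same exact binomial tail (depth-0 sites are excluded as
uncovered), BH adjustment within one patient panel (statsmodels
`fdr_bh`), and detected = q < 0.05. The minimum detectable allelic ratio
is the smallest k/n whose unadjusted tail beats α (k ≥ 1 always; computed
at the panel's median covered depth), matching a per-patient detection
floor rather than an FDR-dependent one — the two can diverge when many
sites are tested. Ancestral enrichment is the one-sided (greater)
hypergeometric tail of the 2×2 {detected} × {ancestral} table over covered
sites; zero margins return p = 1 with a warning. The error rate is a
single global background (default 0.001) rather than per-site, a
deliberate simplification exposed as a parameter.

## Cellular frequency and diversity

φ = VAF · (c_N(1−t) + c_T·t)/(t·m), clamped to [0,1], with c_T looked up
from the sample's segment profile at the mutation's position (gaps default
to c_T = 2 with a warning), c_N = 2 and multiplicity m = 1 by default.
This deterministic single-site estimator replaces Dirichlet-process
clustering of mutations across sites; it is unbiased in expectation for
clonal fractions under the simulator's VAF model (E[VAF] = t·f·m/
((1−t)c_N + t·c_T), so E[φ̂] = f), but it does not share information
between sites and its per-site noise inflates spread at low depth.
Diversity is IQR(φ) per sample with linear-interpolation (type-7)
quantiles — stated explicitly because IQR values depend on the quantile
convention; samples with fewer than 4 frequencies are flagged
low-confidence. Published per-sample IQRs from the motivating study design
(0.085–0.51) are context for scale, not targets, since they come from a
different estimator.

## Simulator

The simulator emulates the study conditions the analysis stages expect.

* **Topology**: random recursive tree over `n_clones` (each new clone
  attaches uniformly to an existing one); clone c0 is the ancestral clone.
* **Mutations**: Poisson(`mutations_per_branch_mean`, default 10) per
  branch under infinite sites; the root branch draws max(1, ·) so the
  founder TP53-like mutation always exists. Loci are uniform over a
  22-autosome genome with Mb-rounded human-like lengths.
* **CNA events**: Poisson(1.5) per branch; event lengths follow a
  focal/arm mixture (85% exponential with ~10 Mb mean plus 1 Mb offset,
  15% arm-to-chromosome scale uniform 40–100% of the chromosome),
  the realistic segmental-CNA spectrum; alleles are tracked as the two
  parental haplotypes, deltas ±1 with copies clamped at 0 (events may
  recur). `wgd_clone` doubles both haplotypes genome-wide, applied after
  that branch's segmental events.
* **Regions**: each sample supports 1–3 clones (uniform), fractions
  Dirichlet(1,…,1), tumour content 0.7 for all samples — a typical
  resected-tumour purity.
* **Counts**: depth ~ NegBin(mean 5000, shape 10), reproducing the
  study's "median > 5000×" with overdispersion; variant reads ~
  Binomial(depth, VAF + ε(1−VAF)) with VAF = t·f·m/((1−t)c_N + t·c_T)
  evaluated at the diploid default (t·f/2); ε = 0.001.
* **Copy-number profiles**: each bulk sample reports its dominant clone's
  integer allele-specific profile, as arrays on bulk DNA do; fractional
  clone-mixture copy numbers are out of scope.
* **Plasma**: one pseudo-sample whose clone fractions are Dirichlet-
  weighted shedding averages, at tumour fraction 0.1 (the scale at which
  ancestral mutations sit comfortably above a 5000× detection floor).

What the simulator does *not* emulate — and therefore what passing tests
do not establish about real data: mapping and alignment artefacts,
per-site error-rate variation and strand bias, subclonal copy number
within a sample, mutation multiplicity > 1, kataegis/clustered mutation
processes, and sampling correlation between adjacent regions. Parameter-
recovery results should be read as correctness of the estimators under
their own model, not as field performance.

All randomness flows from `SimulationConfig.random_seed` through
per-stage `numpy` generators (`default_rng([seed, stage])`), so every
artefact is a pure function of the configuration; the pipeline manifest
records SHA-256 hashes of all outputs and is bit-reproducible.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open in all segment/gene tables; count
positions are 1-based. Exact binomial tails come from `scipy.stats.binom.sf`
(no normal approximation). Pearson r with a zero-variance vector is 0 by
convention. NJ clamps negative branch lengths and reduced distances at 0.
Distance matrices are validated (symmetry 1e-12, finite, hollow,
non-negative). Empty segment profiles yield compound fraction 0 with a
warning; empty p-value lists adjust to empty; degenerate Fisher tables
return p = 1 with a warning; depth-0 count rows are INCONCLUSIVE/uncovered
rather than errors. Sample compositions must sum to 1 within 1e-9.

## Problem sizes

The shipped verification uses the sizes that keep every run interactive:
10⁴ sites for null calibration of presence calling and ctDNA detection,
200 random additive matrices (≤ 8 leaves) for the NJ oracle, 50 seeds of
4-clone trees for doubling recovery, 100 seeds for the paired diversity
comparison, and one default-size simulation (6 clones × 6 samples,
~70 mutations) for parameter recovery. The full test suite and the
acceptance script each complete in well under a minute on one CPU.
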