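# Methods

This note records the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions fixed where a choice had to be made.

## Coverage-based detection

Per scaffold, mean male and female genomic depth are compared as
log2(M/F). The detector keeps scaffolds strictly longer than
`min_length_bp` (default 1,000 bp) with positive depth in both sexes;
shorter or zero-depth scaffolds are tallied, not raised, because draft
assemblies always contain both.

The autosomal anchor `a_coord` is the mode of the log2(M/F) distribution:
a Gaussian KDE with Silverman bandwidth evaluated on a fixed 512-point
grid spanning the data range. A fixed estimator makes the anchor
reproducible across platforms; the grid spacing (~data range/511) bounds
the anchor's discretization error. Note the anchor is the distribution's
*mode*, used as an estimate of the median autosomal ratio — the two
coincide only when autosomes dominate and the ratio distribution is
roughly symmetric, which is exactly the regime the method assumes. For
genomes where sex-linked scaffolds are the majority, `mode_rank=
"secondary"` anchors on the second-highest local maximum instead; it is
an error to request it when the density is unimodal. A degenerate
point-mass distribution (all ratios equal) anchors at that value
directly, since a KDE is singular there.

Candidate windows are closed intervals: X in
[a_coord − 1.1, a_coord − 0.9], Z mirrored above. The windows are
deliberately narrow — they catch scaffolds whose coverage is close to an
exact halving — so per-element sensitivity comes from counting scaffolds,
not from catching every X scaffold. Each element is tested one-sided
(over-representation) by Fisher's exact test on the 2×2 table element ×
candidate, with a flat per-element alpha of 0.01 and no multiple-testing
correction across the six elements: with six tests the family-wise
false-positive rate is bounded near 0.06, and the planted-genome type-I
simulations in the test suite measure the realized per-element rate well
below alpha. The unit of counting is the scaffold, not the base pair, so
long and short scaffolds weigh equally. Elements whose candidate
fraction exceeds 0.25 without reaching significance are annotated
"partial" — a reporting convention for partially sex-linked elements,
not a hypothesis test.

## Element assignment

Gene hits are filtered to scores strictly above 50, then each query gene
keeps its single best location; a gene whose two best hits tie is dropped
entirely, since a tied location carries no positional information.
Scaffolds take the element of the majority of their genes; exact ties are
excluded from all downstream counting (`EXCLUDED_TIE`). Genes with an
unknown reference element count toward a scaffold's gene total but cast
no vote; a scaffold with only unknown-element genes is `UNASSIGNED`.
Reciprocal-best-hit pairing produces the 1:1 ortholog tables used by the
expression analyses.

## SNP calling and young-X detection

A pileup site needs total depth ≥ 6; a SNP is called when at least two
distinct alleles each have count ≥ 0.3 × depth, compared in real
arithmetic (depth 6 ⇒ threshold 1.8 ⇒ an integer count of 2 passes).
The depth-proportional threshold keeps the call rate nearly independent
of coverage. Positions are 1-based; sites present in only one sex count
for that sex alone, and the per-scaffold male SNP fraction uses called-SNP
totals, not site intersections. Scaffolds need at least one SNP
(configurable) for a defined fraction.

The young-sex-chromosome test compares an element's per-scaffold male
SNP fractions against the pooled fractions of the other elements with a
one-sided Mann–Whitney rank-sum test (female fractions under ZW). A
verdict additionally requires the median shift to be at least
`min_shift` (default 0.05): with thousands of scaffolds the rank test
can reach significance on shifts far too small to indicate X–Y
differentiation, and the guard encodes "biologically meaningful excess".
Both groups need ≥ 10 scaffolds with defined fractions; otherwise the
element is reported untestable rather than negative.

## Dosage and sex-bias statistics

Two-sample quantile normalization maps both samples onto the mean of
their order statistics; tied values receive the average of their tied
ranks' reference values (preprocessCore behaviour). On tie-free inputs
the two outputs have identical multisets and the transform is
idempotent; ties can break exact multiset identity, though the pooled
mean is always conserved. Per-gene ratios are recentred by the autosomal
median in log2 space, which pins the autosomal median at exactly 1 for
even sample sizes too. A gene enters a comparison unless its FPKM is
below 1 in *both* samples — requiring joint failure keeps genuinely
sample-specific genes (e.g. testis-specific ones silent elsewhere),
which a single-sample filter would discard.

Class summaries report the median log2 ratio with the boxplot-notch CI,
1.57 × IQR/√n, using type-7 (linear-interpolation) quartiles, and a
two-sided Mann–Whitney test of X against autosomes. Two caveats are
worth knowing. First, the notch is an approximate interval: on the log
ratios produced here its per-run coverage is ~85–90%, so a single run's
CI missing the true median by a few percent is expected behaviour, and
parameter-recovery checks in the test suite therefore require the CI to
exclude the *wrong* magnitude class in essentially every run but to
contain the planted value only in the clear majority. Second, quantile
normalization between samples whose distributions genuinely differ
(e.g. an uncompensated X shifting ~20% of male values down two-fold)
compresses the signal slightly — a measured +1–2% bias on the X median —
and is rank- but not value-preserving under a global rescaling of one
sample, so only the significance calls are exactly scale-invariant.

Sex-bias classes use configurable fold cut-offs (2-fold biased, 5-fold
strong, sex-specific when the other sex is below the FPKM floor); the
testis rules are fixed at 3-fold (strongly testis-biased) and 10-fold
(testis-specific) against each of male head, female head, female body
and ovary, with ≥ comparisons so specificity implies the strong
criterion. X-vs-autosome proportions are compared by Pearson chi-square.

## Parsimony transition mapping

Each Muller element is an unordered binary character (sex-linked or
not); heterogamety is a three-state character (XY/ZW/undifferentiated).
Partially sex-linked elements score as sex-linked but stay annotated.
The engine is a unit-cost Sankoff dynamic program, which is exact on
multifurcating nodes (naive Fitch set-folding can overcount there) and
reduces to Fitch on binary trees; an up-down pass yields, per node, the
set of states attainable in *some* most-parsimonious reconstruction.
The point reconstruction reported delays changes toward the tips: the
root takes the first optimal state in a fixed state order, and each node
keeps its parent's state whenever that is optimal. Gains and losses per
element are counted on this point reconstruction, and exact min/max
ranges over all most-parsimonious reconstructions come from a tuple DP
run alongside the costs; characters whose ranges are non-degenerate are
flagged ambiguous rather than given a false point count. Scores are
invariant under re-rooting for these unordered characters.

## The synthetic generator

The generator emulates the *downstream summaries* of a male/female
resequencing-plus-RNA-seq study of a fly with an unknown karyotype; it
does not simulate reads, sequences or assemblies. Its defaults define
the study conditions used throughout the test suite:

| parameter | default | rationale |
|---|---|---|
| n_scaffolds | 2,000 | a modest draft assembly after length filtering |
| element proportions | A–E 0.21/0.21/0.21/0.21/0.11, F 0.05 | five large arms plus the small dot |
| scaffold lengths | lognormal, ln-mean 8.0, ln-sd 0.6, floor 500 bp | median ≈ 3 kb, short-read scaffold N50s |
| depth_mean | 20 reads/bp per copy-pair | typical resequencing depth |
| depth_dispersion | 0.02 | negative-binomial CV ≈ 14% per scaffold, realistic mapping noise |
| base_het_rate | 1e-3 /bp/sex | insect-scale heterozygosity |
| genes per scaffold | Poisson, 1 gene/10 kb | fly gene density |
| expression | lognormal ln-sd 1.0, measurement noise ln-sd 0.25 | FPKM spread and replicate noise |

Depth per scaffold per sex is a gamma-Poisson (negative-binomial) total
over the scaffold divided by its length, with mean depth_mean ×
copy_number/2; dispersion 0 gives the Poisson limit. A neo-X at
differentiation d uses the male multiplier (1 − d/2), a linear
interpolation between the two well-defined endpoints (equal coverage
while Y reads co-map; half coverage when they no longer do) — the
intermediate shape is this package's parameterization, as no
quantitative model of cross-mapping decay at a given neo-sex age exists.
Pileups contain only variant sites (homozygous sites carry no signal for
the caller): heterozygous sites at base_het_rate per bp per sex, plus
male-only divergent sites on neo-X scaffolds at xy_divergence_rate ×
retained_homology, with Binomial(depth, 0.5) allele splits and optional
uniform sequencing error. Expression plants the compensation mode
multiplicatively on sex-linked genes (male somatic X: 0.5× ancestral
without compensation, restored to 1× under male_up; female X halved only
under female_down; gonads never compensated), with testis-specific
(20× gonad) and ovary-biased (5×) genes planted per the configured
fractions. All randomness flows from one integer seed through numpy
SeedSequence spawn keys, one substream per generator, so any table can
be regenerated independently and byte-identically.

What the generator does *not* emulate — mapping bias between sexes,
repeat-driven coverage artifacts, GC bias, shared polymorphism between X
and Y, partial dosage compensation, and correlated expression noise —
bounds what green tests show: they demonstrate that the statistical
machinery recovers planted signals at realistic noise levels, not that
real libraries are free of the artifacts the upstream alignment and
filtering steps (out of scope here) exist to control.

## Problem sizes used in validation

The validation suite runs the detectors at the defaults above: 100
seeded genomes for X and Z recovery, 200 for type-I control, 100 each
for neo-X detection and its null, 50 per compensation mode for dosage
recovery, exhaustive enumeration to depth 12 for the SNP rule, all
rooted topologies to 5 tips plus seeded random trees to 8 tips for the
parsimony oracle, and 1,000 random 2×2 tables (total ≤ 200) for the
Fisher oracle. The acceptance script reports rates over 50–100 fresh
seeds per scenario.
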