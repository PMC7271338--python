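# Methods

## Problem and model

Thirteen neo-tetraploid rice sister lines derive from a cross of two
autotetraploid parents (a maternal line, 96025-type, and a paternal
line, Jackson-4x-type). Each sister chromosome is modelled as a mosaic
of maternal and paternal segments; on top of that mosaic, some loci
carry alleles found in neither parent. The pipeline infers the mosaic
from parent-differential markers, flags non-parental windows and
alleles, and keeps only the non-parental material conserved across the
whole sibship as candidate causal loci for the fertility improvement.

## Genotype representation

Tetraploid callers are routinely run in diploid mode, so allele dosage
in these call sets is unreliable. We therefore collapse genotypes to
alt-present / alt-absent / missing and never model dosage. All marker
logic uses positive evidence only: a sister *lacking* an allele that
only one parent carries is uninformative by default, because in a
tetraploid an absent call is confounded with dosage and calling
sensitivity. The stricter interpretation (absence supports the
alt-absent parent) is available behind `absence_informative` and is
exercised in tests, not used by default.

A reliable marker requires both parental genotypes called and the site
to pass the quality filter. The removal criterion for low-quality sites
is a configurable QUAL threshold, default 30 — a conventional
variant-quality cutoff; the analysis is insensitive to its exact value
on clean synthetic data, and it is exposed as `--min-qual` for real
call sets.

## Window typing rule

Windows are non-overlapping tiles (step = width = 10 kb by default;
the last window of each chromosome is truncated). For marker counts
(n_m, n_p, n_np):

1. total < `min_markers` (default 1) → **no-data**;
2. unique majority class required; ties → **ambiguous**;
3. majority support = top count / total must be ≥ `support_threshold`
   (default 0.75, inclusive — "at least 75%"); below → **ambiguous**;
4. a non-parental majority additionally needs n_np ≥ `min_np_markers`
   (default 5, i.e. more than four) → otherwise **ambiguous**.

The ≥5 screen applies only to the non-parental class: non-parental
calls are the rarest and most error-prone category, so they carry the
extra reliability requirement, while maternal/paternal windows are
typed from a single clean marker. Refusing to type ties (rather than
imposing a priority order) keeps the rule symmetric and test-visible.
Window counts are the primary reporting basis; merging adjacent
same-type windows into maximal runs is provided (`merge_runs`) as an
optional post-process because the shared-coverage arithmetic
(windows × 10 kb) is exact only at window granularity.

Coordinates are 0-based half-open internally (windows, BED output);
VCF/GFF/QTL interfaces are 1-based inclusive, converted with pos − 1.

## Concordance

Between two call sets, compared units are (variant key, shared sample)
pairs; a pair matches when both report the same presence state, and
pairs with a missing state on either side are excluded from the
denominator. The rate is 100 × matches / compared, rounded half-up to
2 decimals. Presence-state equality is the weakest match definition
consistent with how validation rates are used here.

## Intersections and co-localization

Shared non-parental windows/variants are strict intersections across
all sisters — one dissenting (or uncalled) sister removes a candidate.
Intersection is anti-monotone in the number of sisters (property-
tested). Variant-to-gene and variant-to-QTL mapping is
point-in-interval with 1-based inclusive interval ends, implemented
with interval trees and cross-checked against a brute-force double
loop in tests. A variant inside two overlapping genes counts once per
gene; nested/duplicate QTLs are counted independently by id. Effect
labels (nonsynonymous / synonymous) arrive in the VCF INFO field (tag
`EFF`); effect filtering and intersection commute, so either order
gives the same shared nonsynonymous set.

## Trait statistics

Summaries are mean ± SE (sd/√n, ddof=1). Correlations are Pearson on
per-line trait means; zero-variance traits produce NaN cells with a
warning rather than a silent 0. Contrasts are Welch (unequal-variance)
two-sided t-tests — the conservative default when only "t-test" is
specified and replicate pairing is unknown. Star coding: `**` for
p ≤ 0.01, `*` for 0.01 < p ≤ 0.05 (boundaries inclusive, matching the
conventional footnote ranges). On degenerate sd = 0 tables both group
variances vanish and the t statistic is undefined; we define p = 0
when the constant means differ and p = 1 when they agree, so star
coding remains total. All reported percentages and gram values are
rounded half-up to 2 decimals. For over-parent heterosis the better
parent is the larger mean, appropriate for yield-direction traits; a
per-trait direction map would be needed for traits where smaller is
better (e.g. heading date) and is deliberately out of scope.

The bundled knockout-trial table (`tetramosaic.datasets`) carries the
published group means ± sd for wild-type Huaduo1 and nine knockout
lines. Replicate tables built from those means with sd = 0 make every
contrast exactly the difference of printed means, which is what the
acceptance checks assert; with the published sds the same machinery
produces noisy, realistic tables.

## Synthetic-data generator

The generator emulates exactly the structure the analysis assumes:

- **Parental divergence.** Each parent receives private alt alleles at
  `parental_variant_rate` (default 2 × 10⁻³ /bp, giving ≈ 20
  informative markers per 10-kb window — comfortably above the typing
  thresholds, as in deep-coverage resequencing of divergent lines).
- **Mosaics.** Per sister chromosome, `recomb_breakpoints_per_chrom`
  (default 3) breakpoints are drawn uniformly and snapped to window
  boundaries by default, so every window is pure and truth/inference
  comparison is exact; a flag allows mid-window breakpoints, which
  deliberately creates ambiguous windows for testing. Segment origins
  are drawn independently with per-chromosome maternal probability
  `inheritance_bias` (default 0.5; the default config biases one
  chromosome to 0.95 to emulate the observed whole-chromosome skews).
- **Non-parental material.** Hotspots — intervals with a fixed number
  of variants present in every sister and neither parent — model the
  shared non-parental blocks; the default configuration plants 140
  single-window hotspots of 5 variants across 2 × 1 Mb chromosomes.
  Line-private novel variants occur at `private_novel_rate` (default
  10⁻⁵ /bp). Novel variants never collide with parental positions,
  keeping marker categories disjoint; parental variants are never
  placed inside declared hotspot intervals, because hotspots model
  distinct rearrangement blocks rather than windows of mixed ancestry
  — without this, parental markers would outvote the planted
  non-parental markers under the 75% rule and planted truth would be
  unrecoverable by construction.
- **Labels and outputs.** Novel and parental variants get
  nonsynonymous labels with probability `nonsyn_fraction` (default
  0.5). Output is VCF 4.2 (GT as 0/1 presence), byte-identical for a
  given seed.

What the generator does **not** emulate: read-level error, genotyping
error and missingness, allele dosage, linkage-informed recombination,
multi-allelic sites, indel realignment. Passing truth-recovery tests
therefore demonstrates the correctness of the classification,
window-typing and intersection logic under the model's assumptions —
not robustness to calling noise in real data, where ambiguous windows
and missing genotypes will occur and are handled by the uninformative/
ambiguous/no-data categories.

Trait tables are normal draws per group (mean, sd, ≥ 2 replicates);
expression matrices plant strictly-positive cells for designated
(gene, tissue) pairs over a uniform [0, baseline] background.

## Problem sizes and determinism

Default end-to-end runs use 13 sisters, 2 chromosomes × 1 Mb, ≈ 3,400
variant sites — a scale at which the full pipeline completes in about
a second while every rule is exercised (780 typed windows, 140 shared
non-parental windows, 700 shared variants). All randomness flows from
one top-level seed (numpy `default_rng`); re-running any stage with
the same config and seed produces byte-identical non-log outputs,
which the test suite verifies by hashing.

## Known limitations

- Ambiguous windows are reported, never rescued by neighbouring
  windows (no HMM smoothing across windows).
- The expression filter is presence/absence above a threshold, not a
  differential-expression test.
- QTL coordinates are taken at face value as 1-based inclusive
  intervals on the call-set assembly; no liftover is attempted.
- The t-tests treat replicates as independent; blocked field designs
  would call for a mixed model, which is out of scope.
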