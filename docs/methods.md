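# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that were genuinely open.

## Dosage screen

**Normalization.** For each informative marker the deviation is the
sample intensity minus the female median of that marker; a sample's
normalized value is the median of its deviations over the informative
set. The statistic is invariant to any per-marker additive shift
applied to the whole cohort, and robust to a minority of outlying
markers. On this scale a 2-copy (female-like) sample sits near 0 and
each missing copy subtracts one copy-signal unit; a normal male
(1 copy over the interval) sits near −1 unit.

**Sex-balance filter.** Median log2 ratio of a sample against the
sex-matched reference median, computed separately over X-flank and
Y-flank markers with PAR-associated markers excluded; a sample passes
iff both medians are within ±0.35 (default). Ratios are stabilized
with a pseudocount defaulting to a quarter of the overall flank-marker
median, because the ratio of two near-zero intensities (females on
Y-specific markers) is otherwise dominated by noise. Pass 0 for raw
ratios.

**Reference bands.** One bootstrap pass, no EM, for determinism: the
male and female medians anchor the 1- and 2-copy centers and their
difference estimates the copy-signal unit; samples are provisionally
assigned to the nearest center, and the central 95% interval
(nearest-rank order statistics: lower = ⌈0.025n⌉-th, upper =
⌈0.975n⌉-th) of each reference class forms the band. A Gaussian
mean ± 1.96σ option is available (`ci_method="gaussian"`). At least 40
reference samples per band are required. The deletion band defaults to
an interval centred on the extrapolated 0-copy level with half-width
max(1.5 × haploid band width, 0.15 × copy-signal unit). Two
alternatives were rejected: a band abutting the haploid lower endpoint
converts near-boundary 1-copy samples into deletion calls, and a width
proportional to the haploid band alone degenerates to an empty interval
on noise-free data.

**Classification semantics.** Band membership is a partition: every
sample receives exactly one call, UNCLASSIFIED when outside all bands,
EXCLUDED_IMBALANCE when the balance filter fails. Because the bands
are central 95% intervals, ~5% of every class falls just outside its
own band by construction; perfect accuracy is therefore only attainable
on noise-free data, and the test suite asserts exactly that (zero-noise
accuracy 1.0; at signal-to-noise 6, ≥90% per-class sensitivity and no
cross-class confusion).

**Incidence.** Percentages use the non-excluded same-sex samples as
denominator, matching the convention of reporting rates among
successfully haplogrouped men; raw ratios are retained unrounded and
rounding is presentation-only.

## Y-lineage assignment and dating

**Haplogroup assignment** scores every root-to-tip path of the
reference phylogeny by its number of derived calls; on the winning path
the reported label is the deepest branch with more derived than
ancestral calls among its defining SNPs. Ties go to the path with most
derived calls, then the lexicographically smallest label, making the
result independent of SNP input order. Derived calls on branches off
the chosen path are reported as conflicts rather than silently ignored.

**ASD dating.** Founder-anchored by default: the founder haplotype is
the per-locus modal repeat (ties broken toward the value nearest the
locus mean, then the smaller repeat, for determinism), and
T = (1/L) Σ_l ASD_l/μ_l, which is unbiased under the strict single-step
mutation model since E[(a−f)²] = μT per locus. The founder-anchored
form suits a star-like founder expansion; a pairwise variant
(mean pairwise squared difference / 2μ) is available via `pairwise=True`
for clusters without a clear founder. The quoted ± is the standard
deviation of the L per-locus ratios divided by √L — an across-locus
standard error that captures mutation-rate heterogeneity but not
genealogical correlation; it is recorded in the estimate's metadata.
Missing repeat calls are excluded per locus, not per sample.

**Default STR panel.** A 23-locus PowerPlex-Y23-style panel, tagged
11 SLOW / 12 FAST, with representative per-generation rates
(SLOW ≈ 0.0004–0.002, FAST ≈ 0.003–0.007). These are package defaults
standing in for locus-specific literature estimates; any rate table
with a `mu` column (and optional `panel` tags) can be supplied.

**SNP clock.** T = n/rate with the exact Poisson 95% interval from the
chi-square relation (lower = χ²(0.025, 2n)/2rate, upper =
χ²(0.975, 2n+2)/2rate). Coverage is verified by simulation.

## Junction analysis

Coordinates are 1-based along the 559-bp maximal alignment of the two
parental LTR6B elements, position 1 at the distal (5′) end. Gapped
alignment is restricted to the two variable-length sites ([CCACAC]
distal, [TTACAAGGTG] proximal); allowed total lengths are {551, 554,
559} bp and the observed length-allele sets are stored in the model
rather than derived, since not every combination occurs. A junction
type is an exact sequence identity — no mismatch tolerance — matching
how distinct junctions are enumerated in practice; published type names
claim their canonical sequences first and new types are numbered in
first-seen order (a sorted-canonicalization switch makes ids
input-order independent).

Crossover intervals are open intervals between the last
informative position in the distal-parent state and the first in the
proximal-parent state (X distal for an ePAR junction, Y distal for a
deletion junction, so reciprocal products at the same crossover yield
identical intervals). FIXED_ONLY mode uses fixed differences;
MAJOR_ALLELE mode adds positions where the parental major alleles
differ, which can only narrow the interval. Interleaved parental
states are flagged as possible gene conversion (zero tolerance) rather
than truncated, since NAHR exchanges can be complex.

The allele-sharing test cross-classifies shared-polymorphism sites by
whether the X-element minor allele equals the Y-element major allele
and vice versa, and applies a one-tailed Fisher exact test (exact
hypergeometric tail; degenerate margins give p = 1 by convention).

**Synthetic parental model.** The true parental element sequences are
not bundled; `refdata.default_ltr6b_model()` constructs a synthetic
pair carrying the published structural features (five fixed differences
within the first 100 bp plus one proximal fixed difference, 19
shared-polymorphism sites with an excess of X-minor = Y-major sharing,
the two length sites, X parent 551 bp / Y-PAR parent 559 bp). All
junction-analysis tests that depend on the element model run against
this synthetic pair; sequence-level results on real chromatograms will
differ in the exact positions but not in the operations' semantics.

## Origin counting and history

**Minimum origins.** Each junction type defines a presence/absence
character on the tips of the haplogroup tree; under irreversible
(gain-only, no-loss) parsimony the minimum number of independent gains
is the number of maximal subtrees whose tips are all present, summed
over types. Gain-only is the right model for a Y-linked structural
gain observed in disjoint haplogroups: a loss-permitting model would
collapse every pattern to one ancestral gain. Two caveats, verified by
brute force: the count is **not** monotone in presence (completing a
clade merges gains), and it is a lower bound on the true number of
events only when absences are real — an unsampled carrier tip or a
nested second event splits clades and inflates the count.

**NAHR rate.** Total generations surveyed by a phylogeny =
(total SNPs / mean root-to-tip SNPs) × (TMRCA in years / years per
generation); the rate is independent events divided by that total. The
default generation time is 31 years. Both quantities are returned
unrounded.

**X-linked Hardy–Weinberg.** The allele frequency is estimated from
pooled X chromosomes (one per male, two per female); the chi-square
sums over the five phenotype cells (male carrier/non-carrier, female
het/hom/ref) with df = 2 (five cells − two sex totals − one estimated
parameter). At very low allele frequencies the expected homozygote
count is far below 1 and the test is conservative (simulated rejection
~2–3% at the 5% level for q ≈ 2×10⁻⁴); it is calibrated at moderate
frequencies. An exact/Monte-Carlo alternative was considered and left
out of scope as the conservative direction cannot produce spurious
disequilibrium.

## PheWAS lite

Model dispatch is deliberately two-way: values ⊆ {0,1} → Firth
logistic, anything else → OLS; ordered-categorical handling is out of
scope. Firth regression maximizes l(β) + ½ log det I(β) by Newton
iteration with step-halving, convergence at modified-score norm 10⁻⁸,
50 iterations maximum; per-coefficient p-values are penalized
likelihood-ratio tests (each reduced model carries its own penalty),
preferred over Wald for separation robustness. Standard errors come
from the inverse penalized information. Complete-case analysis per
phenotype; covariates are caller-supplied (ancestry restriction and
same-haplogroup comparisons are both expressible as exposure/covariate
choices); Benjamini–Hochberg q-values are computed jointly across the
scan.

## Synthetic generators: what they emulate, and what they do not

- **Cohorts**: per-marker intensity = copy_signal × copies + Gaussian
  noise; male classes are mutually exclusive (the rare ePAR + deletion
  double carrier, which would be dosage-neutral, is not simulated);
  47,XXY males double the X-flank dosage while informative markers
  follow their true two-copy dosage. Not emulated: array batch
  effects, GC waves, per-probe affinity differences, genotype-cluster
  artifacts. Defaults follow the screened-cohort conditions where
  stated (60 informative markers, ePAR frequency 0.77%, deletion allele
  frequency 2.4×10⁻⁴); the intensity noise (0.08 copy-signal units per
  marker) is a package default chosen so that the per-sample median has
  clearly separated dosage classes — no cohort-specific noise values
  are published.
- **Genealogies**: star topology only (every chromosome independent
  from the founder), matching the founder-expansion setting in which
  ASD dating is applied; strict single-step symmetric mutation.
  Multi-step mutation and non-star coalescent structure are not
  simulated, so passing tests show estimator correctness under the
  model, not robustness to model violation.
- **Junctions**: a single crossover per event; each variable-length
  site is inherited wholesale from the parent contributing its first
  position (a crossover cannot be resolved within an indel). Gene
  conversion tracts are not generated (they are detected, not
  simulated).
- **Phenotypes**: Gaussian shifts and Bernoulli log-odds shifts,
  independent traits. No trait correlation or covariate structure
  beyond what the caller supplies.

## Problem sizes in the test suite

Simulation-backed checks run at desk scale: cohorts of a few hundred
to 30,000 samples, 50-seed ASD recovery at 100 chromosomes, 5,000
replicates for Poisson-interval coverage, 200 random trees (≤12 tips)
against the exhaustive parsimony oracle, 1,000 simulated junctions for
crossover round-trips, and 100-replicate FDR-control runs of 150 null
traits at n = 300. These sizes give comfortable Monte-Carlo margins
for the 2–3-standard-error assertions used.

## Known limitations

- Junction-type and crossover results on real data depend on the true
  parental catalog; the bundled model is synthetic (see above).
- The haplogroup tree walk is a simplification of full haplogroup
  callers: it assumes one defining-SNP set per branch and does not
  model genotyping error rates per SNP.
- ASD standard errors ignore the shared genealogy of sampled
  chromosomes and understate uncertainty for non-star clusters.
- The screen's band semantics cap attainable accuracy at the band
  coverage (95%) for noisy data by construction.
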