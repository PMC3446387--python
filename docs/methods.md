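# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Segmentation

### Model

Clone-level log2 ratios per sample are modelled as piecewise-constant
segment means plus independent probe noise. Circular binary segmentation
(CBS) estimates the segment partition recursively: the current stretch of
n probes is treated as a circle; for every pair of arc boundaries i < j
(with the arc (i, j] and its complement both holding at least `min_width`
probes, default 2) the pooled-variance two-sample t-statistic

    T(i, j) = (mean_arc − mean_comp) / sqrt(s²_pooled (1/m + 1/(n−m)))

is computed, and max |T| is referred to a permutation null obtained by
shuffling the stretch. If the permutation P-value is ≤ α (default 0.01)
the stretch is split at both arc boundaries (a 3-way split when the arc is
interior, so a focal event inside a flat chromosome is isolated in one
step) and the procedure recurses; otherwise one segment is emitted. Each
clone's "smoothed" value is its segment mean — by construction the sum of
n_probes × mean over segments equals the sum of the inputs, and no "undo"
pruning step is applied (segment means feed categorical thresholds
downstream, which do not benefit from merging near-equal neighbours).

Tie-breaking is deterministic: the scan runs in lexicographic (i, j) order
and keeps the first maximum. When the pooled variance is exactly zero with
distinct means (noise-free data) |T| is treated as infinite.

### Permutation P-values and sequential stopping

P-values use the add-one estimator P = (b + 1)/(k + 1), where b of k
permutations reached the observed max |T| (so P can never be zero). The
permutation stream for each tested stretch is seeded deterministically
from (base seed, stretch offset, stretch length); results therefore do not
depend on recursion order, and raising α can only add splits.

Permutations terminate sequentially rather than always running the full
`n_perm` (default 10,000):

* **no-split, exact** — once b reaches ⌊α (n_perm + 1)⌋ the full-run
  P-value is guaranteed to exceed α; the decision equals the full run's.
* **no-split, heuristic** — once b ≥ 10 with (b+1) > 4α(k+1), or b ≥ 25
  with (b+1) > α(k+1), the exceedance rate is above α with high
  confidence (a Besag–Clifford-style curtailment).
* **split** — at checkpoints of 100 permutations, if the running P is
  already ≤ α the split is accepted.

Only arcs whose true permutation P lies within sampling error of α can be
decided differently from an exhaustive run. A clearly flat stretch costs
~20 permutations and a clear change-point ~100, which is what makes a
313-sample × 2,000-clone cohort segmentable in about two minutes on one
CPU; exhaustive 10,000-permutation testing of every borderline arc takes
~15 minutes for the same cohort and changes no planted-truth result.

The O(n²) arc scan and the shuffle loop are compiled with numba.

### Detectability floor

A permutation test counts ties as exceedances, so in the noise-free limit
an event of w probes with identical values in an otherwise constant
stretch of n probes ties the null (both max |T| infinite) whenever a
shuffle happens to make the w values contiguous — probability ≈ n /
C(n, w). For w = 2 this is ≈ 2/n, which exceeds α = 0.01 for n < 200:
two-probe events in zero-noise data are formally undetectable at that
level. With realistic noise the atom at infinity disappears and short
events are ranked continuously.

### Outlier removal and rescaling

Isolated outlier probes are removed before segmentation: clone i is
flagged when it deviates from **both** genomic neighbours (same
chromosome, retained clones; a single neighbour at chromosome ends) by
more than k × MAD, where the MAD is the genome-wide 1.4826-scaled median
absolute deviation of the sample's retained ratios. k = 3 is a
conventional robust-outlier multiplier and is configurable; the
neighbour-deviation form follows the platform's published preprocessing
description, which does not print the multiplier. Removed probes are
excluded from segmentation and afterwards imputed with the mean of the
segment spanning their coordinates, flagged as imputed. Flagging all
clones is a degenerate-profile error.

Per-sample rescaling multiplies ratios by target_MAD / sample_MAD. The
default target is the **cohort median** of per-sample MADs: it equalises
noise across samples while preserving the overall log2 scale on which the
fixed −0.08 / 0.08 / 0.45 thresholds are defined (an absolute target would
silently recalibrate the state definitions). With a single sample, or a
zero cohort target (noise-free data), no rescaling is performed.

## Copy-number states and regions

Thresholds on the smoothed value: loss < −0.08, gain 0.08–0.45
(≈ 3–5 copies), amplification > 0.45 (> 5 copies), else no-change. The two
printed variants of the gain definition ("0.08 to 0.45" and "> 0.08 and
≤ 0.045") conflict; the second is an evident transposition of 0.45, and
the closed interval [0.08, 0.45] is adopted. Boundary values are assigned
away from no-change deterministically: −0.08 → loss, 0.08 → gain,
0.45 → gain. NaN values give a missing state. State calling is monotone in
the smoothed value.

Per-sample amplified intervals are maximal runs of consecutive amplified
clones (first clone start to last clone end). Recurrent cores are maximal
runs of ≥ `min_probes` (default 2) clones whose cross-cohort amplification
frequency reaches `min_fraction` (default two samples — the minimum for
"recurrent"). The smallest region of amplification (SRA) at a locus is the
intersection of the per-sample spanning intervals of amplified clones
overlapping the locus; three nested intervals therefore give the
innermost. If the spans do not intersect the highest-recurrence
overlapping core is returned with a warning. A sample is "amplified at the
locus" iff at least one clone overlapping the locus is in the
amplification state.

FISH classification per case: amplified if more than `cells_threshold`
(default 0.5) of nuclei carry a large signal cluster or more than 5
signals; otherwise gain if the median count is 3–5; otherwise no-change.
"Large signal cluster" has no numeric definition in the assay and is taken
as a per-nucleus boolean supplied with the counts.

## Expression integration

Probes must be detected (detection P < 0.01) in **strictly more than** 25%
of samples — 12 of 48 (25.0%) is excluded, 13 of 48 kept. Gene-level copy
number is the median smoothed value over clones whose interval overlaps
the gene (0-based half-open on both sides); genes with no overlapping
clone are reported missing and excluded from testing.

The overexpressed-when-amplified test groups samples by the **gene-level**
categorical state (not the locus-level flag) and compares expression with
a two-sided Mann-Whitney U test: exact null enumeration when both groups
have ≤ 8 observations and the pooled values are tie-free, the
tie-corrected normal approximation with continuity correction otherwise.
U is reported in the classical min(U₁, U₂) orientation. A gene is flagged
iff P < α (default 0.05) **and** the amplified group's median expression is
higher. Following the source analysis convention no multiple-testing
correction is applied to flags; Benjamini–Hochberg q-values are emitted as
a reference column. Pearson's r between the continuous smoothed values and
expression is reported per gene with the standard t-transform P-value
(computed but not interpreted for flagging).

## Clinicopathological association

2×2 tables use Fisher's exact test with the **minimum-likelihood two-sided
convention**: P is the sum of hypergeometric point probabilities at most
that of the observed table, compared in log space with a 1 + 1e-7 relative
tolerance, using exact log-factorial arithmetic. This convention — and not
the tail-doubling one — reproduces the published cohort-table values
0.0018 (grade), 0.0042 (ER), 0.5398 (HER2) and 0.01984 (CCNE1 × ER) from
their printed counts. A zero margin gives P = 1. r×c tables use the
Pearson chi-square test without continuity correction, df = (r−1)(c−1),
which reproduces the printed 0.0056 (subtypes), 0.0500 (CCNE1 × subtypes)
and 0.9801 (CCNE1 × HER2); a zero expected count is an error naming the
cell. The published table also prints two values that match neither
convention exactly: 0.0024 for ER−/HER2− vs the pooled other subtypes
equals the one-sided hypergeometric tail, and 0.1693 (grade × CCNE1)
matches no convention tried; both are reported by the module as computed
under its stated conventions and are not used as reference values.

Level collapsing (e.g. ER−/HER2− vs all other subtypes) is supported on
the contingency-table object; missing factor values are excluded and
counted.

## Functional screen

Survival fraction = mean target-well luminescence / mean siCON-well
luminescence on the same cell line, with the SEM propagated from replicate
variance by the delta method; at least two replicate wells per condition
and siCON wells on every plate are required. Selective lethality per gene
is a **Welch** unequal-variance two-sided t-test of pool survival
fractions between amplified and non-amplified lines (the group sizes are
as unbalanced as 2 vs 6, which pooled-variance t handles poorly); exact
within-group ties fall back to the pooled-variance test. A call is
*selective* when P < 0.05 with lower mean survival in amplified lines, and
*validated* when additionally ≥ 2 of the individual oligos are themselves
significant in the same direction — the deconvolution guard against
off-target pool effects (a pool with a single effective oligo is rejected).

qRT-PCR normalisation divides the target quantity by the geometric mean of
the two reference-gene quantities (TFRC and MRPL19 in the assay this
emulates; the geometric mean is standard practice for multi-reference
normalisation); knockdown = 1 − silenced/control on the normalised scale.

Dose-response curves are fit by bounded least squares to the 4-parameter
logistic survival = bottom + (top − bottom)/(1 + 10^(hill (log₁₀ d −
log₁₀ mid))) with top ∈ [0.8, 1.2], bottom ∈ [0, 0.5], |hill| ∈ [0.05, 10],
multi-start over the hill sign, convergence tolerances 1e-8. **SF50 is the
dose where the fitted curve crosses 0.5 absolute survival** (the assay's
printed definition), which differs from the curve midpoint (EC50, also
reported) whenever the curve is asymmetric; it is flagged when
extrapolated beyond the dosed range and reported as not reached when the
fit never crosses 0.5. SF50 scales exactly with the dose units
(equivariance), and group differences are compared on log₁₀ SF50 with the
same Welch test.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, with all
randomness flowing from one seeded generator through spawned sub-streams
per data product (clinical labels, copy-number events, probe noise,
expression, screen), so identical seed + config is bit-identical.

* **Genome**: eight chromosomes — the amplicon chromosome at its real
  59.13 Mb length plus seven 35 Mb autosome stand-ins — tiled contiguously
  (a tiling-path array leaves no uncovered gaps) by 2,000 clones at
  ~150 kb spacing, the spacing regime of the 31k-clone full-genome
  platform this emulates at reduced scale.
* **Amplicon**: a planted interval (default 27.8–32.9 Mb on chr19) or a
  list of sub-intervals for multi-core layouts. Each amplified sample
  draws one amplitude per event, uniform 0.6–1.2 — comfortably above the
  0.45 threshold, as in real high-level amplification.
* **Prevalence and clinical enrichment**: amplification probability is
  logistic, p_i = expit(b₀ + ln(OR_grade3)·[grade III] + ln(OR_ER−)·[ER−]),
  with b₀ calibrated by root finding so the cohort mean equals the
  configured prevalence (default 16/313). This reproduces 2×2 enrichment
  odds without rejection sampling. Default odds 20 (grade III) and 5.5
  (ER−) echo the published cohort's table: every amplified tumour there is
  grade III and the ER odds ratio is ≈ 5.5. Marginal clinical rates
  default to that cohort's margins (grade III 204/313, ER− 144/313, HER2+
  64/313); PR is drawn conditionally on ER. With enrichment odds of 1 the
  flag is independent of the covariates.
* **Background events**: per sample, 2 gains and 1 loss of 2–20 clones at
  random positions with amplitudes uniform 0.1–0.4 (negated for losses),
  never overwriting the amplicon — so segmentation always has real work to
  do and gene-level nulls can sit on gained segments without ever reaching
  the amplification state.
* **Noise model**: per-probe Gaussian noise (sd 0.12 — the platform's
  probe noise is not printed, so this is a free parameter exposed in
  config, chosen to make state calling ≈ 99% accurate as tiling BAC arrays
  are), isolated spikes at rate 0.005 with magnitude 1.5–3, and 1%
  polymorphic clones carrying independent ±0.2–0.6 shifts per sample,
  listed in a sidecar file so the filter is testable.
* **Expression**: driver genes respond linearly, expression = baseline +
  β × true clone-level value + N(0, 1); non-drivers are independent of
  copy number. β defaults to 4.0 so the planted driver copy-number/
  expression correlations land in the 0.6–0.8 range reported for real
  amplicon drivers (with β = 1 the correlation would be ≈ 0.2, unlike any
  published driver). One amplicon gene is planted as undetected (detection
  P ≥ 0.01 everywhere), emulating a transcript below array sensitivity.
* **Screen**: 8 cell lines (2 amplified), 3 replicate wells; viability =
  line base luminescence × survival effect × (1 + N(0, cv)), cv = 0.1.
  Driver siRNAs reduce survival to 0.4 only in amplified lines (pool and
  3 of 4 oligos effective); PLK1 is lethal everywhere (positive control);
  siCON has effect 1. An optional off-target decoy (pool lethal, single
  effective oligo) exercises the deconvolution guard; it is off by default
  because with only two amplified lines each ineffective oligo has a ~5%
  false-positive chance, making the decoy's rejection unreliable as a
  planted truth (the rule itself is unit-tested with constructed data).
* **Dose-response**: six ten-fold dilutions 10⁻⁴–10⁻⁹ M of a CDK2-inhibitor
  analogue; true curves are logistic with midpoints 5×10⁻⁸ M (amplified)
  vs 2×10⁻⁶ M, bottom 0.02, additive noise sd 0.05; the recorded truth is
  the absolute-50% dose of the true curve.

### What the generator does not emulate

Genomic waves and GC-content artefacts, spatially correlated probe noise,
tumour-purity and ploidy variation (amplitudes are drawn directly on the
log2 scale), subclonal events, replication-timing effects, batch structure
in expression, plate-position effects in screens, and transfection-
efficiency differences between lines. Passing the recovery tests therefore
shows the pipeline is correct under its own model assumptions — clean
piecewise-constant signals with independent noise — not that it is robust
to the systematic artefacts of real arrays; the preprocessing steps that
target those artefacts (print-tip loess, background subtraction) are
upstream of this package's inputs by design.

## Problem sizes used by the tests and the acceptance script

Unit tests run on scaled-down cohorts (≤ 40 samples, ≤ 400 clones,
permutation counts 100–2,000). The end-to-end study runs at the full
cohort scale — 313 samples × 2,000 clones, α = 0.01, n_perm = 10,000 with
sequential stopping, default seed — in both the acceptance test module and
`scripts/acceptance.py` (~2–3 minutes). Oracle checks cover 100 random
sequences (CBS), all 135,751 tables with total ≤ 40 (Fisher), all group
sizes ≤ 8 (Mann-Whitney), and 200 noisy curves (SF50). The chi-square
type-I property uses 2,000 simulated cohorts of 250 samples.

## Known limitations

* The sequential permutation scheme can decide arcs whose true permutation
  P is within sampling error of α differently from an exhaustive run.
* SRA computation intersects per-sample *spanning* intervals; a sample
  with two disjoint amplified intervals at the locus contributes its
  spanning interval including the gap.
* The Mann-Whitney asymptotic path is used whenever either group exceeds 8
  or ties exist; for tiny tied samples the exact-with-ties null is not
  enumerated.
* Absolute copy-number inference with purity/ploidy correction is out of
  scope; states use only the fixed log2 thresholds and the approximate
  copies interpretation.
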