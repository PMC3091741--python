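# Methods

## Model and procedure

The pipeline analyzes a 2 × 2 fixed design: denervation timepoint
(7 or 35 days) × treatment (vehicle or nandrolone), with one microarray per
animal and 3 arrays per cell by default. Probe-set intensities are assumed
non-negative with multiplicative (log-normal) technical variation: a
per-array scale factor (labeling/hybridization/scanning differences) and
residual noise that is approximately Gaussian on the log₂ scale. All test
statistics therefore run on log₂ of the normalized, floored intensities;
fold changes are ratios of geometric means, which are exponentials of
differences of log₂ means.

Stage order is **normalize → floor → filter → log₂ → test**. Normalizing
before flooring prevents the floor from biting at different effective
levels on differently scaled arrays. The floor (default 10 intensity
units) exists because ratios and log transforms are meaningless at
background; it also implies every downstream value is strictly positive.

### Normalization

Each array is multiplied by `reference / median(array)`, where `reference`
is the median of the per-array medians of the input matrix. The operation
is idempotent, and rescaling any array (or the whole matrix) changes the
output by at most one global factor — the data-derived reference — never
the ratios between entries. Every downstream statistic (variability
filter, F-test on log₂ differences, fold changes, heat-map ratios) is
invariant to that global factor, which is the invariance that matters; the
absolute scale of the normalized matrix is intentionally kept in the units
of the input rather than fixed to an arbitrary constant.

### Variability filter

A probe is kept iff at least `ceil(min_fraction × n_arrays)` arrays differ
from the probe's median (across all arrays) by at least `fold_threshold`
on the ratio scale, `max(v/m, m/v) ≥ threshold`, boundary inclusive.
Defaults: 20 % and 1.5-fold. "Different" is deliberately multiplicative —
fold language is about ratios, not differences. The count threshold is a
ceiling so a fractional requirement is met by whole arrays; the product
`min_fraction × n_arrays` is rounded at the 9th decimal before the ceiling
so binary float representation (0.2 × 10 = 2.0000…04) cannot demand an
extra array. A fully floored (constant) probe deviates nowhere and is
excluded by construction. The filter is applied once, globally, on all
arrays; the same kept set feeds every contrast.

### Contrasts and fold changes

Each contrast is a two-group one-way F-test — equivalent to the
pooled-variance t-test — rather than a four-group omnibus, because the
analysis asks per-comparison questions (drug at 7 d, drug at 35 d, time in
vehicle). Significance is strict `p < α`, α = 0.05 for the drug contrasts
and 0.01 for the time contrast (the time comparison yields many more genes
and the stricter level keeps the confound list specific). No
multiple-testing correction is applied in the standard analysis — the
design deliberately trades specificity for sensitivity at these small
n — but a Benjamini–Hochberg flag is available as a clearly labeled
extension (off by default). With zero within-group variance the p-value
degenerates: 1 when the means agree, 0 (with a warning) when they differ;
this arises in practice only for fully floored probes.

Signed fold change: `r = geomean(a)/geomean(b)` reported as `+r` if
`r ≥ 1`, else `−1/r`, so |FC| ≥ 1 always and a halving reads −2.0.

Probe sets are collapsed to unique known genes (upper-cased symbols;
probes without a symbol are dropped) by minimum p-value, ties broken by
larger |fold change| then lexicographic probe ID. Gene-level analysis
refuses to run without an annotation rather than silently treating probes
as genes.

### Pool algebra

Pools are keyed by gene symbol. The concordant subtraction removes from
the 35-day drug pool (D) exactly those genes present in the time pool (E)
with the same direction of change — direction only, sign of the fold
change, never magnitude. Genes moved in *opposite* directions by time and
drug stay: their drug response cannot be a time artifact. The resulting
identities (B ∪ removed = D, B ∩ removed = ∅, C = A ∩ B) are enforced at
summary time and property-tested.

### Validation statistics

*ANOVA* is the textbook fixed-effects sum-of-squares decomposition.
*Newman–Keuls* sorts the group means, tests each pair at the critical
value of the studentized range for the number of means spanned
(`q_crit(span, df_within, α)`, computed from the studentized-range
distribution by numerical integration of its CDF, accurate to the
published 5 % tables to two decimals for span ≤ 10, df ≤ 120), and applies
step-down blocking: every pair nested inside a non-significant range is
declared non-significant untested. Unbalanced pairs use the Kramer
standard error `sqrt(MSE/2 × (1/nᵢ + 1/nⱼ))`; the study's groups (n = 7–8)
are near-balanced, and this form reduces anticonservatism when they are
not. *Regression* p-values are two-sided, from
`t = r·sqrt((n−2)/(1−r²))` on n−2 df.

*2^−ΔΔCt*: triplicate Ct values are averaged arithmetically on the Ct
scale first; ΔCt = mean Ct(target) − mean Ct(18S); ΔΔCt is anchored to the
arithmetic mean ΔCt of the reference **group** (7-day vehicle), not a
single calibrator sample, so the reference group's geometric-mean fold is
exactly 1. Amplification efficiency is fixed at 2; efficiency correction
and triplicate outlier rejection are out of scope. Any per-sample additive
Ct shift applied equally to target and reference gene (loading/pipetting
differences) cancels exactly.

*Heat-map matrices* divide by the **arithmetic** mean of the vehicle group
at the timepoint, not the geometric mean — display convention and test
convention are deliberately distinct and both implemented as such.

## Synthetic data: what it emulates, what it does not

`generate_expression` plants, on top of log-normal baselines
(log₂ mean 8, sd 1.5), per-array log₂ scale factors (sd 0.2 — planted so
that normalization is load-bearing in tests, not decorative) and residual
log₂ noise (sd 0.15):

* `n_drug7` = 124 genes shifted in the 7-day nandrolone arrays,
* `n_drug35` = 122 genes shifted in the 35-day nandrolone arrays and *not*
  time-confounded (the truth for Pool B),
* `n_shared` = 20 genes shifted at both timepoints (truth for Pool C);
  same direction at both by default, with a flag for sign flips such as
  the Egr-family behaviour seen in real data,
* `n_time` = 318 genes shifted in all 35-day arrays (truth for Pool E), of
  which `round(fraction_concordant × n_time)` = 154 also receive a 35-day
  drug effect in the same direction — the confounded genes the
  subtraction exists to remove. Planted Pool-D truth is therefore
  122 + 154 = 276.

Planted effects default to 3 log₂ units (8-fold). Defaults mirror the
study's scale throughout; every generator is a pure function of
(config, seed). By default each gene is represented by exactly one probe
set, keeping planted counts identical at probe and gene level; a
probes-per-gene distribution is configurable, with the caveat that min-p
collapsing over m probes inflates a gene's null rejection rate to
1 − (1 − α)^m.

Not emulated: probe-level sequence effects, intensity-dependent variance
(the noise sd is constant in log₂), spatial artifacts, batch structure
beyond a scalar per-array factor, and annotation error. Passing tests on
synthetic data therefore validate the statistical machinery and the set
algebra, not robustness to those real-data pathologies.

`generate_ct_table` builds triplicate Ct wells with a per-sample loading
shift shared by target and reference gene (so the ΔΔCt math must cancel
it); `generate_weights` produces gram-scale muscle weights
(`mean 0.9 g, sd 0.12 g`, the order of a denervated rat gastrocnemius)
with a chosen expected correlation to a gene's expression via
scaled-signal-plus-noise.

## False positives in recovered pools

Because filtering is global, every kept probe is tested in every contrast,
and the uncorrected α = 0.05 calls admit ≈ 5 % false positives among the
kept genes that are null *for that contrast*. Two structural consequences,
visible in any honest simulation and quantified by `scripts/acceptance.py`:

* recovered pools A and B exceed their planted sizes by roughly
  `α × (kept genes null for that contrast)` — about 4–5 % at the default
  conditions;
* the intersection pool C is inflated *super*-proportionally: a gene truly
  in B that is falsely flagged in the 7-day contrast lands directly in
  A ∩ B (and vice versa), so C ≈ 20 planted + ≈ 10 such cross-contrast
  false positives at the default conditions, even though the 20 planted
  members are recovered essentially always. This is a property of the
  uncorrected two-contrast design itself, not of the implementation; the
  truth-ledger-restricted count (reported alongside) sits at the planted
  20.

The pooled false-discovery rate across all five pools against the truth
ledger is ≈ 7 % at the default conditions, well under the 20 % working
bound documented for this design.

## Numerical choices

* Ratio comparisons in the filter are plain `>=` on IEEE doubles; the
  boundary fixtures (exactly 1.5-fold) are exactly representable.
* Tables are written with 17 significant digits and re-parsed through
  correctly rounded string→double conversion, making write/read
  round-trips bit-exact.
* The studentized-range distribution is evaluated through its CDF
  (numerical integration); critical values agree with published 5 % tables
  to two decimals over span ≤ 10, df ≤ 120.
* Problem sizes in the test suite are chosen to keep the full suite around
  half a minute: 10,000-probe matrices for calibration and recovery
  (20 seeds), a 15,000-probe fixture for the end-to-end determinism check,
  exact permutation tests at n = 5 + 5.

## Known limitations

* Starts from probe-set expression values; CEL-level summarization (MAS5/
  RMA) is out of scope, so numeric agreement with any particular
  summarization of a real deposited dataset is not guaranteed.
* GO/pathway enrichment of the pools depends on external knowledge bases
  and is out of scope.
* The Newman–Keuls procedure controls error rates only weakly by modern
  standards; it is implemented because it is the study design's post hoc,
  not as a general recommendation.
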