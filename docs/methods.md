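# Methods

## Model and rationale

`stratmr` implements two-sample summary-data Mendelian randomization under
the standard instrumental-variable assumptions: instruments associate with
the exposure, are independent of confounders, and affect the outcome only
through the exposure. The package's distinctive step is *biological-effect
stratification*: biomarker-raising alleles are partitioned by the sign of
their association with a third, downstream indicator trait that indexes the
biomarker's established physiological action. When a biomarker level can
rise either because its action is greater or because tissues resist it, the
instrument set mixes two sub-populations with different causal effects on
the outcome; the pooled IVW estimand is then a weight-average of the two and
can support conclusions true of neither class. Stratification by indicator
sign separates the classes before estimation.

Classification uses the *sign* of the indicator beta only, on records
oriented to the exposure-increasing allele. No p-value gate is applied to
the indicator association: the classification criterion is directional
concordance, and gating on significance would discard exactly the
instruments whose indicator effects are modest but systematic. A record with
a missing indicator association, or an indicator beta of exactly zero, is
unclassified — a direction cannot be asserted — and participates only in the
pooled analysis.

## Pipeline order

select → proxy → align → orient → Steiger → stratify → estimate. Steiger
filtering precedes stratification so that each stratum's estimate is also
directionally filtered; both filters operate on oriented records, and the
order is logged with per-stage counts. Conservation holds at every stage:
each selected instrument ends in the harmonized set or in the provenance log
with a drop reason, and stratum sizes partition the post-Steiger set.

## Harmonization choices

- Instrument selection is strict: P < 5×10⁻⁸ (boundary excluded).
- Allele alignment resolves swapped labels (beta negated, eaf complemented)
  and strand flips (labels complemented, no sign change). Palindromic A/T
  and G/C variants are resolved by allele-frequency concordance and dropped
  as ambiguous when either eaf is missing or within 0.5 ± 0.08 (window
  configurable) — the conservative default, since strand cannot be read from
  labels alone.
- LD proxies (both outcome and indicator tables) require known r² strictly
  above 0.7 within 1 Mb; the best candidate maximizes r², then minimizes
  base-pair distance, then takes the lexicographically smallest id, making
  proxy choice a deterministic total order. A proxy with a different variant
  id carries no allele-label information relative to the index SNP, so its
  beta is oriented by eaf concordance (high-LD pairs have nearly equal
  frequencies); missing or exactly-0.5 frequencies drop the proxy as
  ambiguous. Proxied records keep the index variant's exposure association.
- Records with β̂_X = 0 have no defined exposure-increasing allele and are
  dropped (retained in provenance).
- Inputs are assumed to be pre-resolved independent signals; no LD clumping
  is performed.

## Estimators

IVW is the weighted regression of β̂_Y on β̂_X through the origin with
weights 1/se²(β̂_Y). The random-effects variant (the default) multiplies the
fixed-effect standard error by max(1, √(Q/(L−1))) — multiplicative
over-dispersion floored at one so the reported uncertainty is never smaller
than the fixed-effect uncertainty. IVW p-values use the normal distribution;
a single instrument degenerates to its Wald ratio.

MR-Egger adds a free intercept (mean directional pleiotropy) and requires
≥ 3 instruments and a common orientation convention; its standard errors
carry the analogous max(1, √(Q_E/(L−2))) scale and its p-values use t with
L−2 df. Both closed forms are verified against a generic weighted-least-
squares solver to 1×10⁻¹⁰ relative error in the test suite.

The weighted median interpolates the inverse-variance-weighted empirical
ratio distribution at 0.5 using mid-cumulative weights
s_j = (Σ_{k≤j}w_k − w_j/2)/Σw; the penalized variant first down-weights
instruments by w*_j = w_j·min(1, 20·p_j), p_j the upper χ²₁ tail of
q_j = w_j(ratio_j − β̂_WM)². Standard errors come from a seeded parametric
bootstrap (1000 draws by default) resampling each ratio from
N(ratio_j, se²_j); the penalization is recomputed inside each bootstrap
draw. The penalty constant 20 and the bootstrap scheme follow the standard
published formulation of these estimators.

Heterogeneity is Cochran's Q on the model's fitted values with χ² reference
(L−1 or L−2 df) and Higgins' I² = max(0,(Q−df)/Q)·100. The I² reported is
heterogeneity I², not the Egger instrument-strength I²_GX (an alternative
reading of "I² statistic" in this literature); the Wald-ratio se uses the
first-order delta method se(β̂_Y)/|β̂_X|.

Validity and significance: IVW is flagged invalid when the Egger intercept
has P < 0.05 (strict); when Egger is refused for too few instruments the
flag is "egger-unavailable" and IVW is not auto-invalidated. Headline calls
use the Bonferroni family-wise threshold α/(n_exposures·n_outcomes) —
0.05/(2·2) = 0.0125 for a two-exposure, two-outcome design — with raw
p-values reported alongside.

## Steiger filtering

Variance explained is approximated from summary statistics as
r² = z²/(z²+n−2), z = β̂/se — the squared correlation implied by a
t-statistic of that size at sample size n. The default rule compares point
estimates (kept iff r²_exposure > r²_outcome) with no significance gate,
matching a binary "stronger effect" criterion; records without usable
sample sizes are dropped (configurably kept with a warning). The comparison
is deterministic given identical inputs.

## Synthetic data generator

The generator emulates the three linked summary-statistics tables of a
stratified two-sample MR study with known truth. Conditions it encodes:

- **Traits in standardized units**, so the per-allele beta's sampling se has
  the closed form 1/√(2·eaf(1−eaf)n) and simulated noise is exactly
  calibrated (verified to 5% in the suite).
- **Samples**: 100k exposure, 200k indicator, 100k outcome by default —
  biobank-scale, mirroring the study designs this method targets.
- **Instruments**: 50 independent variants, MAF ~ U(0.05, 0.5), exposure
  effects γ_j ~ N(0, 0.1²) — strong instruments (median |z| ≈ 14 at n=100k),
  appropriate for genome-wide-significant, pre-clumped signals.
- **Two forward classes** with opposite indicator-effect signs
  (±0.5 per unit exposure effect) and class causal effects θ_A = −0.5,
  θ_B = +0.3 — the constellation in which pooled and stratified analyses
  disagree, and the default study condition for the recovery suites.
- **Directional pleiotropy** α_j ~ N(μ_α, σ_α²) is defined *relative to the
  exposure-increasing allele* (the outcome effect gains sign(γ_j)·α_j).
  This matters: pleiotropy drawn on an arbitrary allele coding is partially
  randomized by orientation and no longer targets μ_α. α is independent of γ
  (InSIDE) unless the correlated switch is set.
- **Reverse-causal variants** receive a direct outcome effect
  δ_j ~ N(0, 0.3²) and an induced exposure effect 0.3·δ_j (configurable
  attenuation). The sd 0.3 makes these outcome-first effects clearly
  detectable at biobank scale, which is the regime Steiger filtering
  addresses — a "reverse-causal" variant whose outcome effect is
  statistically null has no measurable direction to recover.
- Allele pairs are drawn from the non-palindromic codings; the three
  studies' noise draws use independent child seeds (two-sample
  independence), and identical seeds reproduce tables bit-for-bit.

What the generator does **not** emulate: LD between causal signals (the LD
reference is a block-diagonal stand-in for proxy-search testing only),
winner's-curse in instrument discovery, sample overlap between studies,
allele-frequency differences between cohorts, non-linearity, and
collider-adjustment artefacts. Passing recovery tests therefore demonstrates
correctness of the estimators and filters under their own assumptions, not
robustness to these real-data complications.

## Validation-suite design notes

- Estimator recovery and type-I suites analyse all simulated variants
  (selection threshold 1.0): with the default strong instruments,
  genome-wide selection changes nothing materially, and the suites isolate
  estimator behaviour from selection effects.
- The Egger-intercept recovery suite *does* select at P < 5×10⁻⁸. On weak
  instruments, orientation by the observed exposure-effect sign occasionally
  flips a record relative to its true orientation, randomizing the
  pleiotropy direction and attenuating the mean intercept; genome-wide
  selection keeps only instruments whose orientation is essentially certain,
  which is also the pipeline's actual design.
- Type-I calibration targets the fixed-effect IVW test. The random-effects
  default floors its dispersion scale at one and is therefore conservative
  by construction (empirical rejection ≈ 0.04 at the 0.05 level in our
  measurements); the fixed-effect variant is the sharp calibration check.
- The Steiger discrimination suite uses equal samples across studies and a
  3× outcome/exposure effect ratio; the acceptance script reports it at
  n = 100,000 per study, where the forward-removal rate is stable, while the
  test suite also exercises n = 50,000.
- Monte-Carlo suite sizes (200 replicates for recovery/coverage/intercept,
  1000 for type-I, 400 variants for Steiger) give Monte-Carlo standard
  errors comfortably below the assertion tolerances while keeping the whole
  suite fast.

## Degenerate inputs and numerical choices

Zero instruments yield structured "no-instruments" results; Egger with < 3
instruments refuses with "insufficient-instruments"; empty strata are
allowed. Simulated p-values are clipped to [1e-300, 1] to respect the (0,1]
table invariant. Report serialization uses repr-precision floats, so
identical configurations produce byte-identical outputs, and table round
trips are exact. Weighted-median interpolation uses stable sorting, making
all estimators invariant to instrument order.

## Known limitations

Real-data complications listed above are out of scope, as are MR-PRESSO,
mode-based, multivariable and non-linear MR, LD clumping, genome-build
liftover, and multi-cluster decompositions of instruments beyond the binary
bioaction/resistance split. The indicator-sign dichotomy itself is a
simplification: instrument classes may be finer-grained than two, and an
indicator trait is a proxy for mechanism, not a measurement of it.
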