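# stratmr

Two-sample Mendelian randomization (MR) with **biological-effect
stratification** of genetic instruments, Steiger directionality filtering,
and pleiotropy-robust estimation — plus a synthetic summary-statistics
generator so the whole pipeline can be validated without any external GWAS
data.

## The problem

A higher circulating biomarker level is biologically ambiguous: an allele
that raises fasting insulin may mark greater insulin *secretion and
bioaction*, or *insulin resistance*; an allele that raises IGF-1 may mark
IGF-1 bioaction or IGF-1 resistance. A naive MR analysis that pools all
biomarker-raising alleles estimates a mixture of two different causal
quantities and can point in a direction that is true of neither.

`stratmr` stratifies biomarker-associated instruments by the **sign of their
effect on a downstream indicator trait** that indexes the biomarker's
established action (e.g. fasting glucose for insulin, childhood height for
IGF-1): a biomarker-raising allele whose indicator effect is concordant with
the biomarker's known action tags bioaction; a discordant allele tags
resistance. Causal effects are then estimated per stratum.

## Methods at a glance

Given harmonized per-SNP associations β̂_Xj (SNP–exposure), β̂_Yj
(SNP–outcome), β̂_Zj (SNP–indicator), all oriented so the effect allele
increases the exposure:

- **IVW**: β̂ = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂²_Xj with w_j = 1/se²(β̂_Yj);
  random-effects se multiplies the fixed-effect se by max(1, √(Q/(L−1))).
- **MR-Egger**: weighted regression of β̂_Yj on β̂_Xj with a free intercept;
  the intercept estimates directional pleiotropy, and a significant intercept
  (P < 0.05) invalidates the IVW estimate.
- **Weighted median / penalized weighted median**: the 50% point of the
  inverse-variance-weighted Wald-ratio distribution, optionally with weights
  w*_j = w_j·min(1, 20·p_j) down-scaling outlying ratios (p_j the upper χ²₁
  tail of the ratio's heterogeneity contribution); bootstrap standard errors.
- **Steiger filtering** removes instrument j when
  r²(outcome) > r²(exposure), with r² = z²/(z²+n−2) — reverse-causal
  variants explain more variance downstream than upstream.
- **Harmonization**: genome-wide-significant instrument selection
  (P < 5×10⁻⁸, strict), allele alignment with strand-flip and palindromic
  (eaf-concordance) resolution, LD-proxy substitution (r² > 0.7 within 1 Mb,
  best-r² / nearest / smallest-id tie-break), orientation to the
  exposure-increasing allele, and full provenance accounting.
- Cochran's Q, Higgins' I², Bonferroni family-wise thresholds, and funnel /
  dosage plot datasets round out the diagnostics.

## Worked example

Simulate a 50-variant study in which variant class A (causal effect
θ_A = −0.5 on the outcome, positive indicator effect) and class B
(θ_B = +0.3, negative indicator effect) are mixed, then analyse it:

```bash
stratmr simulate --seed 7 --out sim
cat > analysis.yaml <<EOF
exposure_path: sim/exposure.tsv
indicator_path: sim/indicator.tsv
outcome_path: sim/outcome.tsv
ld_pairs_path: sim/ld_pairs.tsv
ld_positions_path: sim/ld_positions.tsv
p_threshold: 5.0e-8
labels: {positive: resistance, negative: bioaction}
seed: 7
EOF
stratmr run --config analysis.yaml --out results
stratmr report --results results
```

which prints (abridged):

```
 stratum      label method  n_snps      beta       se          pval
     all        all    IVW      34 -0.194781 0.069661  5.171704e-03
positive resistance    IVW      20 -0.506298 0.014579 3.109357e-264
negative  bioaction    IVW      14  0.309636 0.013524 5.113917e-116
```

The pooled ("all") IVW estimate, −0.19, lies between the two class truths
and describes neither; the stratified estimates recover −0.5 and +0.3 with
tight confidence intervals. The heterogeneity column (not shown) makes the
same point: the pooled set has I² ≈ 99%, the strata far less. This is the
quantitative form of the argument for stratifying biomarker instruments by
their downstream biological effect before causal interpretation.

The same stages are scriptable in Python (`stratmr.simulate`,
`stratmr.harmonize`, `stratmr.filtering`, `stratmr.models`,
`stratmr.pipeline`) and as individual CLI steps
(`stratmr harmonize | filter | estimate`).

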