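# Methods

## Scope and data model

The package analyses dichotomised risk exposures for hyperuricaemia
(HU; serum urate ≥ 0.42 mmol/L, both sexes, inclusive) at three levels:
attributable fractions from a multivariable logistic model, percent
variance explained from a multivariable linear model, and causal
effects of exposures on serum urate from two-sample Mendelian
randomization (MR) on GWAS summary statistics. Individual-level inputs
are plain cohort tables (TSV); summary statistics use the de-facto
whitespace-delimited GWAS dialect (SNP, CHR, POS, EA, OA, EAF, BETA,
SE, P).

All fitting is organised as model/results pairs:
`AttributableFractionModel → AFResults`,
`UrateVarianceModel → UrateVarianceResults`, and MR estimator functions
returning `MREstimate`/`MVMRResult` objects; a thin `urateaf` CLI and
`run_pipeline` orchestrate the stages.

## Exposure coding

Boundary conventions are fixed: HU inclusive (≥ 0.42 mmol/L),
overweight/obese inclusive (BMI ≥ 25 kg/m²), age inclusive (≥ 50 y),
alcohol strict (> 1 drink/week), genetic risk dominant (≥ 1
urate-raising allele). Diet is consumed as a precomputed adherence
score with a configurable non-adherence cutoff (default: score below
0.8, i.e. the top quintile of a uniform score counts as adherent) —
the questionnaire scoring that produces such scores is out of scope,
and whether published cutoffs were quantile- or guideline-based is not
recoverable, so the cutoff is exposed as a parameter rather than
guessed. In the gout cohort, *absence* of urate-lowering therapy is the
risk state and age is dropped from the default model (it confers no
risk there); both are switches.

Exclusion profiles mirror the four cohort designs: `us_population`
(age < 18, kidney disease, gout, urate-lowering therapy, energy intake
outside 600–4200 kcal/day, one of each first-degree pair),
`ukb_recall` (energy > 18,000 kJ women / > 20,000 kJ men, kidney
disease, kin), `ukb_ffq` (kidney disease, kin), and `gout` (keep only
self-reported gout or urate-lowering-therapy users). Kin pairs with
kinship coefficient > 0.177 lose one member; resolution prefers gout
cases in the gout profile (pruning runs before the case filter so the
preference can act), otherwise the member with non-missing urate, then
the first by id. Missing data are handled complete-case per model, with
dropped-row counts retained for audit.

## Attributable fractions

Per exposure, the odds ratio comes from the full multivariable
logistic model (never a marginal 2×2 table), fitted by Newton-IRLS;
rank-deficient designs raise an error naming the collinear columns,
and separation or non-convergence raises rather than silently
reporting. PAF = *f*<sub>cases</sub>(OR − 1)/OR; negative values
(protective exposures) are reported as-is. Per-allele PAFs fit HU on
raw dosages jointly and use the risk-allele frequency among case
chromosomes; fitted ORs < 1 are re-oriented to the urate-raising
allele.

The counterfactual AF of a set *S* is (P̄ − P̄₀)/P̄ with P̄₀ the mean
fitted probability after zeroing the exposures in *S*. AAFs are the
Shapley values of this set function: exact via the subset formula for
k ≤ 9 exposures (2ᵏ memoised prediction passes; the design maximum
here is 8), Monte-Carlo permutation averaging above. In exact
arithmetic the AAFs sum to AF(all); the implementation reproduces this
to ~1e-12. The Monte-Carlo sampler stratifies: when all k! orderings
are enumerable (k ≤ 7) and the permutation budget covers them, the
budget is spread evenly across orderings and only the remainder is
sampled, which removes almost all sampling variance at small k.

Model-based counterfactual prediction (rather than stratified
empirical rates) is used because the AAF must be adjusted for all
other exposures and empirical stratification over 7 binary factors is
infeasible.

Confidence intervals for OR/PAF/AAF are nonparametric bootstrap:
individuals resampled with replacement, the whole pipeline refitted
per replicate, percentile 2.5/97.5 bounds; replicates lost to
separation are counted and a flag is set when more than 10% drop. The
bootstrap (not the delta method) is used for all three statistics for
internal consistency. Minimum 200 replicates; 1000 is the default
recommendation.

## Variance decomposition

OLS of continuous serum urate (mmol/L) on the coded exposures; betas
are adjusted urate differences between risk groups with t-based 95%
CIs. Percent variance explained is the classical partial *R*²
((SSE₋ₑ − SSE)/SSE₋ₑ × 100, equal to the squared partial correlation);
the squared semi-partial form ((SSE₋ₑ − SSE)/SST) is available behind
a flag since the estimator used for the published label is
tool-specific. The same complete-case rows feed both the logistic and
linear models so the two tables describe identical samples. A
structural property worth noting: summed per-allele PAFs of a variant
panel can exceed 100% while partial-*R*² shares of the same variants
cannot — both behaviours are exercised in the test suite.

## Mendelian randomization

Instrument selection: genome-wide significance 5×10⁻⁸ (configurable),
≥ 3 surviving SNPs required, greedy distance pruning keeping the
smallest exposure p-value within a 500 kb window (deterministic
tie-break by position then id). Harmonization intersects on SNP id,
flips the outcome beta when effect/other alleles are swapped, retries
under strand complement, drops irreconcilable records with a reason,
drops palindromic (A/T, G/C) variants by default, and finally orients
every pair to the exposure-increasing allele — MR-Egger is sensitive
to this orientation, IVW and the weighted median are not.

Estimators (J = number of instruments):

* **IVW** — weighted regression of outcome on exposure betas through
  the origin, weights 1/se²_out; Wald ratio at J = 1; Cochran's Q with
  χ²(J−1) heterogeneity p.
* **MR-Egger** — the same regression with a free intercept
  (directional pleiotropy); t-based p-values on J − 2 df.
* **Weighted median** — per-SNP ratios ordered, weights
  β²ₓ/se²_out, midpoint-interpolated 0.5 quantile; SE by parametric
  bootstrap of both beta sets (default 1000 draws, seeded). Consistent
  while valid instruments hold > 50% of the weight.

Standard errors for IVW/Egger use multiplicative random effects with a
floor at the fixed-effects SE (scale √(Q/df), never < 1); fixed
effects are available via a flag since the published flavour is
unstated. The causal decision rule takes all three: IVW p < 0.05/n
(n = 87 habits screened in the motivating analysis; 0.05/87 =
5.747×10⁻⁴), weighted-median p < 0.05, Egger intercept p > 0.05.

**Multivariable MR** maximises the Gaussian likelihood in which
observed exposure betas are noisy measurements of latent true betas
and the outcome beta is Normal(Σₖ θₖ ξₖ, se²_out). Profiling the
latent betas collapses each SNP's contribution to
r²/(se²_out + Σₖ θ²ₖ se²ₓₖ) with r the outcome residual; the Gaussian
log-variance term is retained because without it the criterion is
unbounded whenever an exposure column carries no signal (θₖ → ∞ then
zeroes every residual at vanishing latent cost). θ is optimised by
Nelder-Mead from the weighted-regression start; SEs come from the
finite-difference observed information. Exposure measurement errors
are treated as independent across exposures (two-sample setting). A
weighted multivariable regression estimator is always computed
alongside as a cross-check, and near-collinear exposure beta columns
trigger a warning. Calibration under the full-mediation null was
verified by simulation (z-score s.d. ≈ 0.97).

**Bidirectional MR** runs IVW in both directions with independently
selected instruments and attaches a correlated-pleiotropy flag when
both p-values pass the configured threshold; no causal verdict is
implied. The strict-vs-ambiguous sensitivity comparison reports paired
estimates, sign concordance and Spearman correlation.

## Synthetic data

The cohort generator is linear-additive on the mmol/L scale:
urate = intercept + Σ(dosage × per-allele effect) + Σ(indicator ×
exposure effect) + Gaussian noise, with genotypes binomial(2, freq)
(Hardy–Weinberg) and raw columns (drinks/week, adherence score, BMI,
age) emitted so that coding at the documented thresholds recovers the
generating indicators exactly. Defaults emulate a UK-style
general-population cohort: male fraction 0.43, BMI 27.4 ± 4.7, age
56.7 ± 8, urate-raising allele frequency 0.77 with 0.023 mmol/L per
allele, exposure effects of 0.075 (male), 0.040 (BMI ≥ 25), 0.049
(diuretics), 0.009 (alcohol, age), 0.005 (diet non-adherence) mmol/L,
intercept 0.20 and noise s.d. 0.075 — giving HU prevalence near 12%
and effect sizes on the scale of the published multivariable betas.
The published per-cohort urate means/SDs are not stated, so these
defaults are fixtures chosen to land in the published prevalence range
(8–17%), not facts. Gout mode adds a urate-lowering-therapy exposure
(treated fraction 0.34, effect −0.133 mmol/L), a gout flag, and an
intercept shift. Exposures are independent by default with an optional
Gaussian-copula correlation knob. One root seed feeds named
per-column streams, so adding a column never perturbs existing ones.

The summary-statistic generator draws per-SNP direct exposure effects
from a strength range, adds an upstream-mediator path (bX = bD +
mₓ·bM, bY = θ·bX + c·sign(bX) + m_y·bM), and observes both with
Gaussian error at se = se_scale/√(2·EAF(1−EAF)·N) — the standard GWAS
approximation, giving realistic IVW weights. The constant directional
pleiotropy c is applied in the exposure-increasing-allele orientation,
which is the orientation in which the Egger intercept is defined.
Setting the direct strength range to zero with nonzero mediator
effects produces the full-mediation regime in which univariate MR is
confounded by correlated pleiotropy while mediator-adjusted
multivariable MR recovers the null direct effect. Positions are spaced
2 Mb so distance pruning is a no-op unless deliberately violated; a
configurable fraction of SNPs receives palindromic allele pairs
(without strand error). No LD structure, imputation quality or
realistic allele-frequency spectra are simulated.

What passing tests therefore show: the estimators recover the
parameters of a correctly specified linear-additive world at realistic
effect sizes, sample sizes and instrument strengths, including the
mediation and pleiotropy structures of interest. What they do not
show: robustness to LD between instruments, non-additive genetic
architecture, exposure measurement error at the individual level, or
selection processes beyond the modelled exclusion rules.

## Problem sizes and numerical conventions

Simulation-based checks use cohorts of 20,000 individuals (50,000 for
moment-recovery oracles), instrument sets of 20–50 SNPs, 100–200
seeded replicates for coverage/power properties, 200–1000 bootstrap
replicates for CIs, and 2000 permutations for Monte-Carlo AAFs —
sizes at which the tested tolerances (3–4 SEs, binomial slack on
coverage rates) are comfortably discriminating. Logistic fits use
Newton iterations to tolerance 1e-10; quasi-separation is flagged at
|coefficient| > 15. Wald CIs use z = 1.96 (t quantiles for linear
betas and Egger). Percentages render at one decimal with explicit
signs; not-applicable cells use the `^` marker.

## Known limitations

* Bootstrap CIs refit the full pipeline and are the dominant cost at
  large n_boot; no analytic (delta-method) shortcut is provided.
* Exact AAF enumeration is capped at 9 exposures by design.
* The MR layer deliberately omits LD-aware estimators, MR-PRESSO-style
  outlier removal and explicit correlated-pleiotropy model fitting;
  correlated pleiotropy is detected (bidirectional MR) and adjusted
  for (multivariable MR), not modelled generatively.
* The gout cohort analysis inherits the usual collider-bias caveat:
  conditioning on gout ascertainment can attenuate or reverse effect
  estimates for exposures that cause gout itself; the package reports
  per-cohort estimates and leaves the interpretation to the analyst.
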