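# Methods

## Model and assumptions

Two-sample Mendelian randomization treats genetic variants as
instruments for an exposure. For variant *j*, the exposure GWAS
supplies an effect estimate β̂_Xj with standard error σ_Xj and the
outcome GWAS supplies β̂_Yj, σ_Yj (log-odds per effect allele for
binary traits). Under the instrumental-variable assumptions —
(1) relevance: the variant is associated with the exposure;
(2) exchangeability: it is not associated with confounders;
(3) exclusion restriction: it affects the outcome only through the
exposure — each harmonized pair identifies the causal effect θ through
the Wald ratio β̂_j = β̂_Yj / β̂_Xj, and the estimators pool these
ratios under progressively weaker versions of assumption (3):

* **IVW** assumes all instruments valid. It is the
  inverse-variance-weighted mean of the ratios with first-order
  weights w_j = β̂²_Xj/σ²_Yj, equivalent to weighted least squares of
  β̂_Y on β̂_X through the origin. Exposure-side uncertainty is
  ignored in the weights (the convention of the standard workflow);
  `wald_ratio(..., second_order=True)` exposes the variant-level
  second-order variance for users who want it.
* **MR-Egger** allows a nonzero mean direct effect: weighted
  regression with a free intercept after orienting all β̂_X ≥ 0. The
  intercept estimates average directional pleiotropy and is unbiased
  under InSIDE (direct effects independent of instrument strength).
  Residual overdispersion inflates both SEs via max(1, √(Q/(J−2)));
  inference uses t with J−2 degrees of freedom. The intercept test
  (p < 0.05) is the pipeline's trigger for MR-PRESSO.
* **Weighted median** is consistent when instruments carrying at
  least half the total weight are valid: sort ratios, form cumulative
  weight midpoints s_j = Σ_{k<j} w_k + w_j/2 (weights normalized),
  and linearly interpolate to s = 0.5. SE by parametric bootstrap
  (effects redrawn from normals at their observed values and SEs;
  weights held fixed), 1000 replicates by default, seed mandatory.
* **Simple/weighted mode** assume the largest homogeneous cluster of
  instruments is valid: a Gaussian kernel density over the ratios
  (weights uniform or w_j), bandwidth h = φ·0.9·min(sd, 1.4826·MAD)·
  J^(−1/5) with φ = 1, evaluated on a 512-point grid spanning
  [min−h, max+h]; the estimate is the grid argmax (first maximum on
  ties). If all ratios coincide the common ratio is returned without
  error. Bootstrap SE as above, bandwidth recomputed per replicate.

A causal claim requires all five estimates to agree in sign and all
five p-values to fall below 0.05 — a deliberately conservative
decision rule. P-values are two-sided normal for IVW, the median, and
the modes, and t(J−2) for Egger; the 95% CIs use the matching
quantiles. Odds-ratio transforms (exp of the beta-scale quantities)
are reported everywhere alongside.

## Selection, strength, and harmonization

Genome-wide significance is a strict inequality (p < 5×10⁻⁸).
Clumping is greedy: repeatedly take the smallest-p remaining variant
as an index and discard same-chromosome variants within ±5,000 kb
whose r² with it exceeds 0.01. Ties at equal p break by chromosome,
then position, then variant id, making the output invariant to input
row order. Variants absent from the LD matrix are treated as unlinked
and counted. The ±5,000 kb window (a 10 Mb span) follows common
clumping-tool semantics.

Instrument strength uses the explained-variance form
R² = 2f(1−f)β² / [2f(1−f)β² + 2f(1−f)Nσ²] (f = EAF) and
F = R²(N−2)/(1−R²); variants with F > 10 are retained. Records
without EAF cannot be scored and are rejected or dropped explicitly —
never imputed. A cumulative mode (ΣR² over the instrument set fed to
the same F formula) is provided for set-level strength reporting.

Harmonization flips swapped alleles (negating β_Y and complementing
EAF), detects strand flips by complementing, and handles palindromic
A/T, C/G variants by frequency only, since strand cannot be resolved
from their alleles: they are kept (as aligned) only when both EAFs
are on the same side of 0.5 **and** both MAFs are below 0.3;
otherwise they are dropped as ambiguous. The MAF threshold is
interpreted as an inferability gate — near 0.5 the frequency carries
no orientation signal. Instruments missing from the outcome may be
recovered through a table-driven LD proxy (minimum r² 0.8, with
explicit allele maps from proxy to instrument space); no live LD
queries are performed. Every input instrument is accounted for:
retained + ambiguous + missing + mismatched = input.

## Heterogeneity, sensitivity, and MR-PRESSO

Cochran's Q is Σw_j(β̂_j − β̂_IVW)² with J−1 df (IVW form) or the
weighted residual sum around the Egger line with J−2 df; p-values
from the upper chi-square tail. The multiplicative-random-effects
IVW SE is the fixed-effect SE times max(1, √(Q/(J−1))) — never
smaller than fixed. Leave-one-out uses fixed-effect IVW and flags
exclusions that change the estimate's sign or cross p = 0.05.

MR-PRESSO: observed residuals r_j = w_j(β̂_Yj − β̂₍₋ⱼ₎β̂_Xj)² with
w_j = 1/σ²_Yj and β̂₍₋ⱼ₎ the leave-one-out IVW slope; RSS = Σr_j.
The null distribution comes from parametric simulation (β*_Yj drawn
around the leave-one-out fitted value, β*_Xj around its observation),
1000 replicates by default. Empirical p-values use add-one smoothing,
(1 + #{sim ≥ obs})/(n_sim + 1), so they are never zero. Per-variant
p-values are Bonferroni-multiplied by J; adjusted p < 0.05 flags an
outlier. The corrected estimate is fixed-effect IVW on the
non-outliers. The distortion statistic is
(β̂_all − β̂_corrected)/|β̂_corrected|, compared two-sided against the
same statistic under random outlier-sized removals. The pipeline runs
PRESSO when the Egger intercept test is significant, with a
`force_presso` switch to run it unconditionally.

## Functional prioritization

Instrument sets from several experiments are merged with provenance.
Each variant's b score is its single-SNP Wald beta; a variant
instrumenting several experiments takes the largest-|b| value with
its sign. The sequence-class score is the maximum absolute entry of a
40-component chromatin sequence-class perturbation vector, consumed
from a precomputed table (computing such scores requires a deep
sequence model and is outside this package's scope). Selection keeps
variants with sequence-class score > 1 and |b| > 0.5 (both strict),
ranked by sequence-class score, then |b|, then id; a top-k cap is
optional and off by default — the thresholded filter is treated as
canonical. Variants missing from the score table are flagged and
reported, never silently scored.

## Synthetic-data generator

The generator emulates the summary-statistic structure the analysis
assumes. True instrument effects γ_j are drawn from N(0.06, 0.03) on
the log-odds scale, truncated below so every instrument's true
z-score exceeds 6 — instrument relevance is conditioned on, just as
real instrument selection conditions on genome-wide significance, and
the spread is sized so MR-Egger is adequately powered at J ≈ 40–50
(Egger's slope SE scales as σ_Y/(sd(γ)·√J)). Sampling noise follows
the standard GWAS approximation σ ≈ 1/√(2N·f(1−f)) with MAF uniform
on (0.05, 0.5); the defaults pair a large exposure GWAS
(N = 300,000, biobank scale) with a small outcome GWAS (effective
N = 4,000, the scale of a modest case–control study), giving
instrument F statistics in the hundreds. The default causal effect is
θ = 0.7 (OR ≈ 2).

Pleiotropy modes add direct effects α_j: `balanced` N(0, 0.05),
`directional` N(0.1, 0.05), and `inside_violated` directional with
corr(γ, α) = 0.5 — a fixed, documented choice of InSIDE violation
strength. `pleio_fraction` confines pleiotropy to a subset of
instruments. LD blocks place tag variants next to index instruments
with effect and noise correlation √r², so clumping has real work to
do; distinct loci sit 15 Mb apart on two chromosomes, beyond the
clumping window. A configurable fraction of variants receives
palindromic alleles. Outcome-trait-specific instruments (direct
outcome effects δ ~ N(0.25, 0.05), null for the exposure) make
reverse-direction analyses meaningful: swapping exposure and outcome
selects these variants and correctly finds no reverse effect. Planted
outliers displace β_Y by exactly 10σ_Y. Identical seed and
configuration give byte-identical output; the fast path
`simulate_harmonized` draws instrument-level pairs directly for
calibration studies.

What the generator does **not** emulate: realistic LD from reference
panels (block-constant r² only), per-variant sample-size variation
within a study, allele-frequency differences between ancestries,
winner's-curse-inducing overlap between discovery and analysis
samples, and case-fraction effects on the SE of log-odds estimates
(N is an effective sample size). Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed
data-generating model, not robustness to every pathology of real
GWAS data.

## Numerical and interface choices

* Strict inequalities wherever a threshold is printed (p < 5×10⁻⁸,
  F > 10, score > 1, |b| > 0.5); r² > 0.01 discards in clumping.
* P-values of exactly 0 on input are clamped to the smallest positive
  normal float and counted; computed p-values are floored at the
  smallest positive float so downstream log transforms never fail.
* Floats are written with 12 significant digits; read∘write∘read is
  the identity on summary tables.
* All bootstrap/simulation operations require an explicit seed; the
  five-method suite derives independent child seeds for the median
  and the two modes from one master seed.
* The run manifest contains the full configuration echo, stage
  counts, seeds, and SHA-256 digests of every output table, and no
  timestamps, so identical runs are byte-identical and a run is
  reproducible from its manifest alone.
* One sentence of the source workflow's description — rescaling when
  exposure and outcome effect distributions differ "significantly" —
  defines neither its trigger nor its factor; no rescaling is
  applied.

## Problem sizes used in validation

The test suite and the acceptance script use simulation sizes chosen
for tight Monte-Carlo error at desk scale: 500 replicates for
recovery/coverage and pleiotropy-robustness studies, 1000 replicates
for null calibration (with MR-PRESSO at 200 simulations per
replicate), 100 seeds for planted-outlier detection (20 instruments,
1000 PRESSO simulations), and 20 end-to-end pipeline replicates.

## Known limitations

* No multivariable MR, contamination-mixture or CAUSE-style
  estimators, Steiger direction filtering, I², or Rucker model
  selection.
* LD matrices are consumed, not computed from genotypes; no reference
  panels ship with the package.
* No remote retrieval of GWAS accessions: inputs are local delimited
  text files.
* The first-order IVW weights ignore exposure-side uncertainty; with
  weak instruments (low F) this understates ratio variance — the
  F > 10 gate is the guard.
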