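# Methods

## Scope and design

`mrlink` implements a bidirectional two-sample Mendelian randomization
screen: many exposure GWAS (taxon abundances) against one outcome GWAS
(a binary disease), then a reverse pass using the disease as exposure for
the hit taxa. All estimation operates on summary statistics only; no
individual-level data or external downloads are involved. The package is a
library first (`examples/` shows the intended use from Python), with a thin
CLI for shell runs.

## Data model and harmonization

Summary tables are tab-separated with columns `SNP CHR POS EA OA EAF BETA SE
P N`; rows violating basic invariants (SE ≤ 0, p outside (0,1], identical
alleles, N < 2, EAF outside [0,1]) are dropped and counted. Floats are
written and parsed at full double precision, so write→read round-trips are
exact.

Harmonization aligns each shared SNP's outcome effect to the exposure's
effect allele: identical alleles pass through; swapped alleles negate the
outcome beta and complement its EAF; a strand flip (complementing both
outcome alleles) is attempted before declaring a mismatch; indels match by
exact string equality only. Palindromic (A/T, G/C) variants cannot be
strand-resolved from alleles: they are kept only when the minor-allele
frequency on both sides is at most the ambiguity window (default 0.42), in
which case the frequency side decides orientation; otherwise — including
whenever an EAF is missing — they are dropped as ambiguous. Non-palindromic
variants with a missing EAF harmonize by allele identity alone. These
choices follow common two-sample practice and are deliberately conservative;
the window is a parameter.

## Instrument selection and strength

Selection keeps SNPs with p strictly below the threshold (5×10⁻⁸
genome-wide; 1×10⁻⁵ locus-wide, the default for under-powered exposure GWAS
such as microbiome abundances). Greedy clumping visits SNPs by ascending
p-value (ties broken by chromosome then position); each index SNP removes
remaining SNPs on its chromosome within the distance window whose r² with it
exceeds the ceiling (distance alone removes when no LD matrix is supplied;
SNPs absent from a supplied matrix count as r² = 0 with a warning). The
defaults — 500 kb and r² ≤ 0.3 — are intentionally loose, matching the
screen this package is designed around rather than conventional strict
clumping (10 Mb, r² 0.001); both are parameters. Screening against known
confounder- or outcome-associated variants is supported as a user-supplied
exclusion list applied after clumping, not as a live catalog query.

Instrument strength uses F = R²(N−2)/(1−R²). For J ≤ 10 instruments R² is
the sum of per-SNP contributions 2·EAF(1−EAF)β²; for J > 10 each
contribution is shrunk by its sampling variance,
2pq·β²/(2pq·β² + 2pq·N·SE²). The boundary at exactly 10 is assigned to the
small-set formula (a contiguous reading of the convention; `mode` overrides
it). Both an aggregate F (from total R² and the median N) and per-SNP F
values are reported; an instrument set whose minimum per-SNP F is ≤ 10 is
flagged as weak rather than excluded. The shrunken formula is an
approximation to joint variance explained without genotype data; with very
strong instruments the small-set sum can exceed it noticeably.

## Estimators

Point estimates and standard errors follow the standard summary-data
formulations (README). Numerical conventions:

- IVW uses multiplicative random effects by default: SE = fixed-effect SE ×
  max(1, √(RSS/(J−1))) with weighted residual sum of squares RSS. A
  fixed-effect variant and a permissive single-instrument mode (which
  reduces exactly to the Wald ratio) are available by flag.
- MR-Egger re-orients all exposure effects positive (co-flipping outcome
  effects) before fitting, so the intercept has a consistent sign
  convention. The fit is weighted least squares (statsmodels) with the same
  residual-scale floor; slope and intercept p-values use t with J−2 df.
- The weighted median interpolates the weight-ordered ratios at cumulative
  position 0.5 (clamped at the extremes) and draws its SE from a parametric
  bootstrap (default 1000 resamples) re-sampling both sides from
  normal(observed, SE). The generator seed is mandatory; results are
  bit-for-bit reproducible.
- Wald ratio, IVW and weighted-median p-values use the standard normal;
  intervals use z = 1.959964. p-values are floored at the smallest positive
  double rather than reported as 0.
- Minimum instrument counts: 1 (Wald), 2 (IVW), 3 (Egger and weighted
  median) — a two-point Egger fit is saturated.

## Diagnostics

Cochran's Q uses the IVW weights (βₓ/SEᵧ)² around the IVW estimate with a
χ²(J−1) reference; exposure-side error is ignored in the weights, matching
the estimator. The Egger intercept test is the two-sided t test of the
intercept (J−2 df). Steiger's test sums per-SNP 2·EAF(1−EAF)β² on each side,
takes direction from the larger total, and compares Fisher-z transforms of
the two √R² values scaled by √(1/(Nₓ−3) + 1/(Nᵧ−3)). For a binary outcome
the observed-scale R² makes this approximate (no liability-scale
conversion); reports carry an explicit flag. Steiger is reported, not used
as a hard filter.

## Pipeline

Per exposure: select → clump → exclusion list → harmonize → estimate →
diagnose. The primary method is the Wald ratio for exactly one retained
instrument and IVW otherwise, with Egger and weighted median attached from
three instruments as robustness references (a hit is flagged robust when a
reference model replicates the primary sign at p < 0.05). Exposures with no
surviving instruments are recorded, not dropped — the audit table contains
every input exposure exactly once. Primary p-values across all exposures in
a run form a single Benjamini–Hochberg family; results carry both the raw-p
tier (nominal < 0.05) and the FDR tier, since screens of many weak GWAS
often have no FDR-surviving hits and users must be able to see both.
Reverse mode swaps roles for the hit taxa and forces the genome-wide
threshold for the disease instruments. All per-taxon random streams derive
from the run seed and a stable taxon index, so identical inputs and seed
give byte-identical report files (numeric cells fixed at 3 decimals,
non-applicable cells as `NA`, rows ordered by classification then exposure).

## Synthetic data

The generator emulates the structure, not the biology, of a microbiome
panel GWAS paired with a binary disease GWAS. Per instrument SNP:
β̂ₓ = γ + ε with SE 1/√(2·MAF(1−MAF)·Nₓ), and β̂ᵧ = b·γ + α + u with the
binary outcome's effective sample size shrunk by v = case·control/N² on the
log-odds scale. Defaults mirror the intended cohorts: Nₓ = 18,473,
Nᵧ = 55,374 with case fraction 0.3645, MAF ~ U(0.05, 0.5), 12 instrument
SNPs plus 30 null SNPs per taxon, 20 taxa of which two are causal
(b = ±0.3). Default instrument magnitudes |γ| ~ U(0.06, 0.12) put per-SNP F
in the ~20–80 range where the bulk of locus-wide microbiome instruments
sit. Pleiotropy regimes: none, balanced (zero-mean α), or directional
(nonzero-mean α) on a configurable invalid fraction, with an optional
strength-correlated ("InSIDE-violating") mode. LD is block-diagonal
constant-r² with block members placed within the clumping window;
summary-stat noise is drawn independently of LD (sufficient for testing
threshold crossings, not a calibrated joint distribution). A fraction of
outcome rows is written with swapped allele labels so harmonization always
has real work. Binary-outcome effects are simulated directly on the
log-odds scale (no liability model). What passing tests therefore show is
estimator and pipeline correctness under the stated generating model — not
robustness to real-data pathologies such as sample overlap, population
stratification, or winner's-curse instrument selection.

Estimator-validation scenarios (parameter recovery, calibration, robustness
ordering) use 50 valid instruments with |γ| ~ U(0.15, 0.40) — per-SNP F
roughly 100–900, inside the range observed for strong microbiome
instruments — so that finite-sample regression dilution (order SE²/γ²,
about 0.2% of the effect here) is negligible relative to Monte-Carlo
resolution at 200 replicates. Validating consistency where the estimator's
own conditions hold is the point of those scenarios; weak-instrument
behaviour is a separate, documented phenomenon (the dilution factor is
visible by shrinking γ).

Problem sizes used by the test suite and the acceptance script — 200
replicates for Monte-Carlo scenarios, 1000 for calibration checks, panels
of 8–20 taxa — were chosen as the smallest sizes at which the binomial or
Monte-Carlo bands quoted in the tests are meaningful.

## Known limitations

- No proxy-SNP lookup, liftover, VCF input, or genotype-panel LD
  computation; the LD matrix must be supplied (or distance-only clumping
  accepted).
- No MR-PRESSO, mode-based, multivariable or contamination-mixture
  estimators.
- Steiger on binary traits is observed-scale and approximate.
- The confounder screen is an exclusion-list hook; it does not query
  external GWAS catalogs.
- Leave-one-out and single-SNP scans are not produced.
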