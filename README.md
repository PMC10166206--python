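# mrlink

Bidirectional two-sample Mendelian randomization (MR) from GWAS summary
statistics, built for microbiome-to-disease screens: many exposures (e.g.
gut-microbiota taxon abundances), one binary outcome, and a reverse pass over
the hits. A synthetic-data generator with known ground truth makes every
stage testable without any cohort download.

**Who it is for.** Researchers who have per-trait GWAS summary tables
(SNP, alleles, EAF, beta, SE, p, N) and want a reproducible causal screen
with the standard estimator battery and sensitivity checks, plus
methodologists who want a seeded simulation harness for those estimators.

## The model

Genetic variants G that robustly associate with an exposure X serve as
instrumental variables for the causal effect of X on an outcome Y, under the
usual IV assumptions (relevance; no confounder association; exclusion
restriction). With summary statistics (β̂ₓⱼ, β̂ᵧⱼ) per SNP j:

- **Wald ratio** (1 instrument): β̂ = β̂ᵧ/β̂ₓ, SE = |SEᵧ/β̂ₓ|.
- **IVW** (≥2): β̂ = Σwⱼβ̂ₓⱼβ̂ᵧⱼ / Σwⱼβ̂ₓⱼ², wⱼ = 1/SEᵧⱼ²; multiplicative
  random effects inflate the SE by the residual scale when it exceeds 1.
- **MR-Egger** (≥3): the same weighted regression with a free intercept;
  under InSIDE the slope is pleiotropy-robust and the intercept estimates
  average directional pleiotropy.
- **Weighted median** (≥3): the median of the weight-ordered per-SNP ratio
  distribution, consistent while valid instruments hold >50% of the weight;
  SE via seeded parametric bootstrap.

Instruments are chosen at the genome-wide (5×10⁻⁸) or locus-wide (1×10⁻⁵)
threshold, thinned by greedy clumping (500 kb window, r² ≤ 0.3 by default),
and scored with F = R²(N−2)/(1−R²), where R² sums per-SNP contributions
2·EAF(1−EAF)β² (shrunk by sampling variance for sets larger than 10).
Sensitivity checks: Cochran's Q (heterogeneity), the Egger intercept test
(pleiotropy), Steiger's Fisher-z directionality test, and Benjamini–Hochberg
FDR across the exposure family. Binary-outcome effects are log odds ratios;
reports show OR with 95% CI.

## Worked example

`examples/02_forward_screen.py` simulates a 20-taxon panel in which
`genus.Taxon001` truly raises the outcome (log-odds +0.3 per SD of
abundance) and `genus.Taxon002` lowers it (−0.3), then runs the forward
screen:

```
20 of 20 taxa had instruments; forest tables in scratch/example_screen/report/

genus.Taxon002     ivw         n_snp=12 OR=0.695 [0.641, 0.754] p=1.52e-18 q=0.000 tier=fdr_significant
genus.Taxon001     ivw         n_snp=11 OR=1.475 [1.329, 1.637] p=2.59e-13 q=0.000 tier=fdr_significant
genus.Taxon020     ivw         n_snp= 8 OR=0.877 [0.784, 0.980] p=2.09e-02 q=0.139 tier=nominal
genus.Taxon005     ivw         n_snp=11 OR=0.908 [0.829, 0.995] p=3.91e-02 q=0.195 tier=nominal
...
```

The two causal taxa head the ranking and survive FDR (`tier=fdr_significant`;
exp(0.3) ≈ 1.35, and the IVW intervals cover it); two null taxa reach nominal
p < 0.05, as expected by chance among 18 nulls, and FDR keeps them out.
The other examples demonstrate panel generation (`01`), the estimator
battery with pleiotropy diagnostics (`03`), and reverse MR with a Steiger
directionality check (`04`).

A thin CLI wraps the same library calls:

```bash
mrlink simulate --config truth.yaml --out panel/
mrlink run --exposures panel/ --outcome panel/outcome.tsv \
           --pthresh 1e-5 --clump-kb 500 --clump-r2 0.3 --seed 17 --out report/
```

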