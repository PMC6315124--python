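# Methods

This document records the statistical models, default parameters, numerical
choices, and known limitations of `bilfreqsel`.

## 1. Synthetic BIL generator (`bilfreqsel.simulate`)

### Genetic map

Twelve chromosomes with lengths (181, 157, 166, 129, 122, 125, 118, 121,
93, 83, 117, 109) cM — realistic rice map lengths — carrying 124 SSR-style
markers (`RM{chrom}{index}`). Each chromosome places markers at both ends
and sorted uniform positions in between. All positions are in
centimorgans; physical coordinates are never modelled.

### Pedigree and meiosis

Lines are BC1F6 by default: one backcross to the recipient followed by
five selfing generations (`n_backcrosses=1`, `n_selfing_generations=5`).
Gametes are simulated per chromosome as a two-state Markov switch process:
the starting homolog is chosen with probability 1/2 and a crossover occurs
between adjacent markers with probability `kosambi_inverse(d)` for map
distance `d`. Consequences that the test suite verifies directly:

* donor allele frequency 1/4 after BC1 (`0.25`),
* residual heterozygosity `0.5 · (1/2)^t` after `t` selfings
  (`0.5/32 ≈ 1.6%` for BC1F6),
* adjacent-marker recombination equal to the Kosambi-inverse of their
  distance at the single-meiosis level.

Genotypes are coded `OU` (recipient homozygote, dosage −1), `HET` (0),
`AR` (donor homozygote, +1), `NA` (missing). An optional `missing_rate`
masks calls at random.

### Trait model

Dry weight (population trait) and shoot fresh weight (RNA-seq panel
trait) are

```
y_i = baseline + Σ_q a_q · E[dosage_i at q] + ε_i
```

with baseline 4.01 mg and four planted QTL (chr3 40 cM +0.35, chr6 60 cM
−0.28, chr7 55 cM +0.55, chr10 40 cM +0.48). The effects sum to 1.10, so
noise-free parental means are ≈ 2.91 and ≈ 5.11 mg ("≈" because interior
QTL dosages are flank-conditioned expectations, which admit a small
double-crossover probability even in pure parents). Noise is scaled from a
target broad-sense heritability `h²` (default 0.6):
`noise_sd = sqrt(var_g · (1 − h²)/h² · n_rep)` per replicate, replicates
averaged. The fresh-weight trait uses a `scale=5.0` multiplier so its
magnitude resembles mg-scale seedling fresh weights distinct from the dry
weights.

### Expression model

For gene g and sample i:
`FPKM = 2^(μ_g + a_g·dosage_i + c_g·z_i + ε)`, where `μ_g ~ N(0.7, 2.6)`
on the log2 scale (spanning silent to highly expressed), `z` is the
standardized trait of the expression samples, `c_g = ±1.2` for the 20
planted causal genes (giving |r| ≈ 0.94 with the trait at the default
log2 noise SD of 0.45), and planted eQTL add `a_g · dosage`. A 10%
fraction of null genes is forced near-silent (mean FPKM ≤ 0.01) to
exercise the expression filter. Expression is generated for the RNA-seq
panel: 20 randomly chosen BILs plus both parents (22 samples), coupled to
the fresh-weight trait of those same 22 samples — mirroring the study
design in which the whole population has the trait but only the panel has
RNA-Seq.

### qPCR model

A standard dilution series (10³–10⁸ copies) defines a line
`Cq = intercept + slope·log10(copies)` with slope −1/log10 2 (100%
efficiency) and intercept 38. Per-line true log2 copies follow the focal
gene's planted couplings; biological replicates add log2-scale noise,
technical replicates add Cq-scale noise.

### Randomness

Every stream uses `numpy.random.SeedSequence([seed, stream, *extra])`
counters, so results are independent of worker count and call order. All
derived seeds stay below 2³¹.

## 2. Preprocessing (`bilfreqsel.preprocess`)

Genes with mean FPKM **strictly greater than 0.01** across samples are
kept (a mean of exactly 0.01 is removed); kept values are transformed as
`log2(FPKM + 0.01)`. The pseudocount makes zero map to log2(0.01) ≈ −6.64
and leaves large values essentially unchanged. Filtering and the
transform commute, which the suite checks property-based.

## 3. Selection frequency (`bilfreqsel.selection`)

Per trial *t* of `n_trials` (default 10,000):

1. draw `floor(0.10 · G)` genes uniformly without replacement
   (3,704 of a 37,043-gene universe),
2. standardize the subset's log2 expression and center the trait,
3. evaluate the LASSO path (scikit-learn `lasso_path`; objective
   `(1/2n)‖y − Xβ‖² + λ‖β‖₁`) on a 100-point geometric grid from
   `λ_max = max|Xᵀy|/n` down to `10⁻³·λ_max`,
4. take the largest λ whose active set reaches **eight** variables; if the
   active set jumps past eight, truncate to the eight largest |β|. The
   model size is capped at `n − 1` when samples are scarce.

The selection frequency of a gene is `selected_count / n_trials` — the
denominator is all trials, not just the trials where the gene appeared in
the subset, so a perfect gene's frequency ≈ the subset fraction (0.10).
The report adds the Pearson r/p of each selected gene with the trait and
the conditional frequency (`selected/appearance`).

*Numerical shortcut:* the path is evaluated in chunks of λ values with
early stopping at the first λ reaching the target model size. This is
decision-identical to evaluating the full path (tested on random
instances) and ~27× faster. A `LassoCV`-based penalty rule is available
as an option; the fixed-model-size rule is the default because the study
fixes eight explanatory variables per trial.

Correctness is anchored by a test-only proximal-gradient (ISTA) oracle
solving the same objective to 10⁻⁶ agreement.

## 4. Interval mapping (`bilfreqsel.mapping`)

* **Map function** — Kosambi: `d = 25·ln((1+2r)/(1−2r))` cM, inverse
  `r = ½·tanh(d/50)`.
* **Pseudomarker imputation** — expected dosages on a 1 cM grid (union of
  grid and marker positions). Each line's two homologs are independent
  Markov chains; at a test position the dosage is the expectation over the
  phase-consistent homolog configurations of the nearest non-missing
  flanking genotypes, with weights from Kosambi-inverse transition
  probabilities. Validated against a Monte Carlo enumeration oracle.
* **Scan** — Haley–Knott-style regression of the trait on expected dosage:
  `LOD = (n/2)·log10(RSS_reduced/RSS_full)` with an RSS floor of
  `10⁻¹²·TSS`; `R² = 100·(RSS_red − RSS_full)/TSS`; the additive effect is
  the dosage coefficient. CIM adds stepwise-selected marker cofactors
  (partial-F entry p ≤ 0.05, exit p > 0.10, at most 5), dropping any
  cofactor within a 10 cM window of the tested position. Partial-F tests
  ignore RSS improvements below `10⁻¹⁰·TSS` so perfectly collinear markers
  cannot enter on floating-point dust.
* **Threshold** — the empirical 95th percentile (type-7/linear quantile)
  of the genome-wide max LOD over 1,000 trait permutations (default).
  Cofactors are held fixed under permutation by default
  (`reselect_cofactors_in_permutations=False`); re-selection per
  permutation is available but ~100× slower. Cofactor-free (simple
  interval mapping) permutations use a fully vectorized multi-trait scan.
* **Calls** — one QTL per contiguous supra-threshold region at its LOD
  peak (ties to the smaller cM), annotated with the nearest marker. eQTL
  scans reuse the same machinery on log2 expression of a gene.

## 5. Association statistics and qPCR (`bilfreqsel.stats`)

Pearson correlation with the two-sided t-test p-value (cross-checked
against a permutation oracle and SciPy); classic one-way ANOVA;
`copies/µl = ng·10⁻⁹·N_A / (bp·650)` for dsDNA; standard curves by least
squares of Cq on log10(copies) with `efficiency = 10^(−1/slope) − 1`.
Quantification averages technical replicates on the Cq scale, inverts the
curve to copies, and reports per-line mean log2 copies over biological
replicates.

## 6. Pipeline (`bilfreqsel.pipeline`, CLI `bilfreqsel`)

`run_pipeline` executes simulate → preprocess → selection → QTL/qPCR →
eQTL, writing every artifact as TSV (`%.6g`) plus `summary.json` with
counts, timings and a SHA-256 configuration hash (the output directory is
excluded from the hash). `compare_to_truth` scores a finished run against
the planted truth: median causal-gene frequency vs. the null 95th
percentile, QTL localization errors, and additive-effect bias.

## 7. Acceptance calibration (target t3)

`scripts/acceptance.py` simulates 100 null datasets (104 lines, default
map, trait independent of genotype with SD 0.6), computes each dataset's
5% threshold from 100 permutations in simple-interval-mapping mode, and
reports the fraction whose genome-wide max LOD exceeds its own threshold.
The expected value is the nominal 0.05 within binomial error
(SE ≈ 0.022 at n = 100). Runtime ≈ 30 s on one CPU.

## 8. Recovery-test conditions (chosen a priori)

The planted-signal acceptance test uses: 20 seeds × 500 trials on a
2,000-gene universe with 20 planted causal genes (gene criterion: median
planted frequency above the null 95th percentile in ≥ 18/20 seeds), and
50 simulations of two QTL at per-QTL h² = 0.20 with n = 104, simple
interval mapping and 100-permutation thresholds (QTL criterion: ≥ 80%
localized within 10 cM). These sizes were fixed before running the tests
and are not tuned to outcomes.

## Limitations

* The generator plants additive effects only — no epistasis, no
  dominance beyond residual heterozygosity, no genotype×environment.
* Expression couplings are linear on the log2 scale with Gaussian noise;
  real RNA-Seq counts are overdispersed and library-size confounded.
* The map is distance-only; marker order/physical position discrepancies
  and segregation distortion are not modelled.
* CIM uses expected-dosage (Haley–Knott) regression, not a full mixture
  likelihood; with 1.6% residual heterozygosity the difference is
  negligible, but it would matter in an F2.
* Cofactor selection under permutation is fixed by default, which is
  standard but slightly anticonservative relative to full re-selection.
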