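# Methods

## The cascade

The pipeline reproduces a gene-discovery cascade for residual disease risk
in a case-control exome design. Its stages, in fixed order:

1. **Site-level QC.** A variant is excluded if any rule fires:
   mean depth over non-missing samples < 8 reads; mean depth among
   minor-allele carriers < 4 reads; mapping quality < 40; strand-bias
   exact-test p < 10⁻³ on the ref/alt × fwd/rev read-count table;
   mean heterozygote alt-read fraction outside [0.25, 0.75]; exact
   Hardy-Weinberg p < 10⁻⁶ computed in controls only. Only the two depth
   cutoffs are canonical to this design; the remaining four thresholds are
   conventional exome-QC values and are config-overridable, so results
   under the defaults should be described as "with standard QC", not as a
   replication of any specific study's QC. HWE is tested in controls
   because true case-control association violates HWE in cases by design.
   "Minor-allele mean depth" defaults to the mean *total* depth among
   samples carrying ≥ 1 minor allele; a variant reading (mean minor-allele
   AD among carriers) sits behind `minor_depth_mode="allele"`.

2. **Qualifying sets.** Variants with MAF strictly < 0.05 enter up to five
   nested deleteriousness sets (see README). Missing predictor calls count
   as "not deleterious": they can never grant strict membership and never
   revoke broad membership granted by another predictor. PolyPhen-2 HumDiv
   "possibly damaging" and "probably damaging" both map to deleterious
   everywhere HumDiv acts as one of the five predictors. The MAF is taken
   from the annotation table; in the synthetic path that is the cohort
   allele frequency.

3. **Collapsing burden test.** Dominant (CAST-style) carrier coding;
   samples missing at every qualifying site of a cell are excluded from
   both carrier and non-carrier counts. The two-sided Fisher exact p sums
   hypergeometric probabilities of all tables at the observed margins that
   are no more probable than the observed table. Both this test and the
   Hardy-Weinberg exact test use arbitrary-precision integer point weights,
   so tie comparisons are exact; the only floating-point operation is the
   final division. The odds ratio is the cross-product, with the
   Haldane-Anscombe +0.5 correction applied to all cells whenever any cell
   is zero (a conditional-MLE estimator is available via
   `or_estimator="cmle"`). The collapsed MAF (cMAF) defaults to the
   aggregate minor-allele frequency over qualifying sites (minor-allele
   count / non-missing allele slots); a carrier-fraction variant sits
   behind `cmaf_mode="carrier"`. The screen keeps rows with p < 0.05 and
   OR > 3.5 (strict inequalities) and deduplicates genes across sets. No
   multiple-testing correction is applied at this stage — the scan reports
   its row count so users can correct downstream.

4. **Evidence mapping.** Survivors are joined case-insensitively against
   four TSV evidence tables (GLGC-style lipid trait p-values,
   CARDIoGRAMplusC4D-style CAD genes, MGI-style mouse phenotype categories,
   GWAS-catalog-style CAD flags). A gene is kept with evidence in ≥ 1 of
   the first three; the GWAS-catalog flag is annotation only. GLGC
   evidence means "any trait p-value present" — no re-thresholding. The
   packaged tables are synthetic emulation snapshots (see
   `src/rarecascade/data/synthetic_evidence/README.md`); no alias
   resolution is attempted.

5. **Carrier-phenotype analysis.** Within cases only, each (gene, set,
   phenotype) cell is tested by OLS of the phenotype on the 0/1 carrier
   indicator with no covariates. With a single binary regressor this is
   algebraically the pooled-variance two-sample t-test and the slope is
   exactly the carrier-minus-noncarrier mean difference; the implementation
   uses that closed form (cross-checked against statsmodels OLS in the
   tests). Zero residual variance is degenerate: p = 1 with a warning when
   the group means agree, p = 0 otherwise. Genes need ≥ 1 significant
   phenotype row (p < 0.05) to continue. Pathway filters then act on the
   union of a gene's set-level rows — a gene passes if any set's rows
   satisfy the pattern: lipid (significant positive β on a lipid trait),
   thrombosis (PT and APTT both significant and both negative; both
   positive is reported separately as a bleeding direction), inflammation
   (anchor CRP or fibrinogen β > 0, WBC β > 0, neutrophil-% β > 0,
   monocyte-% β < 0, all p < 0.05).

6. **Cohort comparison.** Descriptive case-vs-control table: per-arm mean
   and SD with a two-sided Wilcoxon rank-sum p for quantitative
   phenotypes, percentages with a two-sided Fisher exact p for categorical
   ones. The Wilcoxon p is exact for per-arm n ≤ 25 without ties and a
   tie-corrected normal approximation otherwise.

## The synthetic cohort generator

The generator emulates the structure the cascade needs, not any real
dataset's content:

- **Arms and genes.** Defaults: 92 cases, 102 controls, 200 genes ×
  3 variants. Background variants draw an allele frequency uniformly on
  (0.001, 0.02) — rare but with realistic carrier counts at n ≈ 200 — and
  sample unphased diploid genotypes binomially, identically in both arms,
  with no linkage between variants.
- **Planted risk genes** are parameterised directly by per-arm carrier
  probabilities; each planted carrier receives one heterozygous allele at
  a randomly chosen variant of the gene, and planted genes carry no
  background variation, so the configured carrier probability is the
  direct estimand of the collapsing test.
- **Annotations.** Functional classes are drawn from configurable weights
  (default: 55% missense, 30% synonymous, 5% each nonsense / splice /
  frameshift). Missense variants get a latent deleterious state
  (probability `latent_deleterious_prob`, default 0.5 — a free parameter
  of the generator, not an empirical estimate) and five conditionally
  independent predictor calls, each agreeing with the latent state with
  probability `predictor_concordance` (default 0.9). Planted-gene variants
  are restricted to non-synonymous classes with a deleterious latent
  state so planted carriers actually hold qualifying alleles.
- **Phenotypes** are Gaussian around per-phenotype (mean, SD) baselines
  (defaults follow published clinical baselines of a
  conventional-risk-factor-free early-onset CAD arm, e.g. LDL-C
  76.0 ± 33.03 mg/dL), plus additive shifts for carriers of planted
  genes, plus a categorical sex column. Both arms share the same
  baselines, noise is independent across phenotypes, and heavy-tailed
  markers (CRP, PT) are simulated with their nominal SDs, so simulated
  cross-arm comparisons are null by construction and the generator makes
  no claim about real inter-marker correlation, skewness, or arm
  differences. Passing tests therefore demonstrate correctness of the
  cascade's logic and calibration under this generative model — not
  performance on real exomes.
- **Sequencing fields** (depths ~ Poisson(100), balanced allele and strand
  splits, MQ 60) are deep and clean so default QC passes unless a test
  perturbs them deliberately.

The default demo plants `CABP1` (LDL-C +73.87 mg/dL) and `KLHL8`
(fibrinogen +9.94 g/L, WBC +4.91 × 10⁹/L, neutrophil +16.9 %, monocyte
−5.17 %) at carrier rates 15% in cases vs 0.5% in controls. The shift
magnitudes are reference effect sizes this cascade style is designed to
detect; the carrier rates were chosen, by a binomial power calculation at
n = 92/102, to make single-run recovery by the p/OR screen near-certain,
since the demo doubles as a deterministic worked example. The power and
calibration suites use their own conditions (12% vs 1% at n = 200/200 for
power; no planted genes at n = 100/100 for null calibration).

## Numerical and design notes

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; annotation and phenotype stages use child
  seed sequences so stages are independently reproducible. Fixed seed ⇒
  bit-identical outputs.
- Exact-test tie handling: two tables with rationally equal point
  probabilities are always both included; this is what makes the
  enumeration-oracle agreement hold to 10⁻¹², rather than to a relative
  tie tolerance.
- The strand-bias QC rule delegates to `scipy.stats.fisher_exact`:
  strand tables hold whole-cohort read counts (margins ~10⁴–10⁵) where
  big-integer enumeration is infeasible and floating-point evaluation is
  amply accurate against the 10⁻³ cutoff.
- Degenerate 2×2 margins (no carriers anywhere, or an empty arm) give
  p = 1 with a warning rather than an error, so null scans over sparse
  genes proceed.
- Replicate counts in the validation suites (200 null cohorts, 200 power
  replicates, 200 effect-recovery replicates; 100 each in the acceptance
  script) were sized so Monte-Carlo standard errors are several-fold
  smaller than the margins being asserted.
- Coordinates are 1-based as in VCF; multi-allelic records are split into
  bi-allelic records with per-allele AD bookkeeping at ingestion.

## Known limitations

- No linkage disequilibrium, population stratification, relatedness, or
  covariate confounding in the generator; regressions are unadjusted (a
  covariate hook is deliberately absent rather than half-supported).
- Gene symbols are matched by case-folding only; no alias or ortholog
  resolution against the evidence tables.
- The burden test is carrier-collapsing only; variance-component tests
  (SKAT-type) and allele-count burden regression are out of scope (an
  allele-count cMAF is reported, but the test statistic is the carrier
  table).
- The packaged evidence tables are small synthetic snapshots for
  demonstration and testing; real analyses should point the loader at
  full database exports.
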