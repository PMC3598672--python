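# Methods

`mirblood` analyses whole-blood miRNA profiles measured on a digital
hybridization counting panel in a three-group allergen-challenge design:
healthy controls (HC), asthmatic subjects immediately before allergen
inhalation (pre) and the same subjects about two hours after (post). This
note records the models, the numerical conventions, what the synthetic data
emulate, and the design choices taken where the problem was genuinely open.

## Count preprocessing

Raw code counts pass through a fixed ladder (`preprocess.run_preprocess`):

1. **Probe-specific background subtraction.** Some probes carry a known
   per-probe background that must be subtracted before normalization. These
   correction values are assay-lot-specific and are therefore a user input
   (default: empty map). A subtraction that goes negative is set to 1 count.
2. **Positive-control normalization.** Each panel carries six synthetic RNA
   spike-ins at 0.125–128 fM covering the assay's dynamic range. Each sample
   is scaled so its positive-control sum equals the cross-sample arithmetic
   mean of those sums, removing hybridization/binding efficiency differences.
3. **Negative-control background thresholding.** Per sample, the detection
   threshold is mean + 2·sd of the eight negative-control probes (sample sd,
   n−1 denominator). The threshold is subtracted from every endogenous count
   and a probe is *detected* only if its subtracted count is non-negative in
   **every** sample. A flag (`subtract=False`) switches to a detection-only
   reading in which the threshold is used for filtering but counts are kept;
   the subtract-and-keep reading is the default because the thresholding and
   filtering text reads most naturally as one subtraction step.
4. **Content normalization.** Each sample is scaled so that its total over
   the detected set equals the cross-sample mean of those totals. Any fixed
   target would give identical downstream test statistics (both
   normalizations are ratio-based and the log2 scale turns the target into a
   common additive constant); the mean is used for interpretability. A
   corollary, asserted in the tests: rescaling one sample's raw counts
   changes the final expression matrix only by one global log2 constant.
5. **Minimum-count filter.** Probes whose *minimum* normalized count across
   samples is ≥ 100 are retained (boundary inclusive). "At least 100
   counts" is ambiguous between a min and a mean rule; the min rule is the
   conservative reading and the default, with `rule="mean"` selectable.
6. **log2 transform**, flooring counts at 1 (so 0 → 0). The floor-at-1
   convention matches the treatment of negative background-subtracted
   values elsewhere in the ladder; a +1 offset would compress genuine
   low-count fold changes instead.

A `QCReport` records per-step endogenous-probe attrition (which is asserted
non-increasing), the per-sample scale factors and detection thresholds.

## Differential expression

Each probe is fitted with an independent two-group linear model on the log2
scale (`TwoGroupDE`). The default per-probe estimator is robust IRLS with
Huber weights (tuning constant 1.345, ≤ 50 iterations, tolerance 1e-8, via
statsmodels RLM), falling back to the ordinary pooled-variance fit for
degenerate probes; `robust=False` selects the closed-form ordinary fit,
which is fully vectorised. The two study contrasts (HC vs pre, pre vs post)
are fitted as independent unpaired models; the pre/post pairing is
deliberately *not* modelled in the default analysis (a paired option exists
for study), matching the original analysis strategy whose own discussion
acknowledges the unpaired statistic is conservative for the paired contrast.

Residual variances are shrunk by empirical Bayes under the scaled
inverse-chi-square hierarchy: posterior variance
`(d0·s0² + df·s²)/(d0 + df)`, moderated t referred to `t(d0 + df)`. The
hyperparameters are moment-matched on the log variances using
digamma/trigamma identities, with a Newton inversion of the trigamma
function; when the method-of-moments excess variance is non-positive the
prior df is infinite and variances are fully pooled. `d0 = 0` reproduces
the ordinary t exactly — this limit, the hand-computable posterior variance,
and per-probe monotonicity of |t| in `d0` are all asserted in the tests.
Ensembles of fewer than 10 probes cannot support hyperparameter estimation;
the model object then reports ordinary t with a warning.

Multiple testing uses the Benjamini–Hochberg step-up with q-values
`q_(i) = min_{j≥i} m·p_(j)/j` capped at 1, flagged at FDR 1% by default.
The implementation is cross-checked in the tests against both a literal
brute-force evaluation of the definition and the statsmodels
implementation.

## Cell-specific deconvolution

The measured whole-blood signal is modelled as a fraction-weighted mixture
of cell-type-specific expression. Within each group g, expression is
regressed onto the relative cell-type frequencies **through the origin**
(zero cells, zero signal):

    y_g = β_1g x_1g + … + β_Kg x_Kg + ε_g

so β_kg is the mean expression attributable to cell type k in group g.
Fractions are carried on the 0–1 scale and rows are renormalized to sum to
1 (printed leukocyte differentials need not close to 100%); the per-percent
coefficient some reports quote is the 0–1 coefficient × 0.01, and the scale
choice cancels exactly in the test statistic. With the small HC group
(n = 4), the five leukocyte classes are collapsed to K = 2: granulocytes
(neutrophils + eosinophils + basophils) and PBMC (lymphocytes + monocytes);
the grouping scheme is configurable.

Groups are compared per cell type with a Wald-like contrast whose SE pools
the per-group coefficient SEs with sample-size weights:

    t_k21 = (β̂_k2 − β̂_k1) / se_k21,
    se_k21 = √((n1·se²_k1 + n2·se²_k2)/(n1 + n2))

Significance comes from an empirical null built by reshuffling the group
labels B = 1000 times; each sample's (expression, fractions) pair travels
intact, which is the only reshuffling under which the statistic is
exchangeable under the null. The p-value is two-sided with the
(b+1)/(B+1) convention (minimum attainable p = 1/1001 at B = 1000);
two-sidedness is chosen for consistency with the Wald analogy since the
sidedness is not otherwise determined. The permutation fits are evaluated
in a batched form (per-permutation normal equations via einsum), so a full
B = 1000 run costs milliseconds; singular within-group designs are
resampled.

### Power at the profiled study's scale — a measured limitation

The permutation test is exactly calibrated (null rejection 0.050 at nominal
0.05 over 200 replicates), but its power at n = 4 vs 7 with K = 2 is low
for moderate effects, for two structural reasons: (i) the two fraction
columns sum to 1 and granulocytes dominate (mean ≈ 0.65), so
se(β̂_PBMC) ≈ σ·m_gran/(s·√n) is several residual sds when the
granulocyte-fraction spread s is the realistic 0.12–0.19; (ii) the n = 4
group's coefficient SEs rest on n − K = 2 residual df, making the
permutation null heavy-tailed — an observed |t| of 5–6 can still sit near
the 5% tail. Measured over 50 simulation replicates at a PBMC-only effect
of 4 residual sds, PBMC power at p ≤ 0.05 is ≈ 0.1 under fraction spreads
matched to the printed differentials, and only ≈ 0.5 even under maximally
dispersed fractions; ≈ 90% power requires an effect of roughly 16 residual
sds. Detection of a real cell-specific signal at this design size therefore
implies a very large underlying effect. The granulocyte false-positive rate
stays near nominal throughout.

## Synthetic cohorts

`simulate.SimulationConfig` defaults encode the profiled design: 4 HC,
7 paired pre/post asthmatics (18 samples), 734 endogenous probes, 6 positive
controls on a geometric 4-fold ladder between the printed 0.125 and 128 fM
endpoints, 8 negative controls, 5 housekeeping mRNAs, K = 2 cell types.

* **Fractions** are Dirichlet per group, moment-matched to the printed
  granulocyte/PBMC differential means and spreads (α0 = m(1−m)/s² − 1,
  with sd = SE·√n propagated from the component classes): HC (3.3, 1.7),
  pre (9.4, 5.5), post (28.4, 12.9).
* **Counts** are negative binomial (gamma–Poisson, variance μ + φμ², single
  global dispersion φ = 0.1, Poisson at φ = 0) around
  `libsize_s · eff_s · Σ_k f_sk · cell_means[p,k,g]`, with log-normal
  per-sample library-size and assay-efficiency factors (σ = 0.1 each; the
  efficiency factor also scales the spike-ins and is removed by
  positive-control normalization). Per-probe baselines are log-normal
  (median 25 counts, log-sd 1.6), giving the same qualitative attrition as
  a real panel (roughly a third of probes detected, ~10% passing the
  100-count filter). Negative controls are rounded truncated Gaussians
  (mean 8, sd 3 counts).
* **Ct tables** follow `Ct = ct_at_unit − log2(abundance)` (exactly one
  cycle per doubling), with duplicate wells, Gaussian replicate noise
  (sd 0.15 cycles) and reference assays RNU44/RNU6B; low abundances
  naturally produce Ct > 35, the censoring limit.

These are stand-ins: the generator does not emulate ligation chemistry,
probe cross-hybridization, sequence content, or the real assay's
(unpublished) noise process, and the cohort manifest says so. Passing tests
demonstrate correctness of the computations and calibration under this
generative model, not fidelity to any particular instrument.

## qPCR validation arm

Replicate wells are averaged per (sample, assay); censoring at Ct > 35 is
applied to the collapsed mean (the detection limit applies to the
measurement, not to individual wells). ΔCt = Ct_target − mean(Ct_RNU44,
Ct_RNU6B) — the reference mean is per sample, which is the only reading
consistent with "normalizing" — and relative expression is 2^−ΔCt. A
censored reference excludes the sample with a logged reason. Either ΔCt or
2^−ΔCt can be regressed onto cell fractions; 2^−ΔCt is the default since
the cell-mixture model is additive on the linear abundance scale.

## Cohort summaries

PC20 group summaries use the geometric mean, adopted because it reproduces
both printed group values (3.3 and 1.7 mg/ml) from the per-subject entries.
The standard error of means uses the population (n) sd denominator by
default — the convention that reproduces the printed 32.7 ± 3.3 for the
asthmatic ages (the n−1 convention gives 3.6 and is selectable). Rounding
(1 decimal for means, 2 significant figures for shifts) is display-only.
Group comparisons of blood-count analytes use one-way ANOVA, which for two
groups equals the equal-variance t-test.

## Problem sizes

The bundled calibration/power harnesses use 200 replicates for permutation
calibration (B = 1000), 50 replicates for the power study, and 50 × 1000
probes for the DE null study — sizes at which the Monte-Carlo error is a
small fraction of the quantities compared and a full run takes seconds on
one CPU, thanks to the batched permutation fits and vectorised ordinary DE
path.
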