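# mirblood

Analysis of whole-blood miRNA profiles from digital hybridization counting
panels (NanoString nCounter-style), built for allergen-inhalation-challenge
studies in asthma: healthy controls versus asthmatics sampled immediately
before and ~2 hours after challenge. Whole blood is a cell mixture, so the
package pairs conventional differential expression with a cell-specific
deconvolution that asks *which* leukocyte compartment carries a signal.

It provides, as a library plus a `mirblood` command line:

* **Count preprocessing** — probe background correction, positive
  spike-in normalization (six controls, 0.125–128 fM), per-sample
  negative-control background thresholding (mean + 2 sd, detection in all
  samples), content normalization to the detected set, a ≥100-count filter
  and log2 transform, with a QC report of probe attrition.
* **Moderated differential expression** (`TwoGroupDE` → `DEResults`) —
  per-probe robust two-group linear models (Huber IRLS), empirical-Bayes
  variance shrinkage with moderated t on d0 + df degrees of freedom, and
  Benjamini–Hochberg FDR (1% by default).
* **Cell-specific deconvolution** (`CellDeconvolution` → `DeconvResults`) —
  per-group regression of expression onto cell fractions *through the
  origin*, y_g = Σ_k β_kg x_kg + ε_g, so β_kg is the expression
  attributable to cell type k; groups compared per cell type with the
  Wald-like statistic

      t_k21 = (β̂_k2 − β̂_k1) / √((n1·se²_k1 + n2·se²_k2)/(n1+n2))

  against a 1000-permutation empirical null (labels reshuffled, each
  sample's expression/fraction pair intact; two-sided (b+1)/(B+1) p).
* **RT-qPCR validation** — duplicate collapsing, Ct > 35 censoring,
  ΔCt against the mean of RNU44/RNU6B, relative expression 2^−ΔCt, and the
  same cell-fraction regression on the qPCR readout.
* **Cohort summaries** — geometric-mean PC20, allergen-induced shift
  (pre PC20 / post PC20), mean ± SE demographics, one-way ANOVA group
  comparisons of blood counts.
* **A synthetic cohort generator** with known cell-specific ground truth
  (Dirichlet fractions moment-matched to published leukocyte differentials,
  negative-binomial mixture counts, spike-in ladders, Ct tables), so every
  stage is testable end to end without any external data.

## Worked example

Simulate a paper-scale cohort (4 HC, 7 paired pre/post asthmatics, 734
probes) in which one PBMC-dominant miRNA is under-expressed in asthmatics
and drops further after challenge, then run the full analysis:

```python
import numpy as np
from mirblood.simulate import SimulationConfig, simulate_cohort, default_cell_means
from mirblood.preprocess import run_preprocess
from mirblood.de import TwoGroupDE
from mirblood.deconvolution import CellDeconvolution, CellFractions

cfg = SimulationConfig(seed=7)
cell_means = default_cell_means(cfg, np.random.default_rng(7))
cell_means[41, 0, :] = 150.0                     # granulocytes (HC, pre, post)
cell_means[41, 1, :] = [20000.0, 2500.0, 500.0]  # PBMC
cohort = simulate_cohort(SimulationConfig(seed=7, cell_means=cell_means))

expr, qc = run_preprocess(cohort.counts)
for contrast in (("HC", "pre"), ("pre", "post")):
    res = TwoGroupDE.from_dataframe(expr.values, cohort.metadata, contrast).fit(fdr=0.01)
    print(res.summary(top=2))

frac = CellFractions(cohort.fractions, source="simulated")
model = CellDeconvolution(expr, frac, cohort.metadata)
print(model.fit(("HC", "pre"), probes=["hsa-miR-SIM0042"], B=1000, seed=7).summary())
```

The QC report shows the attrition ladder — 734 probes profiled, 291 above
background in every sample, 53 above 100 counts:

```
input                            endogenous retained: 734
negative_background_threshold    endogenous retained: 291
filter_min_count                 endogenous retained: 53
```

The spiked probe is the one discovery in *both* contrasts at BH FDR 1%
(log2 fold changes −2.5 and −2.1, i.e. ~6-fold and ~4-fold down):

```
Two-group moderated differential expression
  contrast: pre - HC   robust: True
  probes: 53   residual df: 9   prior df: 7.42825   prior var: 0.1735
  significant at BH FDR 0.01: 1

                 logFC     se      t        p  posterior_sd         q   flag
hsa-miR-SIM0042 -2.516 0.4002 -6.865  3.3e-06        0.4755 0.0001749   True
```

The deconvolution attributes the drop to PBMCs — the PBMC coefficient
(mean expression attributable to PBMCs) falls by 3.3 log2 units versus 2.1
for granulocytes — though at n = 4 vs 7 the permutation p-values remain
above 0.05, a power limitation of this design size that is quantified in
`docs/methods.md`:

```
          probe    cell_type  beta_g1  se_g1  beta_g2  se_g2      t  pooled_se  p_perm
hsa-miR-SIM0042 granulocytes    10.59  1.033    8.531 0.3866 -2.967      0.695 0.06893
hsa-miR-SIM0042         pbmc    15.49   1.82    12.14 0.6768 -2.738      1.223  0.1489
```

The cohort summary reproduces the derived demographics of the bundled
example table (`mirblood.cohort.demo_subjects()`):

```
age (asthmatic): 32.7 +/- 3.3
geometric mean PC20 pre:  3.3 mg/ml
geometric mean PC20 post: 1.7 mg/ml
allergen-induced shifts (pre/post): 0.44, 2.5, 0.62, 1.5, 3.4, 3.6
shift mean +/- SE: 2.0 +/- 0.5
```

The same stages are available from the shell:

```sh
mirblood simulate --out sim --seed 7
mirblood preprocess --counts sim/counts.csv --out prep
mirblood de --expr prep/expression.csv --meta sim/metadata.csv --contrast HC:pre --out de.csv
mirblood run --config run.yaml     # full pipeline with a provenance manifest
```

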