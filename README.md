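# rbdge

Digital gene-expression analysis of retinoblastoma subtypes, built as a
reusable, tested Python package.

Retinoblastoma tumors fall into two histopathological subtypes —
undifferentiated (URB), which carries high-risk features, and differentiated
(DRB).  Profiling the two on a NanoString nCounter panel (770 endogenous
genes, 30 housekeeping reference genes, a positive-control ladder and
probe-free negatives) gives per-lane digital counts from which subtype
markers and pathway activity can be read out.  `rbdge` implements that whole
analysis chain for anyone working with nCounter-style count data in small
two-group cohorts:

* **RCC I/O** — parse and emit the plain-text Reporter Code Count lane
  format, assemble probes × samples count matrices, read annotation tables.
* **Normalization** — per-lane positive-control factors
  `f_l = mean(g)/g_l` (geometric means of the spike-in ladder), background
  subtraction at `τ_l = μ_l + 2σ_l` from negative controls,
  housekeeping-gene biological normalization `r_l = mean(h)/h_l`, and a
  one-sided one-sample *t*-test noise filter (a gene is "expressed" iff
  *p* ≤ 0.05 against the pooled threshold).
* **Differential expression** — per gene on log2(x+1) counts: Shapiro–Wilk
  gates each group; both normal → pooled-variance Student's *t*, otherwise
  Wilcoxon–Mann–Whitney (exact for tie-free pooled n ≤ 12); FDR control by
  Benjamini–Hochberg with significance at *q* ≤ 0.05; plus mean–variance QC,
  sample correlation, PCA and hierarchical clustering.
* **Clinical table battery** — Pearson χ² (no continuity correction),
  two-sided point-probability Fisher exact, tie-corrected Kruskal–Wallis and
  Mann–Whitney over subtype-stratified covariates.
* **Marker scoring** — per-gene ROC (URB positive), Mann–Whitney AUC,
  percentile bootstrap CIs (B = 1000), Youden-*J* cutoffs, a summed
  binarized composite score S, and a least-squares logistic curve
  P(URB | S) = 1/(1+e^−(a+bS)).
* **Conditional inference trees** — permutation-moment association tests
  (T = Σxᵢyᵢ with conditional mean and variance), Bonferroni variable
  selection, α-stopping, and leave-one-out cross-validation. Written from
  first principles.
* **Pathway overlay** — ternary (−1/0/+1) node states for curated MAPK,
  PI3K–AKT and cell-cycle diagrams by majority vote of significant member
  genes, with hypergeometric over-representation p-values.
* **Synthetic cohorts** — a seeded negative-binomial (gamma–Poisson)
  generator emulating the CodeSet, lane-specific technical factors,
  background-level genes and a configurable fraction of truly differential
  genes, with full ground truth, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from rbdge.simulate import SimulationConfig, simulate_dataset
from rbdge.normalization import normalize_pipeline
from rbdge.de import run_de
from rbdge.scoring import (select_markers, composite_score,
                           score_performance, fit_probability_model,
                           predict_probability)

ds = simulate_dataset(SimulationConfig(seed=42))   # 11 URB + 10 DRB + 2 controls
norm, tfac, rfac, calls, bg = normalize_pipeline(ds.counts)
print(f"above noise: {sum(c.above_noise for c in calls)}/770")

de = run_de(norm, ds.annotations, calls)
print(f"differential (q<=0.05): {int(de.significant.sum())}/{len(de)} tested")

markers = select_markers(de, norm, ds.annotations, top_k=5)
score = composite_score(markers)
labels = np.array(["URB"] * 11 + ["DRB"] * 10)
sens, spec, sweep = score_performance(score, labels, threshold=3)
print(f"score>=3 -> sensitivity {sens:.2f}, specificity {spec:.2f}")

model = fit_probability_model(score.scores.to_numpy(), labels)
print(f"P(URB|S=4) = {predict_probability(model, 4):.3f}")
```

prints

```
above noise: 724/770
differential (q<=0.05): 157/724 tested
score>=3 -> sensitivity 1.00, specificity 1.00
P(URB|S=4) = 1.000
```

724/770 genes clear the noise floor (46 genes are simulated at the
negative-control background and are correctly filtered), 157 of the 724
tested genes are called differential at *q* ≤ 0.05 (the generator plants
154 true effects among the tested set at |log2 FC| = 1.5), and the 5-gene
composite score separates the subtypes perfectly at threshold 3, so the
fitted probability curve saturates.

A command-line interface mirrors the stages
(`rbdge simulate|normalize|de|table1|score|ctree|pathway|run`); `rbdge run
--config pipeline.yaml` executes everything and writes a manifest plus one
artifact per stage.

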