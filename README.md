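# braindeconv

Marker-based cell-type deconvolution for bulk brain RNA-seq, with the full
evaluation loop around it: synthetic benchmark generation, marker-gene
selection, three proportion estimators plus a single-gene baseline,
accuracy metrics, and the two downstream analyses that motivate
deconvolution in the first place — composition-adjusted phenotype
association and cell-type interaction eQTL scanning.

## The problem

Bulk cortical RNA-seq mixes the transcriptomes of neurons, astrocytes,
oligodendrocytes, microglia and endothelial cells in unknown, per-sample
proportions. A gene's apparent expression change can therefore reflect a
shift in cell composition rather than a change in gene activity, which
inflates false positives in disease-association studies and hides
cell-type-specific genetic regulation. Deconvolution estimates the mixing
proportions from the bulk profile using cell-type marker genes, so that
composition can be measured, adjusted for, and exploited.

## Methods implemented

**Marker selection.** Per cell type, a one-vs-rest Welch t-test on log2 CPM
with Benjamini–Hochberg correction; markers are the top *k* genes (default
100) by log2 fold-change among those with FDR < 0.05. Helpers remove genes
shared between lists and filter subtype markers that are not actually
enriched in the parent type.

**Estimators.** With bulk expression O (genes × samples) and marker-average
matrix M (cell types × samples):

- *DSA-style* (semi-supervised; marker identities only): model
  M = diag(s) P with P on the simplex, solve Σₖ M[k,j]/sₖ = 1 for all
  samples j by non-negative least squares, and set P = diag(1/s) M,
  clipped and renormalised.
- *NNLS* (supervised): per sample solve min‖y − Xβ‖², β ≥ 0, where X is the
  signature matrix of per-type mean marker expression; normalise β.
- *log-mean*: per-type mean log2 expression minus the pure-reference
  offset, exponentiated and normalised.
- *single-marker baseline*: one gene per type (ENO2/GFAP/CD68/CD34/OLIG2 in
  the classic brain panel), raw expression as a relative score.

**Evaluation.** Per-cell-type Spearman/Pearson correlation across samples
(relative accuracy), MSE with a 10 000-permutation significance test
(absolute accuracy), the critical correlation r\* = t\*/√(n−2+t\*²), and
per-gene percent-variance-explained regression on the proportions.

**Downstream.** Per-gene phenotype association with and without proportion
covariates (Bonferroni classification into both / unadjusted-only /
adjusted-only / neither), and the interaction-eQTL model
y = αg + βc + γ(g×c) scanned over cis SNP–gene pairs (±1 Mb around the
TSS) with a global BH FDR of 0.1.

**Simulation.** A labelled single-cell population with planted markers,
pseudo-bulk mixtures of cells drawn with replacement (realised fractions
kept as ground truth), negative-binomial read noise (Var = μ + φμ²),
IHC-like multiplicative measurement error, composition-confounded
phenotypes, and genotypes with planted interaction effects. See
`docs/methods.md` for the model details and limitations.

## Worked example

```python
from braindeconv import (standard_scenario, deconvolve_dsa,
                         per_celltype_correlation, critical_correlation,
                         mse_per_celltype)

scen = standard_scenario(seed=1)            # 5 types, 70 mixtures, phi = 0.2
props = deconvolve_dsa(scen.bulk, scen.markers)
corr = per_celltype_correlation(props, scen.truth.proportions)
mse = mse_per_celltype(props, scen.truth.proportions)
print(corr[["r", "p"]].join(mse).round(4))
print(f"critical r at n=70: {critical_correlation(70, 0.05, 'one'):.3f}")
```

prints

```
                      r    p     mse
cell_type
Neuron           0.9829  0.0  0.0075
Oligodendrocyte  0.9765  0.0  0.0058
Astrocyte        0.9777  0.0  0.0028
Microglia        0.9657  0.0  0.0031
Endothelial      0.9508  0.0  0.0048

critical r at n=70: 0.198
```

Every cell type — including endothelial cells at 7 % of the population —
is tracked far above the 0.198 one-sided significance threshold for 70
samples (the usual "r > 0.2" rule), and the absolute proportions are
recovered to within a few percentage points (MSE ≤ 0.0075).

The same workflow is available from the shell:

```bash
braindeconv simulate --out run/ --seed 1
braindeconv deconv --expression run/expression.tsv --markers run/markers.gmt \
                   --method dsa --out run/props.tsv
braindeconv evaluate --pred run/props.tsv --truth run/truth.tsv --out run/report.tsv
```

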