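# gliamorph

Integrated analysis of CNS inflammation at two coupled levels: unsupervised
multivariate statistics of **microglial morphology** and dynamical modeling of
the **cytokine network** that drives it.

Microglia — the resident immune cells of the central nervous system — change
shape when inflammation is triggered (for example by systemic LPS, a TLR-4
agonist): somata swell, process arbors retract and remodel. Those changes
track cytokine signaling, most prominently the tension between
pro-inflammatory TNFα and anti-inflammatory IL-10. This package implements a
pipeline for studying that coupling in a two-genotype design (wild type vs.
*IL-10⁻/⁻* knockout, four time points over five days after LPS):

* **Feature expansion** — per-cell morphometry exports (16 scalar soma and
  whole-filament features, 12 per-process distributed features) are expanded
  into a cells × 110 matrix: each distributed feature contributes its mean,
  median, mode, standard deviation, coefficient of variation, 95% CI
  half-width, skewness and kurtosis.
* **Time-course testing (ODP-style)** — per feature, natural cubic splines
  are fitted to the temporal profile pooled across genotypes (error SS⁰) and
  per genotype (error SSᴬ); the statistic *F = (SS⁰ − SSᴬ)/SSᴬ* is calibrated
  by a stratified residual bootstrap and converted to q-values.
* **Feature selection** — a feature enters downstream analysis when its PCA
  loading magnitude across the first four components exceeds 0.2 or its
  time-course p-value is below 0.05.
* **Offset-NMF cell states** — the selected, Z-scored, min-shifted matrix
  **D** (features × cells) is factorized as **D ≈ WH + c·1ᵀ** with NNDSVD
  initialization and multiplicative updates; the per-feature offset *c*
  absorbs constant expression. Cells are classified by their largest
  coefficient (six morphological states at rank 6) and feature sets are read
  off the basis rows. Nonmetric MDS on the Spearman distance *d = 1 − ρ*
  validates the classes; a hypergeometric test scores knockout enrichment.
* **Adaptation indices** — per feature and genotype, the scaled mean profile
  Z̄ ∈ [0, 1] yields *A = 1 − (Z̄_final − Z̄_t0)/(Z̄_peak − Z̄_t0)* (A = 1:
  complete recovery to baseline). Uncertainty is propagated to first order,
  and genotypes are contrasted with a conservative pooled-spread T statistic
  (df = 2·n_min − 2, Benjamini–Hochberg within feature sets).
* **Cytokine network model** — six microglial cytokines (TNFα, IL-1β, IL-6,
  TGFβ, IL-10, CCL5) with Hill-type activation/inhibition, an LPS production
  multiplier, and a CNS-environment compartment: a first-order delay cascade
  converts microglial IL-10 into environmental TGFβ that feeds back onto
  IL-1β and IL-6. Degradation constants are derived so that every species
  rests at 0.1 until stimulated. Knockouts remove a node and its edges;
  dose–response sweeps compare wild type and IL-10 knockout.

Because no raw data are deposited for this kind of study, the package ships a
seed-reproducible synthetic generator that emulates the design (218 cells
from 28 mice, long-tailed feature distributions, six latent cell states, and
an LPS perturbation whose recovery is more complete in the knockout) so every
stage is exercisable and testable end to end.

## Worked example

```python
from gliamorph import synthetic as syn
from gliamorph.features import build_feature_matrix, zscore, select_features, shift_nonnegative
from gliamorph.odp import odp_test
from gliamorph.multivariate import pca, nmf, cluster_enrichment
from gliamorph.adaptation import adaptation_table

cells = syn.generate_cells(syn.default_design(seed=0))
z = zscore(build_feature_matrix(cells))       # 218 cells x 110 features
odp = odp_test(z, n_boot=500, seed=0)
print(odp.sort_values("q").head(3)[["F", "p", "q"]].round(4))
#                               F      p       q
# feature
# Soma ellipsoid length A  0.0994  0.002  0.0339
# Soma ellipsoid length C  0.0920  0.002  0.0339
# Number vertices          0.0977  0.002  0.0339
```

Soma-geometry features show the strongest genotype-specific dynamics (small
bootstrap p at the 1/501 floor; q < 0.05), exactly the planted contrast: the
knockout's soma response peaks earlier and recovers more completely.

```python
selected = select_features(pca(z).loadings, odp["p"])   # 54 features
zsel = z.subset(selected)
dec = nmf(shift_nonnegative(zsel), rank=6, seed=0)
print(dec.cell_clusters.value_counts().sort_index().to_dict())
# {1: 40, 2: 45, 3: 50, 4: 44, 5: 25, 6: 14}
print(cluster_enrichment(dec.cell_clusters,
                         zsel.row_meta["genotype"]).sort_values("p").head(1))
#  cluster  size  n_KO        p
#        4    44    27 0.002258
```

Six non-empty morphological classes emerge; one (the activated, large-soma
state) is significantly enriched in knockout cells (hypergeometric
p ≈ 0.0023).

```python
indices, comparisons = adaptation_table(zsel)
print(comparisons[comparisons.feature == "Soma area"]
      [["feature", "A_WT", "A_KO", "T", "q"]].round(3))
#     feature  A_WT   A_KO       T    q
#   Soma area  0.69  0.926  25.366  0.0
```

Soma area recovers ~69% of its excursion in the wild type but ~93% in the
knockout — IL-10 impedes the adaptive recovery of the inflammatory
morphology, the counter-intuitive headline the network model reproduces *in
silico*:

```python
from gliamorph.cytokines import default_network, dose_response
print(dose_response(default_network(), (0.1, 1.0, 10.0)).round(3))
# variant  dose   peak  adaptation
#      wt   0.1  0.555       0.994
#      wt   1.0  2.194       0.952
#      wt  10.0  3.497       0.971
#      ko   0.1  0.611       1.000
#      ko   1.0  2.909       1.000
#      ko  10.0  5.207       1.000
```

The knockout's TNFα peak is larger at every dose, yet its adaptive recovery
is at least as complete — removing the negative feedback *enhances*
adaptation.

## Command line

```bash
gliamorph run-all --seed 0 --outdir results/
gliamorph simulate --outdir results/        # just the network simulation
```

Every output table carries a provenance header (package version, seed,
configuration hash); reruns with the same configuration are byte-identical.

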