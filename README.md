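# ifnomics

Interferon-score analysis of trisomy 21 (T21) multi-omics cohorts.

People with Down syndrome carry three copies of the four interferon-receptor
genes on chromosome 21 and live with chronically hyperactive interferon
(IFN) signaling — an "interferonopathy" whose strength varies widely between
individuals. A practical way to measure that strength from whole-blood
RNA-seq is an **IFN score**: for a panel of interferon-stimulated genes
(ISGs), z-score each gene against the euploid-control mean and SD of
covariate-adjusted expression, then sum,

```
score(s) = Σ_g  ( x_gs − μ_g^ctrl ) / σ_g^ctrl
```

so a control sample scores ~0 and a sample one control-SD high on every one
of 18 signature genes scores exactly +18. `ifnomics` implements the full
analysis pipeline around that statistic for researchers studying IFN
biology in T21 (or any two-group cohort with a graded latent driver):

* **`synthetic`** — a cohort generator with a latent per-individual IFN
  activity that drives planted ISGs (~1.5× chr21 dosage on top), plasma
  analyte panels, immune-cell compositions and clinical condition flags,
  plus one longitudinal on/off-drug subject. Every downstream stage is
  testable against this generative truth.
* **`preprocess`** — 3×IQR extreme-outlier fences per karyotype per
  analyte, immunoassay fit-range resolution (per-plate min/max fill,
  duplicate-well averaging, >10 % out-of-range flagging), metabolite zero
  replacement + per-sample median normalization, and protected linear-model
  covariate adjustment.
* **`signature`** — T21 vs control differential expression (per-gene linear
  model on log2 RPKM) filtered to ISGs with fold change ≥ 1.5, q < 0.1, and
  not on chr21 (dosage-driven ISGs are deliberately excluded).
* **`scoring`** — `IFNScorer`, an sklearn-style transformer that freezes
  control reference stats at `fit` and scores any sample at `transform`;
  plus the kynurenine/tryptophan ratio.
* **`association`** — Spearman screens with BH q-values, log2 differential
  abundance models, beta regression (logit link, constant precision, Fisher
  scoring) for compositional immune-cell frequencies, and preranked GSEA
  with a gene-label permutation null.
* **`stratify`** — Monti consensus clustering (Pearson distance, subsampled
  hierarchical clustering, delta-area k selection), Gower distances over
  mixed clinical data, PAM with silhouette-based k selection,
  observed/expected condition enrichment with Fisher tests, Mann-Whitney
  score comparisons.
* **`longitudinal`** — on/off-drug fold changes, cohort IQR reference
  bands, and score-trajectory classification for a JAK-inhibitor case.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from ifnomics import (CohortConfig, generate_cohort, differential_expression,
                      select_isg_signature, IFNScorer)

cohort = generate_cohort(CohortConfig(seed=1))          # 300 T21 / 100 control
de = differential_expression(cohort.expression, cohort.metadata)
sig = select_isg_signature(de, cohort.gene_annotation)
print(f"signature size: {len(sig)} genes")

controls = list(cohort.metadata.index[cohort.metadata.karyotype == "control"])
scorer = IFNScorer(signature=sig).fit(cohort.expression, controls)
scores = scorer.transform(cohort.expression)["ifn_score"]
t21 = cohort.metadata.karyotype == "T21"
print(f"median IFN score: T21 {scores[t21].median():.1f}, "
      f"control {scores[~t21].median():.1f}")
rho = spearmanr(scores, cohort.latent.activity)[0]
print(f"Spearman rho vs latent IFN activity: {rho:.3f}")
```

prints

```
signature size: 18 genes
median IFN score: T21 27.0, control 0.7
Spearman rho vs latent IFN activity: 0.981
```

All 18 planted ISGs are recovered with no false positives; T21 samples sit
far above controls with wide overlap-free spread; and the score tracks the
generator's hidden IFN activity almost perfectly — which is the point of
the statistic: it is a per-sample estimate of an unobservable latent drive.

A `simulate → signature → score → associate → stratify → longitudinal`
command-line surface mirrors the library (`ifnomics --help`).

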