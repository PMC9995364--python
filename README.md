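# amlsc — single-cell AML analysis toolkit

`amlsc` implements the bespoke computational procedures used to track acute
myeloid leukemia (AML) and its chemotherapy-resistant leukemia stem cells
(LSCs) through longitudinal single-cell RNA-seq, and to translate a
stemness signature into a survival risk model. It is aimed at computational
biologists who need these procedures as tested, seedable library functions
rather than analysis-notebook fragments:

* **NPM1 mutation genotyping from 3' reads** — the NPM1 type-A mutation (a
  TCTG tandem duplication at chr5:171410540–171410543) is captured by 3'
  scRNA-seq reads. Reads are matched against the duplication core
  `TCTCTGTCTGGC` and its nine boundary-truncated, anchored variants;
  molecules are UMI-collapsed; cells are classed MUT (≥ 1 mutant UMI),
  WT (> 5 wild-type UMIs, none mutant), ND (≤ 5 WT UMIs) or NoCall (no
  locus coverage); clusters are extended wholesale to leukemic through a
  sequential rule list keyed on MUT/WT fractions.
* **Chromosome-7 monosomy calling** — del(7) halves aggregate chr7
  expression; cells are scored with an expression-bin-matched module score
  (mean over chr7 genes minus mean over matched controls) and split by an
  exact 1-D two-means, low mode → AML.
* **Signature scoring and reduction** — module-score positivity (score > 0)
  for the miR-126-derived 126High stemness signature, plus an item-test
  reduction keeping genes with Spearman rho > 0.3 (Bonferroni p < 0.05)
  against the full-signature score.
* **Cross-platform survival risk** — per-patient quartile categorization
  (−1/0/+1), lasso-penalized Cox with 10-fold CV, training-median split of
  the linear predictor, transfer to a test cohort, log-rank + hazard ratio.
* **Auxiliary statistics** — hashtag-label rescue/discard via a
  medoid-anchored 0.98-quantile boundary on a 2-D embedding; single-hit
  limiting-dilution stem-cell frequency (cloglog GLM, Wald CI); Cohen's
  kappa between gene sets over a DEG universe.
* **Synthetic data with ground truth** (`amlsc.syndata`) — seeded generators
  for every input above (planted duplication reads, monosomy count matrices,
  latent-coupled signature genes, survival cohorts, hashtag embeddings,
  dilution tables), so every procedure is testable against known truth.

See `docs/methods.md` for the models, assumptions and parameter defaults.

## Worked example

End-to-end on synthetic data (simulate → genotype → classify → score →
reduce → risk → refine → dilution), library API:

```python
import amlsc
from amlsc.pipeline import run_end_to_end

metrics = run_end_to_end(amlsc.SynthConfig(seed=7, n_cells=600, n_patients=120), "out/")
```

which prints (seed 7):

```json
{
 "genotyping":    {"n_cells": 600, "n_called_mut": 173, "mut_recall": 0.72, "mut_false_calls": 0},
 "chr7_monosomy": {"accuracy": 0.982, "silhouette": 0.797, "weak_bimodality": false},
 "signature":     {"pct_positive": 65.7, "n_kept": 49, "recall": 0.98, "false_keep": 0},
 "survival":      {"test_logrank_p": 0.0051, "test_hazard_ratio": 2.77, "n_test_events": 37},
 "hto":           {"rescued_fraction": 1.0, "stray_discarded_fraction": 1.0},
 "lda":           {"frequency": 0.00167, "ci": [0.00098, 0.00285], "ci_covers_truth": true}
}
```

Reading the numbers: 72% of cells carrying a planted mutant molecule are
directly called MUT (the rest have reads that genuinely miss the
duplication window — no false positives occur); monosomy labels recover the
planted AML cells at 98% accuracy; the signature reduction keeps 49 genes,
recovering 49/50 planted informative genes and none of the 150 decoys; the
transferred risk model separates test-cohort survival (log-rank p = 0.005,
HR ≈ 2.8 against a planted HR of 3); every planted mislabeled-Negative cell
is rescued and every stray discarded; the dilution CI covers the planted
frequency of 1/500.

The same stages are exposed as a CLI (`amlsc --help`). For example:

```bash
$ amlsc simulate lda --seed 3 --out simdemo
$ amlsc lda --table simdemo/lda.tsv
{"frequency": 0.001369, "one_in": 730.6, "ci": [0.000808, 0.002319], "confidence": 0.95, "status": "ok"}
```

i.e. an estimated stem-cell frequency of about 1 in 731 transplanted cells
(95% CI 1/1238–1/431) from a 3-dose × 12-mouse table generated at a true
frequency of 1/500.

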