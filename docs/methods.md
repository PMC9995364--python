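# Methods

This note documents the statistical procedures `amlsc` implements, the
assumptions behind them, the tunable parameters, what the synthetic-data
generators emulate (and deliberately do not), and the numerical choices made
where the design was open.

## NPM1 type-A mutation genotyping (`amlsc.genotyping`)

The NPM1 type-A mutation is a 4-nt TCTG tandem duplication at
chr5:171410540–171410543, close enough to the 3' end of *NPM1* that 3'
scRNA-seq reads capture it. The genotyper rests on one asymmetric assumption:
**a single mutant transcript proves a cell leukemic, but absence of mutant
transcripts proves nothing** (dropout is pervasive at single-cell depth).

**Motif matching.** A read supports the mutant allele iff it contains the
unanchored core motif `TCTCTGTCTGGC`, ends with one of four suffix-anchored
truncations (`GATCTCTGTCTGG`, `GATCTCTGTCTG`, `GATCTCTGTCT`, `GATCTCTGTC`),
or begins with one of five prefix-anchored truncations (`CTCTGTCTGGCAG`,
`TCTGTCTGGCAG`, `CTGTCTGGCAG`, `TGTCTGGCAG`, `GTCTGGCAG`). Anchored motifs
catch duplications truncated at read boundaries. Matching is exact: a
sequencing error in the motif forfeits that read's evidence (sensitivity
cost) but exactness guarantees specificity; non-ACGT characters never match.

**UMI collapsing.** Reads sharing a (cell barcode, UMI) pair are one
molecule. A molecule is MUT if *any* read matches; otherwise WT if some
read's aligned interval fully contains the 4-nt locus (only then is absence
of the duplication informative — a design decision of this package, since the
minimal condition for wild-type evidence is full containment); otherwise
uninformative. On read–UMI conflicts MUT wins. UMIs are scoped within
barcodes; cross-cell UMI collisions are ignored.

**Cell classes.** MUT: ≥ 1 mutant UMI. WT: 0 mutant and > 5 WT UMIs.
ND (not detected): 0 mutant, ≤ 5 WT UMIs, with locus coverage. NoCall: no
read overlaps the locus by even one base. Cells with locus-overlapping reads
but no classifiable molecule are ND, reserving NoCall strictly for zero
coverage.

**Cluster extension.** Leukemic cells co-cluster, so per-cluster class
fractions drive a sequential rule list (first match fires): (1) MUT ≥ 40% →
whole cluster leukemic; (2) 20–40% MUT and WT < 5% → whole cluster; (3)
10–20% MUT, WT < 5%, myeloid cluster, NoCall majority → whole cluster; (4)
5–10% MUT, WT = 0%, myeloid, NoCall majority → whole cluster; (5) MUT < 5% →
only MUT cells. Whole-cluster extension never includes WT cells, which are
excluded from all downstream analysis. Configurations matching no rule (e.g.
25% MUT with 6% WT) conservatively fall back to rule-5 behavior and are
flagged. Fractions are computed over all cluster cells by default
(`denominator="covered"` restricts to covered cells); ND cells in rule-5
clusters are never leukemic. The myeloid flag is explicit per-cluster input
(it encodes a judgment — marker expression — this package does not automate,
though `modulescore.module_score` on a marker list thresholded at 0 is the
natural helper).

## Chromosome-7 monosomy classification (`amlsc.modulescore`)

Loss of one chr7 copy halves the aggregate expression of chr7 genes. Per-cell
evidence is a **module score**: counts are normalized to 10,000 per cell and
log1p-transformed; genes are ranked by dataset-average expression into
`n_bins` = 24 equal-count bins; each target gene draws `n_ctrl` = 100 control
genes from its own bin; the score is the mean over target genes minus the
mean over the pooled (deduplicated) control genes. Bin-matched controls
cancel depth and abundance effects, so a constant matrix scores exactly zero
and adding a constant to all log-values leaves scores unchanged. When a bin
holds ≤ `n_ctrl` genes the whole bin serves as control pool (sampling with
replacement would break the exact-zero identity when the gene set is the
whole matrix). Control draws are keyed by gene *name*, making scores
invariant under gene reordering. The defaults mirror the conventional
single-cell scoring parameters; neither is reported by upstream work, so both
are exposed.

The chr7 score distribution over a mixed sample is bimodal; a **two-cluster
1-D k-means** labels the low-score mode AML. The 1-D problem is solved
exactly (optimal contiguous split of the sorted scores minimizing
within-group variance), removing initialization randomness entirely; the
low/high → AML/non-AML mapping therefore cannot flip between runs. A
silhouette of the split is reported with a `weak_bimodality` flag below 0.4 —
a reporting aid, not a gate. Note the optimal split of even unimodal 1-D data
has silhouette ≈ 0.5, so the flag marks only near-degenerate inputs; the
planted-monosomy regime scores ≈ 0.8.

## Signature scoring and item-test reduction (`amlsc.signatures`)

The 126High signature (genes upregulated in miR-126-high leukemic stem
cells) is scored with the same module score; a cell is positive iff its score
is strictly > 0, and percent-positive is summarized per sample.

The **item-test reduction** keeps the genes that drive the full-signature
score, as in reliability analysis: each signature gene's expression is
Spearman-correlated with the full-signature score across all cells; kept
genes need rho > 0.3 and Bonferroni-corrected p < 0.05 (correction over the
signature's full gene list). Spearman is rank-based, so correlating
log-normalized expression is identical to correlating per-gene z-scored
("scale") data. P-values use the t approximation for n > 30 cells and a
seeded Monte-Carlo permutation test (9,999 resamples) below — exact
enumeration is infeasible between n = 10 and 30, and below 10 cells the
reduction refuses to run. Zero-variance genes have undefined rho and are
dropped with a reason code. Setting `alpha >= 1` disables the significance
gate entirely (no silent filtering when both thresholds are released).

Marker gating for differential expression: |logFC| ≥ 0.25, expressed in
> 25% of cells in at least one compared group, Wilcoxon p < 1e-5; and
intra-cluster comparisons are eligible only when both groups have ≥ 5 cells.

## Cross-platform survival risk stratification (`amlsc.survival`)

Expression from different platforms (microarray intensity, RNA-seq counts)
is incomparable in absolute terms, so each patient's profile is categorized
**by that patient's own quartiles**: −1 below Q1, +1 above Q3, 0 between,
with strict inequalities (boundary values → 0) and linear-interpolation
quartiles (the common default; the convention is exposed). Categorization
depends only on within-patient ranks, hence is invariant to any strictly
monotone per-patient transform — the property that makes cross-platform
transfer meaningful. The quartile universe defaults to all measured genes.

A **lasso-penalized Cox model** (coordinate-descent path via
scikit-survival's glmnet-equivalent) is fit on the categorized training
matrix. The penalty is chosen by seeded 10-fold cross-validation, stratified
by event status, minimizing the Verweij–van Houwelingen cross-validated
partial-likelihood deviance (the "CV error" is otherwise underspecified;
deviance is the package's choice, exposed). Ties are handled by Breslow's
method. The linear predictor's **training median** is the cutoff; high risk
iff predictor strictly > cutoff (ties go low). The model — coefficients and
cutoff — transfers to the test cohort unchanged; genes missing from test
data raise rather than impute. If the selected penalty zeroes every
coefficient the model is flagged degenerate and refuses to assign groups
(under null data this is the expected outcome more often than not). Groups
are compared with the log-rank test; the hazard ratio (high vs low) and Wald
95% CI come from a Cox fit on the group indicator; Kaplan–Meier curves are
emitted as step functions.

## Hashtag label refinement (`amlsc.auxstats.refine_hto`)

Droplet hashtag demultiplexing leaves false Negatives (background noise) and
false positives. On a 2-D embedding, cells sharing a hashtag form a compact
cluster. For each hashtag in input order: the **medoid** of its initially
labeled cells (the member minimizing summed Euclidean distance to the rest,
computed in chunks to bound memory) anchors a boundary whose half-width is
the 0.98 quantile of member distances to the medoid; the boundary is an
axis-aligned box by default (the quantile disc, also implemented, is always a
subset). Hashtag-labeled cells outside their boundary are discarded
(→ Negative, provenance `discarded`); Negative cells inside are rescued
(→ hashtag, provenance `rescued`). A cell rescued by an earlier hashtag is
never relabeled, and a discarded cell is never rescued — discarding means
removal from analysis. Boundaries derive from the *initial* labeling (frozen
in the state), which makes refinement exactly idempotent. Bare `Doublet`
labels carry no hashtag attribution and are untouched. Rescuing singlets of
*other* hashtags is off by design: it can oscillate between overlapping
clusters.

## Limiting-dilution frequency (`amlsc.auxstats.estimate_frequency`)

Under the single-hit model a recipient fails to engraft with probability
exp(−f·dose), f the stem-cell frequency per cell. The MLE comes from a
binomial GLM with complementary log-log link and log-dose offset (the
intercept is log f) — the same formulation as the standard limiting-dilution
estimator — with a Wald CI on log f back-transformed (default confidence
0.95). The estimator is exactly dose-scale-consistent (doses × c ⇒ f / c).
Boundary tables have no interior MLE: all-negative data report f = 0 with a
one-sided upper bound from inverting P(all negative); all-engrafted data
report "no limiting dose reached" with a one-sided lower bound from
inverting P(all engrafted) (solved by Brent's method).

## Gene-set kappa (`amlsc.auxstats.kappa_score`)

Cohen's kappa on the two binary membership vectors over a shared DEG
universe: κ = (p_o − p_e)/(1 − p_e), observed vs marginal-chance agreement —
an overlap measure weighted for the sets' sizes, used to cluster enriched
terms. Degenerate marginals (p_e = 1) yield κ = 1 for identical vectors and
an error otherwise, rather than NaN.

## Synthetic data (`amlsc.syndata`)

Every generator is seeded per (config seed, operation name), so adding a
generator never perturbs the others and identical configs are byte-identical.
Defaults define the simulated study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_cells` | 2000 | desk-scale single-sample dataset |
| `frac_aml` | 0.5 | balanced leukemic/normal mixture |
| `mut/wt_expression_rate` | 3 / 3 | UMIs per cell over a 3' locus of a highly expressed gene |
| `nocall_fraction` | 0.10 | cells with zero locus coverage |
| `read_length` | 90 nt | 3' v3 R2 read scale |
| `n_genes` | 2000 | enough for 24 expression bins |
| `n_chr7_genes`, `monosomy_factor` | 100, 0.5 | one-copy loss across a chromosome-scale gene set |
| `n_signature_genes`, `n_informative` | 200, 50 | signature with a truly coupled core |
| `coupling_strength` | 1.0 | log-mean slope on the latent score: a strongly co-expressed stemness program |
| `n_patients`, `hazard_coefficients`, `censoring_rate` | 300, (ln 3,), 0.3 | detectable planted hazard with realistic censoring |
| `lda_frequency`, `lda_doses` | 1/500, {125, 500, 2000} × 12 mice | doses bracketing 1/f |
| `hto_negative_fraction`, `hto_stray_fraction` | 0.05, 0.01 | rescuable and discardable planted errors; strays are kept below the 2% tail of the 0.98-quantile boundary, otherwise the radius is set by the strays themselves |

`gen_reads` builds a 300-nt wild-type transcript whose core `GATCTCTGGCAG`
spans the locus and a mutant transcript with the TCTG duplicated
(`GATCTCTGTCTGGCAG`); each molecule is a unique (barcode, UMI) with one read
window placed uniformly, so boundary-truncated mutant patterns arise
naturally, and mutant windows are projected through the insertion to
reference coordinates. A mutant read ending exactly at the insertion point is
genuinely indistinguishable from wild type — the generator reproduces that
ambiguity rather than hiding it. `gen_counts` draws gamma-Poisson (negative
binomial) counts with log-normal per-gene base means and dispersions and a
mild log-normal cell size factor; informative signature genes multiply their
mean by exp(coupling × latent). `gen_survival` categorizes its own planted
genes before applying the hazard, matching the estimand of the risk
pipeline; censoring is independent exponential calibrated to the requested
rate. `gen_lda` draws engraftment as Bernoulli(1 − exp(−f·dose)).

**What the generators do not emulate:** ambient RNA, empty droplets,
doublet expression profiles (HTO doublets are placed, not expression-mixed),
splicing, batch effects, sequencing errors in reads, probe-level microarray
structure, or inter-patient heterogeneity in survival baselines. Recovery
results on this synthetic data therefore demonstrate correctness of the
procedures under their own model assumptions, not robustness to artifacts
real data would add.

## Problem sizes used by the test and acceptance suites

Recovery suites run at 2,000 cells × 2,000 genes (monosomy, reduction), 200
null replicates of 500 cells × 200 genes (family-wise false-keep), 100 null
and 30 planted survival cohorts (n = 150 / 300 patients), 200 limiting-
dilution tables, and a 10,000-cell hashtag population — sizes chosen so the
full suite completes in a couple of minutes while keeping every planted
effect in its detectable regime.

## Known limitations

* Exact motif matching has no error tolerance; per-base error rates ~1e-3
  over a 12-mer cost ≈ 1% molecule sensitivity, unmodeled here.
* Cluster-extension fractions use all cells by default; with very low
  coverage the MUT fraction is diluted and rules fire late (the `covered`
  denominator is the mitigation).
* The silhouette bimodality flag cannot detect "no monosomy present" on
  unimodal data (see above); inspect the score histogram.
* The lasso CV minimizes deviance; concordance-based selection can pick
  different penalties on small cohorts.
* `refine_hto` assumes hashtag clusters are compact and roughly isotropic on
  the embedding; elongated clusters leak cells past an axis-aligned box.
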