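"""Stemness-signature scoring, positivity calls, item-test reduction, marker gates.

The miR-126-derived 126High signature is a directional gene list scored per
cell with the expression-bin-matched module score; a cell is signature-positive
when its score is strictly above zero. The item-test reduction keeps the genes
that actually drive the full-signature score: those whose per-gene scaled
expression has a positive, non-negligible (rho > 0.3) and Bonferroni-significant
(adjusted p < 0.05) Spearman correlation with the full-signature score across
cells. Marker-filtering and comparison-eligibility gates for differential
expression are included here because they share the signature workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .modulescore import ModuleScoreParams, ScoreVector, log_normalize, module_score
from .readio import CountMatrix


@dataclass(frozen=True)
class SignatureDefinition:
    """Named, directional gene list (direction: 'up' or 'down')."""

    name: str
    genes: tuple[str, ...]
    direction: str = "up"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


@dataclass
class ReductionResult:
    table: pd.DataFrame  # index gene; columns rho, p, p_adj, kept, reason
    reduced: SignatureDefinition | None
    rho_min: float
    alpha: float

    @property
    def kept_genes(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def score_signature(
    matrix: CountMatrix,
    signature: SignatureDefinition,
    params: ModuleScoreParams = ModuleScoreParams(),
) -> tuple[ScoreVector, np.ndarray, pd.DataFrame]:
    """Module score + per-cell positivity (score > 0) + per-sample % positive."""
    scores = module_score(matrix, list(signature.genes), params)
    positive = scores.scores > 0
    if "sample" in matrix.cell_meta.columns:
        sample = matrix.cell_meta["sample"].to_numpy()
    else:
        sample = np.repeat("all", matrix.n_cells)
    summary = (
        pd.DataFrame({"sample": sample, "positive": positive})
        .groupby("sample", sort=True)["positive"]
        .agg(n_cells="size", pct_positive=lambda s: 100.0 * s.mean())
        .reset_index()
    )
    return scores, positive, summary


def reduce_signature(
    matrix: CountMatrix,
    signature: SignatureDefinition,
    scores: ScoreVector,
    rho_min: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> ReductionResult:
    """Item-test reduction: keep genes with rho > rho_min and Bonferroni p < alpha.

    Each signature gene's per-gene scaled (z-scored log-normalized) expression
    is Spearman-correlated with the full-signature score over all cells;
    p-values use the t-approximation for n > 30 and a seeded permutation test
    below; Bonferroni corrects over the signature's full gene list. Zero-
    variance genes have undefined rho and are dropped with a reason code.
    """
    n = matrix.n_cells
    if n < 10:
        raise ValueError(f"need >= 10 cells for item-test reduction, got {n}")
    if len(scores.scores) != n:
        raise ValueError("score vector length does not match matrix cells")
    X = log_normalize(matrix)
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    n_tests = len(signature.genes)
    score_rank = stats.rankdata(scores.scores)

    rows = []
    rng = np.random.default_rng(seed)
    for gene in signature.genes:
        if gene not in index:
            rows.append((gene, np.nan, np.nan, np.nan, False, "absent"))
            continue
        expr = X[index[gene]]
        if np.ptp(expr) == 0:
            rows.append((gene, np.nan, np.nan, np.nan, False, "zero_variance"))
            continue
        rho = _spearman(stats.rankdata(expr), score_rank)
        p = _spearman_p(rho, n, expr, scores.scores, rng)
        p_adj = min(1.0, p * n_tests)
        # alpha >= 1 disables the significance gate entirely (p_adj caps at 1)
        kept = bool(rho > rho_min and (alpha >= 1.0 or p_adj < alpha))
        rows.append((gene, rho, p, p_adj, kept, ""))

    table = pd.DataFrame(
        rows, columns=["gene", "rho", "p", "p_adj", "kept", "reason"]
    ).set_index("gene")
    kept_genes = tuple(table.index[table["kept"]])
    reduced = (
        SignatureDefinition(f"{signature.name}_reduced", kept_genes, signature.direction)
        if kept_genes
        else None
    )
    return ReductionResult(table, reduced, rho_min, alpha)


def _spearman(rank_a: np.ndarray, rank_b: np.ndarray) -> float:
    """Pearson correlation of (average-tie) ranks."""
    a = rank_a - rank_a.mean()
    b = rank_b - rank_b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom)


def _spearman_p(
    rho: float,
    n: int,
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_resamples: int = 9999,
) -> float:
    if n > 30:
        if abs(rho) >= 1.0:
            return 0.0
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        return float(2 * stats.t.sf(abs(t), df=n - 2))
    # small n: two-sided Monte Carlo permutation test on rho
    rank_y = stats.rankdata(y)
    rank_x = stats.rankdata(x)
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(rank_x)
        if abs(_spearman(perm, rank_y)) >= abs(rho) - 1e-12:
            hits += 1
    return (hits + 1) / (n_resamples + 1)


def filter_markers(
    de_table: pd.DataFrame,
    logfc_min: float = 0.25,
    pct_min: float = 0.25,
    p_max: float = 1e-5,
) -> list[str]:
    """Marker gate: |logFC| >= 0.25, expressed in > 25% of cells in at least
    one compared group, Wilcoxon p < 1e-5.

    ``de_table`` needs columns gene, logFC, pct_in, pct_out, p.
    """
    required = {"gene", "logFC", "pct_in", "pct_out", "p"}
    missing = required - set(de_table.columns)
    if missing:
        raise ValueError(f"de_table missing column(s): {sorted(missing)}")
    if de_table.empty:
        return []
    keep = (
        (de_table["logFC"].abs() >= logfc_min)
        & (de_table[["pct_in", "pct_out"]].max(axis=1) > pct_min)
        & (de_table["p"] < p_max)
    )
    return de_table.loc[keep, "gene"].tolist()


def eligible_comparison(n_group_a: int, n_group_b: int, min_cells: int = 5) -> bool:
    """Intra-cluster comparisons require at least ``min_cells`` in both groups."""
    return n_group_a >= min_cells and n_group_b >= min_cells
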