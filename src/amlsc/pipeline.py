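"""End-to-end orchestration: simulate, genotype, classify, score, reduce, risk.

``run_end_to_end`` exercises every stage on synthetic data with known truth
and reports truth-vs-inferred recovery metrics per stage. Stages communicate
through files under the output directory (each stage reads back what the
previous one wrote), so a library run is equivalent to chaining the CLI
subcommands. A JSON run manifest records the config hash, seed, package and
dependency versions, per-file digests and collected warnings.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import auxstats, genotyping, modulescore, readio, signatures, survival, syndata
from .syndata import SynthConfig


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(config: SynthConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_end_to_end(config: SynthConfig, out_dir: str | Path) -> dict:
    """Run every stage on generated data; return metrics + manifest path.

    Writes per-stage inputs/outputs and ``manifest.json`` under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    metrics: dict[str, dict] = {}

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # --- stage 1: reads -> genotypes -> cluster assignment -------------
        reads, read_truth = syndata.gen_reads(config)
        readio.write_reads_tsv(reads, out / "reads.tsv")
        read_truth.to_csv(out / "reads_truth.tsv", sep="\t")
        reads_in, n_skipped = readio.read_reads(out / "reads.tsv")
        molecules = genotyping.collapse_molecules(reads_in)
        coverage = genotyping.compute_coverage(reads_in)
        for bc in read_truth.index:  # cells with no reads are NoCall
            coverage.setdefault(bc, False)
        genotypes = genotyping.genotype_cells(molecules, coverage)
        gdf = pd.DataFrame(
            [(g.cell_barcode, g.n_mut_umi, g.n_wt_umi, g.call) for g in genotypes],
            columns=["cell", "n_mut_umi", "n_wt_umi", "call"],
        ).set_index("cell")
        gdf.to_csv(out / "genotypes.tsv", sep="\t")
        truth_mut = read_truth["n_mut_molecules"] > 0
        called_mut = gdf["call"].reindex(read_truth.index).eq("MUT")
        n_truth_mut = int(truth_mut.sum())
        metrics["genotyping"] = {
            "n_cells": int(len(read_truth)),
            "n_skipped_reads": n_skipped,
            "n_called_mut": int(called_mut.sum()),
            "mut_recall": float((called_mut & truth_mut).sum() / n_truth_mut)
            if n_truth_mut
            else None,
            "mut_false_calls": int((called_mut & ~truth_mut).sum()),
        }

        # --- stage 2: counts -> chr7 monosomy + signature ------------------
        matrix, count_truth = syndata.gen_counts(config)
        readio.write_mtx(matrix, out / "counts")
        count_truth.to_csv(out / "counts_truth.tsv", sep="\t")
        matrix_in = readio.read_mtx(out / "counts")
        chr7 = syndata.chr7_genes(config)
        score = modulescore.module_score(matrix_in, chr7)
        try:
            mono = modulescore.classify_monosomy(score)
            labels = mono["labels"]
            acc = float(
                np.mean((labels == "AML") == count_truth["is_aml"].to_numpy())
            )
            metrics["chr7_monosomy"] = {
                "accuracy": acc,
                "silhouette": mono["silhouette"],
                "weak_bimodality": mono["weak_bimodality"],
            }
        except ValueError as exc:
            metrics["chr7_monosomy"] = {"error": str(exc)}

        sig = signatures.SignatureDefinition(
            "126High_synthetic", tuple(syndata.signature_genes(config))
        )
        sig_scores, positive, summary = signatures.score_signature(matrix_in, sig)
        summary.to_csv(out / "signature_positivity.tsv", sep="\t", index=False)
        reduction = signatures.reduce_signature(matrix_in, sig, sig_scores)
        reduction.table.to_csv(out / "signature_reduction.tsv", sep="\t")
        kept = set(reduction.kept_genes)
        informative = set(syndata.informative_genes(config))
        null_genes = set(sig.genes) - informative
        metrics["signature"] = {
            "pct_positive": float(100.0 * positive.mean()),
            "n_kept": len(kept),
            "recall": float(len(kept & informative) / len(informative))
            if informative
            else None,
            "false_keep": len(kept & null_genes),
        }

        # --- stage 3: survival risk stratification -------------------------
        expr, surv = syndata.gen_survival(config)
        readio.write_expression(expr, out / "expression.tsv")
        readio.write_survival(surv, out / "survival.tsv")
        expr_in = readio.read_expression(out / "expression.tsv")
        surv_in = readio.read_survival(out / "survival.tsv")
        rng = config.rng("split")
        n = len(expr_in)
        idx = rng.permutation(n)
        train, test = idx[: n // 2], idx[n // 2 :]
        cat = survival.quartile_categorize(expr_in)
        try:
            model = survival.fit_risk_model(
                survival.CategorizedMatrix(cat.values.iloc[train], cat.universe),
                surv_in.iloc[train],
                seed=config.seed,
            )
            model.to_json(out / "risk_model.json")
            if model.degenerate:
                metrics["survival"] = {"degenerate": True}
            else:
                groups = survival.apply_risk_model(model, cat.values.iloc[test])
                ev = survival.evaluate_groups(groups, surv_in.iloc[test])
                metrics["survival"] = {
                    "degenerate": False,
                    "test_logrank_p": ev.logrank_p,
                    "test_hazard_ratio": ev.hazard_ratio,
                    "n_test_events": ev.n_events,
                }
        except ValueError as exc:
            metrics["survival"] = {"error": str(exc)}

        # --- stage 4: hashtag refinement ------------------------------------
        embedding, labels0, hto_truth = syndata.gen_hto(config)
        pd.DataFrame(embedding, columns=["x", "y"]).assign(label=labels0).to_csv(
            out / "hto.tsv", sep="\t", index=False
        )
        state = auxstats.HTOState(embedding, labels0)
        refined, _ = auxstats.refine_hto(state)
        rescuable = hto_truth["planted"] == "mislabeled_negative"
        stray = hto_truth["planted"] == "stray"
        metrics["hto"] = {
            "rescued_fraction": float(
                (refined.provenance[rescuable.to_numpy()] == "rescued").mean()
            )
            if rescuable.any()
            else None,
            "stray_discarded_fraction": float(
                (refined.provenance[stray.to_numpy()] == "discarded").mean()
            )
            if stray.any()
            else None,
        }

        # --- stage 5: limiting dilution -------------------------------------
        lda_table = syndata.gen_lda(config)
        lda_table.to_csv(out / "lda.tsv", sep="\t", index=False)
        fit = auxstats.estimate_frequency(auxstats.LDAExperiment(lda_table))
        metrics["lda"] = {
            "frequency": fit.frequency,
            "ci": list(fit.ci),
            "true_frequency": config.lda_frequency,
            "ci_covers_truth": bool(fit.ci[0] <= config.lda_frequency <= fit.ci[1]),
            "status": fit.status,
        }

        caught = [str(w.message) for w in wlist]

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "files": {
            p.name: _digest(p) for p in sorted(out.iterdir()) if p.is_file()
        },
        "warnings": caught,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    metrics["manifest"] = str(out / "manifest.json")
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=str))
    return metrics
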