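"""End-to-end pipeline: disease transcriptome -> normalization scoring ->
gene-set scoring -> enrichment, plus the serum PD analysis.

`run_pipeline` reads validated inputs, executes every stage whose inputs are
present, writes each stage's outputs as headered CSV/TSV into the run
directory together with a provenance record (config JSON + SHA-256 hash),
and returns a summary dictionary (also written as ``summary.json``).
Outputs are deterministic for a fixed config; a failed run removes the
partially written run directory if this invocation created it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import io as pio
from .config import PipelineConfig
from .de import (PairedDifferentialExpression, filter_expressed, normalize_counts)
from .enrichment import ora, term_gene_network
from .genesets import read_gmt
from .gsva import compare_group_scores, gsva_scores
from .scoring import (differential_normalization, fraction_normalized,
                      percent_improvement, transcriptome_heatmap_matrix)
from .serum import HCReference, SerumPDModel, comparison_table

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _provenance(config: PipelineConfig, run_dir: Path) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True)
    digest = hashlib.sha256(blob.encode()).hexdigest()
    (run_dir / "config.json").write_text(blob)
    (run_dir / "provenance.json").write_text(
        json.dumps({"config_sha256": digest, "seed": config.seed}, indent=2)
    )
    return digest


def run_pipeline(config: PipelineConfig) -> dict:
    run_dir = Path(config.out_dir)
    created = not run_dir.exists()
    run_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, run_dir)
    except Exception:
        if created:
            shutil.rmtree(run_dir, ignore_errors=True)
        raise


def _run(config: PipelineConfig, run_dir: Path) -> dict:
    _provenance(config, run_dir)
    summary: dict = {"seed": config.seed}

    collection = read_gmt(config.gmt) if config.gmt else None

    if config.counts and config.meta:
        counts = pio.read_counts_tsv(config.counts)
        meta = pio.read_meta(config.meta)
        if set(meta["sample_id"]) != set(counts.columns):
            raise ValueError("metadata sample ids do not match count matrix columns")
        expressed = filter_expressed(counts)
        expr = normalize_counts(counts.loc[expressed], pseudocount=config.pseudocount)
        logger.info("de: %d/%d genes pass expression filter", len(expressed), len(counts))

        de_res = PairedDifferentialExpression(expr, meta, week=config.baseline_week).fit()
        de_res.table.to_csv(run_dir / "de_results.csv", index=False)
        transcriptome = de_res.disease_transcriptome(config.fc, config.de_fdr)
        transcriptome.to_frame().to_csv(run_dir / "disease_transcriptome.tsv",
                                        sep="\t", index=False)
        summary["disease_transcriptome"] = {
            "n_total": len(transcriptome),
            "n_up": transcriptome.n_up,
            "n_down": transcriptome.n_down,
            "fc_threshold": config.fc,
            "fdr_threshold": config.de_fdr,
        }
        if len(transcriptome) == 0:
            raise ValueError("empty disease transcriptome; nothing to score")

        matrix, ordering = transcriptome_heatmap_matrix(expr, meta, transcriptome,
                                                        baseline_week=config.baseline_week)
        matrix.to_csv(run_dir / "heatmap_matrix.tsv", sep="\t")
        (run_dir / "heatmap_ordering.json").write_text(json.dumps(ordering, indent=2))

        arms = sorted(meta["arm"].unique())
        weeks = sorted(w for w in meta.loc[meta["tissue"] == "lesional", "week"].unique()
                       if w != config.baseline_week)
        impr_frames, summaries = [], []
        by_arm_week: Dict[tuple, pd.DataFrame] = {}
        for arm in arms:
            for week in weeks:
                impr = percent_improvement(expr, meta, transcriptome, arm, week,
                                           baseline_week=config.baseline_week)
                by_arm_week[(arm, week)] = impr
                impr_frames.append(impr)
                summaries.append(fraction_normalized(impr, config.norm_threshold))
        pd.concat(impr_frames).to_csv(run_dir / "improvement.csv", index=False)
        norm_summary = pd.DataFrame(summaries)
        norm_summary.to_csv(run_dir / "normalization_summary.csv", index=False)
        summary["pct_normalized"] = {
            f"{r['arm']}_week{int(r['week'])}": r["pct_normalized"]
            for _, r in norm_summary.iterrows()
        }

        diff_rows = []
        summary["differential_normalization"] = {}
        if len(arms) == 2:
            for week in weeks:
                res = differential_normalization(
                    by_arm_week[(arms[0], week)], by_arm_week[(arms[1], week)],
                    config.improvement_min, config.difference_min,
                )
                for g in res.set_A:
                    diff_rows.append((week, g, res.arm_A))
                for g in res.set_B:
                    diff_rows.append((week, g, res.arm_B))
                summary["differential_normalization"][f"week{week}"] = {
                    res.arm_A: len(res.set_A), res.arm_B: len(res.set_B),
                }
                if collection is not None:
                    universe = list(expr.genes)
                    for arm_label, genes in ((res.arm_A, res.set_A), (res.arm_B, res.set_B)):
                        table = ora(genes, universe, collection, config.de_fdr)
                        table.to_csv(run_dir / f"ora_week{week}_{arm_label}.csv", index=False)
                        if len(table):
                            net = term_gene_network(table, top_n=min(10, len(table)))
                            net.to_csv(run_dir / f"network_week{week}_{arm_label}.tsv",
                                       sep="\t", index=False)
        pd.DataFrame(diff_rows, columns=["week", "gene", "better_arm"]).to_csv(
            run_dir / "differential_normalization.tsv", sep="\t", index=False)

        if collection is not None:
            scores = gsva_scores(expr, collection)
            scores.scores.to_csv(run_dir / "gsva_scores.tsv", sep="\t")
            groups = {
                f"{t[:1].upper()}{t[1:2]}_{a}_w{w}": grp["sample_id"].tolist()
                for (t, a, w), grp in meta.groupby(["tissue", "arm", "week"])
                if len(grp) >= 2
            }
            if len(groups) >= 2:
                kw = compare_group_scores(scores, groups)
                kw.to_csv(run_dir / "gsva_group_tests.csv", index=False)
                summary["gsva_sets"] = list(scores.scores.index)

    if config.serum and config.hc:
        serum = pio.read_serum(config.serum)
        hc = HCReference.from_table(pio.read_hc(config.hc))
        comp = comparison_table(serum, hc)
        comp.to_csv(run_dir / "serum_vs_hc.csv", index=False)
        pd_res = SerumPDModel(serum, baseline_week=config.baseline_week).fit()
        pd_res.effects.to_csv(run_dir / "serum_pd_effects.csv", index=False)
        pd_res.contrasts.to_csv(run_dir / "serum_pd_contrasts.csv", index=False)
        flags = pd_res.flag_proteins(config.olink_fc, config.olink_fdr)
        (run_dir / "pd_flags.json").write_text(json.dumps(flags, indent=2, sort_keys=True))
        summary["pd_flags"] = {k: len(v) for k, v in flags.items()}

    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
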