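"""Percent-improvement ("normalization") scoring of disease transcripts.

For a disease-associated gene the baseline lesional/nonlesional gap defines
100% of the possible improvement; at a later week the group-mean lesional
level is scored as

    improvement_pct = 100 * (L0 - Lt) / (L0 - NL0)

on the log2 scale, where L0/Lt are the arm's mean lesional expression at
baseline/week t and NL0 its mean nonlesional baseline expression. 0 means no
change, 100 means the lesional mean reached the nonlesional baseline;
values below 0 (worsening) or above 100 (overshoot) are kept unclipped.
The same formula handles up- and downregulated genes because numerator and
denominator flip sign together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import DiseaseTranscriptome, _expr_frame

__all__ = [
    "percent_improvement",
    "fraction_normalized",
    "differential_normalization",
    "DifferentialNormalizationResult",
    "transcriptome_heatmap_matrix",
]


def _gene_list(transcriptome) -> List[str]:
    if isinstance(transcriptome, DiseaseTranscriptome):
        return list(transcriptome.genes)
    return list(transcriptome)


def _check_gap(denom, genes) -> None:
    if (np.asarray(denom) == 0).any():
        bad = list(np.asarray(genes)[np.asarray(denom == 0)])
        raise ValueError(f"zero lesional/nonlesional baseline gap for genes {bad[:5]}")


def _mean_profile(frame: pd.DataFrame, meta: pd.DataFrame, genes, arm, week, tissue,
                  pooled_arms: bool = False) -> pd.Series:
    sel = meta[(meta["week"] == week) & (meta["tissue"] == tissue)]
    if not pooled_arms:
        sel = sel[sel["arm"] == arm]
    if len(sel) == 0:
        raise ValueError(f"no {tissue} samples for arm={arm}, week={week}")
    return frame.loc[genes, sel["sample_id"].tolist()].mean(axis=1)


def percent_improvement(
    expr,
    meta: pd.DataFrame,
    transcriptome,
    arm: str,
    week: int,
    baseline_week: int = 0,
    pooled_nl: bool = False,
    per_patient: bool = False,
) -> pd.DataFrame:
    """Per-gene percent improvement toward nonlesional baseline.

    Returns a DataFrame with columns ``gene, arm, week, mean_L0, mean_Lt,
    mean_NL0, improvement_pct``. ``pooled_nl`` uses the across-arm
    nonlesional baseline mean as the reference; ``per_patient`` averages
    per-subject improvement instead of using group means (only subjects
    biopsied at both weeks contribute).
    """
    frame = _expr_frame(expr)
    genes = _gene_list(transcriptome)
    if len(genes) == 0:
        raise ValueError("transcriptome is empty")
    missing = [g for g in genes if g not in frame.index]
    if missing:
        raise ValueError(f"transcripts absent from expression matrix: {missing[:5]}")

    nl0 = _mean_profile(frame, meta, genes, arm, baseline_week, "nonlesional",
                        pooled_arms=pooled_nl)
    if per_patient:
        les = meta[(meta["tissue"] == "lesional") & (meta["arm"] == arm)]
        base = les[les["week"] == baseline_week].set_index("subject_id")["sample_id"]
        at_t = les[les["week"] == week].set_index("subject_id")["sample_id"]
        common = base.index.intersection(at_t.index)
        if len(common) == 0:
            raise ValueError(f"no subjects with lesional biopsies at weeks "
                             f"{baseline_week} and {week} in arm {arm}")
        l0 = frame.loc[genes, base.loc[common].tolist()]
        lt = frame.loc[genes, at_t.loc[common].tolist()]
        denom = l0.mean(axis=1) - nl0
        _check_gap(denom, genes)
        impr = 100.0 * (l0.to_numpy() - lt.to_numpy()).mean(axis=1) / denom.to_numpy()
        l0_mean, lt_mean = l0.mean(axis=1), lt.mean(axis=1)
    else:
        l0_mean = _mean_profile(frame, meta, genes, arm, baseline_week, "lesional")
        lt_mean = _mean_profile(frame, meta, genes, arm, week, "lesional")
        denom = l0_mean - nl0
        _check_gap(denom, genes)
        impr = 100.0 * (l0_mean - lt_mean) / denom
    return pd.DataFrame(
        {
            "gene": genes,
            "arm": arm,
            "week": week,
            "mean_L0": np.asarray(l0_mean, float),
            "mean_Lt": np.asarray(lt_mean, float),
            "mean_NL0": np.asarray(nl0, float),
            "improvement_pct": np.asarray(impr, float),
        }
    )


def fraction_normalized(impr: pd.DataFrame, threshold_pct: float = 75.0) -> pd.Series:
    """Summarize an ImprovementTable: share of transcripts with improvement
    strictly above ``threshold_pct``."""
    if len(impr) == 0:
        raise ValueError("empty improvement table")
    arm = impr["arm"].iloc[0]
    week = int(impr["week"].iloc[0])
    n_total = len(impr)
    n_norm = int((impr["improvement_pct"] > threshold_pct).sum())
    return pd.Series(
        {
            "arm": arm,
            "week": week,
            "threshold_pct": float(threshold_pct),
            "n_normalized": n_norm,
            "n_total": n_total,
            "pct_normalized": 100.0 * n_norm / n_total,
        }
    )


@dataclass
class DifferentialNormalizationResult:
    """Transcripts better normalized by one arm than the other."""

    week: int
    set_A: List[str]
    set_B: List[str]
    arm_A: str
    arm_B: str
    improvement_min: float
    difference_min: float


def differential_normalization(
    impr_a: pd.DataFrame,
    impr_b: pd.DataFrame,
    improvement_min: float = 50.0,
    difference_min: float = 25.0,
) -> DifferentialNormalizationResult:
    """Genes better normalized by one arm: improvement > ``improvement_min``
    and margin over the other arm > ``difference_min`` (strict inequalities).
    The two sets are disjoint by construction."""
    a = impr_a.set_index("gene")["improvement_pct"]
    b = impr_b.set_index("gene")["improvement_pct"]
    if set(a.index) != set(b.index):
        raise ValueError("improvement tables cover different gene universes")
    b = b.loc[a.index]
    in_a = (a > improvement_min) & ((a - b) > difference_min)
    in_b = (b > improvement_min) & ((b - a) > difference_min)
    return DifferentialNormalizationResult(
        week=int(impr_a["week"].iloc[0]),
        set_A=sorted(a.index[in_a]),
        set_B=sorted(a.index[in_b]),
        arm_A=str(impr_a["arm"].iloc[0]),
        arm_B=str(impr_b["arm"].iloc[0]),
        improvement_min=improvement_min,
        difference_min=difference_min,
    )


def _leaf_order(block: np.ndarray, ids: List[str]) -> List[str]:
    """Average-linkage, correlation-distance leaf ordering of gene profiles."""
    if len(ids) <= 2:
        return list(ids)
    x = block - block.mean(axis=1, keepdims=True)
    norms = np.sqrt((x**2).sum(axis=1))
    norms[norms == 0] = 1.0
    xn = x / norms[:, np.newaxis]
    corr = np.clip(xn @ xn.T, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.average(squareform(dist, checks=False))
    leaves = hierarchy.leaves_list(link)
    return [ids[i] for i in leaves]


def transcriptome_heatmap_matrix(
    expr,
    meta: pd.DataFrame,
    transcriptome: DiseaseTranscriptome,
    baseline_week: int = 0,
) -> Tuple[pd.DataFrame, dict]:
    """Ordered expression matrix behind the disease-transcriptome heatmap.

    Rows: upregulated genes first, then downregulated, each block ordered by
    hierarchical clustering (average linkage, correlation distance) of
    baseline lesional profiles. Columns grouped by (tissue, arm, week).
    Returns ``(matrix, ordering)`` where ``ordering`` records the row and
    column orders and block boundaries.
    """
    frame = _expr_frame(expr)
    base_les = meta[(meta["tissue"] == "lesional") & (meta["week"] == baseline_week)]
    ref = frame.loc[transcriptome.genes, base_les["sample_id"].tolist()].to_numpy()
    gene_pos = {g: i for i, g in enumerate(transcriptome.genes)}
    ordered_genes: List[str] = []
    for group in (transcriptome.up_genes(), transcriptome.down_genes()):
        block = ref[[gene_pos[g] for g in group], :]
        ordered_genes.extend(_leaf_order(block, group))
    tissue_rank = {"nonlesional": 0, "lesional": 1}
    cols = meta.assign(_t=meta["tissue"].map(tissue_rank)).sort_values(
        ["_t", "arm", "week", "sample_id"], kind="stable"
    )["sample_id"].tolist()
    matrix = frame.loc[ordered_genes, cols]
    ordering = {
        "genes": ordered_genes,
        "samples": cols,
        "n_up": transcriptome.n_up,
        "n_down": transcriptome.n_down,
    }
    return matrix, ordering
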