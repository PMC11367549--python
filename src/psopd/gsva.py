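"""Single-sample gene-set variation scores (GSVA-style).

Per gene, a Gaussian-kernel cumulative density across samples turns raw
log2 expression into a relative expression statistic; per sample, genes are
ranked by that statistic and a symmetric rank weight |p/2 - rank| is formed.
A weighted Kolmogorov-Smirnov-like random walk down the ranked list then
scores each gene set: steps up by the tau-powered rank weight inside the
set, down by a constant outside it. Under the ``max_diff`` convention the
score is the maximum positive deviation plus the minimum negative deviation
of the walk, which lies in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection
from .stats import kruskal_wallis, significance_stars

__all__ = ["ScoreMatrix", "gsva_scores", "compare_group_scores"]


@dataclass
class ScoreMatrix:
    """Gene sets x samples enrichment scores plus the parameters used."""

    scores: pd.DataFrame
    tau: float
    mode: str
    kcdf: str = "Gaussian"

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("scores must be finite")


def _kernel_cdf(x: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF of each entry within its gene (row), bandwidth
    sd/4; constant genes fall back to a vanishing bandwidth (rank CDF)."""
    from scipy.stats import norm

    n = x.shape[1]
    sd = x.std(axis=1, ddof=1)
    h = sd / 4.0
    z = np.empty_like(x, dtype=float)
    for i in range(x.shape[0]):
        if h[i] > 0:
            z[i] = norm.cdf((x[i][:, None] - x[i][None, :]) / h[i]).mean(axis=1)
        else:
            z[i] = np.full(n, 0.5)
    return z


def gsva_scores(
    expr,
    sets: GeneSetCollection,
    tau: float = 1.0,
    mode: str = "max_diff",
) -> ScoreMatrix:
    """Compute per-set, per-sample variation scores.

    ``expr`` is a genes x samples log2 expression DataFrame (or
    ``ExpressionMatrix``). Sets are intersected with the expression
    universe; sets with fewer than 2 genes after intersection are dropped
    with a warning. Needs >= 3 samples for the kernel density to be
    meaningful. ``mode`` is ``max_diff`` (default) or ``max_abs`` (largest
    absolute deviation, signed).
    """
    import logging

    from .de import _expr_frame

    logger = logging.getLogger(__name__)
    frame = _expr_frame(expr)
    if frame.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if mode not in ("max_diff", "max_abs"):
        raise ValueError(f"unknown mode {mode!r}")
    genes = list(frame.index)
    restricted = sets.restrict(genes, min_size=2)
    dropped = set(sets.names()) - set(restricted.names())
    for name in sorted(dropped):
        logger.warning("gene set %s has < 2 genes in the universe; dropped", name)
    if len(restricted) == 0:
        raise ValueError("no gene sets left after intersecting with the universe")

    x = frame.to_numpy(dtype=float)
    p, n = x.shape
    z = _kernel_cdf(x)

    # per-sample ranking, largest statistic first; ties broken by gene order
    order = np.empty((p, n), dtype=int)
    ranks = np.empty((p, n), dtype=float)
    for j in range(n):
        idx = np.lexsort((np.arange(p), -z[:, j]))
        order[:, j] = idx
        ranks[idx, j] = np.arange(1, p + 1)
    weight = np.abs(p / 2.0 - ranks) ** tau  # symmetric rank statistic

    gene_pos = {g: i for i, g in enumerate(genes)}
    out = np.zeros((len(restricted), n))
    for k, (name, members) in enumerate(restricted):
        member_mask = np.zeros(p, dtype=bool)
        member_mask[[gene_pos[g] for g in members]] = True
        m = member_mask.sum()
        dec = 1.0 / (p - m)
        for j in range(n):
            in_set = member_mask[order[:, j]]
            w = weight[order[:, j], j]
            steps = np.where(in_set, w, 0.0)
            denom = steps.sum()
            walk = np.cumsum(np.where(in_set, steps / denom, -dec))
            pos = max(walk.max(), 0.0)
            neg = min(walk.min(), 0.0)
            if mode == "max_diff":
                out[k, j] = pos + neg
            else:
                out[k, j] = pos if pos > -neg else neg
    scores = pd.DataFrame(out, index=restricted.names(), columns=frame.columns)
    return ScoreMatrix(scores, tau=tau, mode=mode)


def compare_group_scores(
    scores: ScoreMatrix, groups: Dict[str, Sequence[str]]
) -> pd.DataFrame:
    """Kruskal-Wallis comparison of each set's scores across sample groups.

    ``groups`` maps group label -> sample ids. Returns per-set H, p, and the
    conventional star annotation (``***`` p<.001, ``**`` p<.01, ``*`` p<.05,
    ``ns`` otherwise).
    """
    frame = scores.scores
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        missing = [s for s in groups[lab] if s not in frame.columns]
        if missing:
            raise ValueError(f"group {lab!r} references unknown samples: {missing[:5]}")
        if len(groups[lab]) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    rows = []
    for name in frame.index:
        vals = [frame.loc[name, list(groups[lab])].to_numpy(float) for lab in labels]
        h, pval = kruskal_wallis(vals)
        rows.append((name, h, pval, significance_stars(pval)))
    return pd.DataFrame(rows, columns=["set", "H", "p", "stars"])
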