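"""Disease-transcriptome definition from paired lesional/nonlesional skin.

Counts are converted to log2 counts-per-million with a pseudocount, and the
lesional-vs-nonlesional comparison at baseline is tested with an
empirical-Bayes moderated paired t-statistic: per-gene sample variances of
the paired log2 differences are shrunk toward a mean-variance trend
(lowess-smoothed), with the prior degrees of freedom estimated by the method
of moments on the log sample variances. Because the test operates on paired
log2 differences, the per-gene effect is exactly the log2 of the geometric
mean fold change, so the disease transcriptome is the set of genes with
|log2 GM fold change| > log2(fc) at BH FDR < alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .longitudinal import fit_ratio_model
from .serum import PDEffectResults
from .stats import adjust_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "normalize_counts",
    "filter_expressed",
    "PairedDifferentialExpression",
    "DEResults",
    "DiseaseTranscriptome",
    "paired_de",
    "define_disease_transcriptome",
    "pd_transcript_model",
]


@dataclass
class ExpressionMatrix:
    """log2(CPM + pseudocount-adjusted) gene x sample matrix."""

    log2cpm: pd.DataFrame
    lib_sizes: pd.Series
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2cpm.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def genes(self) -> pd.Index:
        return self.log2cpm.index

    @property
    def samples(self) -> pd.Index:
        return self.log2cpm.columns


def _expr_frame(expr) -> pd.DataFrame:
    return expr.log2cpm if isinstance(expr, ExpressionMatrix) else expr


def normalize_counts(counts: pd.DataFrame, pseudocount: float = 0.5) -> ExpressionMatrix:
    """log2 CPM: ``log2((count + pc) / (libsize + 2 pc) * 1e6)``.

    The pseudocount keeps zero counts finite; the matching library-size
    offset keeps the transform exact for the implied two-cell composition.
    """
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    lib = arr.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero library size in samples: {bad}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    log2cpm = np.log2((arr + pseudocount) / (lib + 2 * pseudocount)[np.newaxis, :] * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(log2cpm, index=counts.index, columns=counts.columns),
        pd.Series(lib, index=counts.columns, name="lib_size"),
        pseudocount,
    )


def filter_expressed(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_frac: float = 0.25
) -> pd.Index:
    """Genes with CPM >= ``min_cpm`` in at least ``min_frac`` of samples."""
    lib = counts.to_numpy().sum(axis=0).astype(float)
    cpm = counts.to_numpy() / lib[np.newaxis, :] * 1e6
    keep = (cpm >= min_cpm).mean(axis=1) >= min_frac
    return counts.index[keep]


# ---------------------------------------------------------------------------
# Moderated paired t
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations, as in the
    classic empirical-Bayes variance-moderation scheme)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(
    s2: np.ndarray, df: float, amean: np.ndarray, frac: float = 0.4
) -> Tuple[np.ndarray, float]:
    """Estimate (per-gene prior variance, prior df) from sample variances.

    Fits a lowess trend of the (bias-corrected) log variances against mean
    expression; residual spread in excess of the chi-square sampling noise
    determines the prior degrees of freedom by method of moments.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    ok = s2 > 0
    if ok.sum() < 10:
        # too few informative genes for a trend; flat prior at the median
        s0 = float(np.median(s2[ok])) if ok.any() else 1e-8
        return np.full_like(s2, s0), math.inf
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    order = np.argsort(amean[ok], kind="stable")
    fitted = np.empty_like(e)
    sm = lowess(e[order], amean[ok][order], frac=frac, return_sorted=False)
    fitted[order] = sm
    resid = e - fitted
    n = resid.size
    evar = float(np.var(resid, ddof=1)) * (n - 1) / n - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        offset = special.digamma(df_prior / 2.0) - math.log(df_prior / 2.0)
    else:
        df_prior = math.inf
        offset = 0.0
    # extrapolate the trend to genes excluded from the fit (s2 == 0)
    trend_all = np.empty_like(s2, dtype=float)
    trend_all[ok] = fitted
    if (~ok).any():
        # nearest-by-abundance fill
        idx_ok = np.flatnonzero(ok)
        for i in np.flatnonzero(~ok):
            j = idx_ok[np.argmin(np.abs(amean[idx_ok] - amean[i]))]
            trend_all[i] = trend_all[j]
    s0 = np.exp(trend_all + offset)
    return s0, float(df_prior)


@dataclass
class DEResults:
    """Moderated paired differential-expression results.

    ``table`` columns: gene, mean_diff (log2 lesional - nonlesional, which
    for a paired design is the log2 geometric-mean fold change), t, p, fdr,
    direction.
    """

    table: pd.DataFrame
    n_pairs: int
    prior_df: float
    residual_df: float

    def disease_transcriptome(
        self, fc_threshold: float = 2.0, fdr_threshold: float = 0.05
    ) -> "DiseaseTranscriptome":
        return define_disease_transcriptome(self, fc_threshold, fdr_threshold)

    def summary(self) -> str:
        t = self.table
        n_sig = int((t["fdr"] < 0.05).sum())
        return (
            f"Paired moderated DE: {len(t)} genes, {self.n_pairs} pairs, "
            f"prior df {self.prior_df:.3g}, residual df {self.residual_df:.0f}; "
            f"{n_sig} genes at FDR < 0.05"
        )


@dataclass
class DiseaseTranscriptome:
    """The disease-associated transcript set with directions.

    Members satisfy |mean paired log2 difference| > log2(fc_threshold) and
    BH FDR < fdr_threshold; ordered by (fdr, p, gene id) for determinism.
    """

    genes: List[str]
    direction: Dict[str, str]  # gene -> "up" | "down"
    fc_threshold: float
    fdr_threshold: float

    @property
    def n_up(self) -> int:
        return sum(1 for g in self.genes if self.direction[g] == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for g in self.genes if self.direction[g] == "down")

    def __len__(self) -> int:
        return len(self.genes)

    def up_genes(self) -> List[str]:
        return [g for g in self.genes if self.direction[g] == "up"]

    def down_genes(self) -> List[str]:
        return [g for g in self.genes if self.direction[g] == "down"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "direction": [self.direction[g] for g in self.genes]}
        )


class PairedDifferentialExpression:
    """Paired lesional-vs-nonlesional model at one visit week.

    Subjects lacking either tissue at the week are excluded (logged).
    ``fit(prior_df=...)`` overrides the estimated prior degrees of freedom:
    0 disables shrinkage (classical paired t), ``inf`` uses the trend
    variance alone.
    """

    def __init__(self, expr, meta: pd.DataFrame, week: int = 0) -> None:
        frame = _expr_frame(expr)
        meta = meta.copy()
        if list(meta["sample_id"]) != list(frame.columns):
            meta = meta.set_index("sample_id").loc[frame.columns].reset_index()
        at_week = meta[meta["week"] == week]
        pairs: List[Tuple[str, str, str]] = []
        for subj, grp in at_week.groupby("subject_id"):
            les = grp[grp["tissue"] == "lesional"]["sample_id"]
            non = grp[grp["tissue"] == "nonlesional"]["sample_id"]
            if len(les) == 1 and len(non) == 1:
                pairs.append((str(subj), les.iloc[0], non.iloc[0]))
            else:
                logger.warning("subject %s unpaired at week %s; excluded", subj, week)
        if len(pairs) < 3:
            raise ValueError(f"need >= 3 complete pairs at week {week}, found {len(pairs)}")
        self.expr = frame
        self.week = week
        self.pairs = sorted(pairs)

    def fit(self, prior_df: Optional[float] = None, trend_frac: float = 0.4) -> DEResults:
        les = self.expr[[p[1] for p in self.pairs]].to_numpy()
        non = self.expr[[p[2] for p in self.pairs]].to_numpy()
        diffs = les - non
        n = diffs.shape[1]
        mean_diff = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        df_resid = float(n - 1)
        amean = (les + non).mean(axis=1) / 2.0

        if prior_df is None or (np.isfinite(prior_df) and prior_df > 0):
            s0, d0_est = _fit_variance_prior(s2, df_resid, amean, frac=trend_frac)
            d0 = d0_est if prior_df is None else float(prior_df)
        elif prior_df == 0:
            s0, d0 = np.zeros_like(s2), 0.0
        else:  # prior_df == inf
            s0, _ = _fit_variance_prior(s2, df_resid, amean, frac=trend_frac)
            d0 = math.inf
        if math.isinf(d0):
            s2_post = s0
            df_total = np.inf
        else:
            s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid

        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_diff / np.sqrt(s2_post / n)
        zero_var = s2_post == 0
        t = np.where(zero_var & (mean_diff == 0), 0.0, t)
        if np.isinf(df_total):
            p = 2.0 * sps.norm.sf(np.abs(t))
        else:
            p = 2.0 * sps.t.sf(np.abs(t), df_total)
        p = np.where(zero_var & (mean_diff == 0), 1.0, p)
        p = np.where(zero_var & (mean_diff != 0), 0.0, p)
        # all-zero genes carry no evidence
        allzero = (les == les[:, :1]).all(axis=1) & (non == non[:, :1]).all(axis=1) & (s2 == 0) & (mean_diff == 0)
        p = np.where(allzero, 1.0, p)

        table = pd.DataFrame(
            {
                "gene": self.expr.index,
                "mean_diff": mean_diff,
                "t": t,
                "p": p,
                "direction": np.where(mean_diff >= 0, "up", "down"),
            }
        )
        table["fdr"] = adjust_fdr(table["p"].to_numpy())
        return DEResults(table=table, n_pairs=n, prior_df=float(d0), residual_df=df_resid)


def paired_de(expr, meta: pd.DataFrame, week: int = 0,
              prior_df: Optional[float] = None) -> DEResults:
    """Functional wrapper around :class:`PairedDifferentialExpression`."""
    return PairedDifferentialExpression(expr, meta, week=week).fit(prior_df=prior_df)


def define_disease_transcriptome(
    de: DEResults, fc_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> DiseaseTranscriptome:
    """Select genes with |log2 GM fold change| > log2(fc) and FDR < alpha."""
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    cut = math.log2(fc_threshold)
    t = de.table
    members = t[(t["mean_diff"].abs() > cut) & (t["fdr"] < fdr_threshold)]
    members = members.sort_values(["fdr", "p", "gene"], kind="stable")
    return DiseaseTranscriptome(
        genes=list(members["gene"]),
        direction=dict(zip(members["gene"], members["direction"])),
        fc_threshold=fc_threshold,
        fdr_threshold=fdr_threshold,
    )


def pd_transcript_model(
    expr,
    meta: pd.DataFrame,
    transcript_set: Sequence[str],
    baseline_week: int = 0,
) -> PDEffectResults:
    """Longitudinal PD effects on lesional transcripts.

    Response: each subject's lesional log2 ratio to their baseline lesional
    value; covariate: the subject's baseline lesional-minus-nonlesional
    difference; fixed week x arm cell means; subject random intercept.
    Returns per-gene per-week within-arm effects and between-arm contrasts
    (the ``analyte`` column carries the gene id).
    """
    frame = _expr_frame(expr)
    missing = [g for g in transcript_set if g not in frame.index]
    if missing:
        raise ValueError(f"transcripts not in expression matrix: {missing[:5]}...")
    les = meta[meta["tissue"] == "lesional"]
    non0 = meta[(meta["tissue"] == "nonlesional") & (meta["week"] == baseline_week)]
    nl_sample = dict(zip(non0["subject_id"], non0["sample_id"]))
    base_sample = dict(
        zip(les[les["week"] == baseline_week]["subject_id"],
            les[les["week"] == baseline_week]["sample_id"])
    )
    eff_rows, con_rows = [], []
    for gene in transcript_set:
        x = frame.loc[gene]
        records = []
        for _, r in les[les["week"] != baseline_week].iterrows():
            subj = r["subject_id"]
            if subj not in base_sample or subj not in nl_sample:
                continue
            base_l = x[base_sample[subj]]
            records.append(
                (subj, r["arm"], int(r["week"]),
                 x[r["sample_id"]] - base_l,
                 base_l - x[nl_sample[subj]])
            )
        df = pd.DataFrame(records, columns=["subject_id", "arm", "week", "ratio", "baseline"])
        fit = fit_ratio_model(df)
        for _, r in fit.cell_effects.iterrows():
            eff_rows.append((gene, r["arm"], int(r["week"]), r["estimate"], r["se"], r["df"], r["p"]))
        for _, r in fit.contrasts.iterrows():
            con_rows.append((gene, r["contrast"], int(r["week"]), r["estimate"], r["se"], r["df"], r["p"]))
    cols = ["estimate", "se", "df", "p"]
    effects = pd.DataFrame(eff_rows, columns=["analyte", "arm", "week", *cols])
    contrasts = pd.DataFrame(con_rows, columns=["analyte", "contrast", "week", *cols])
    if len(effects):
        effects["fdr"] = effects.groupby(["arm", "week"])["p"].transform(adjust_fdr)
    if len(contrasts):
        contrasts["fdr"] = contrasts.groupby("week")["p"].transform(adjust_fdr)
    return PDEffectResults(effects, contrasts, baseline_week=baseline_week)
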