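"""Serum analyte pharmacodynamics.

Three layers of analysis, all on the log2(pg/ml) scale (or directly on NPX
values, which are already log2):

1. group summaries per (arm, week, analyte) and Welch comparisons against a
   separately procured healthy-control reference, reporting the log2 ratio
   of group mean to healthy-control mean;
2. per-analyte longitudinal mixed models on log2 ratios to baseline (week,
   arm, week x arm fixed effects; baseline value as covariate; subject
   random intercept), with per-week within-arm effects, between-arm
   contrasts, and Benjamini-Hochberg adjustment across analytes;
3. Pearson correlation of analyte levels with PASI severity scores.

Proteins are flagged as showing a pharmacodynamic effect in an arm when the
estimated reduction exceeds a fold-change threshold (default 1.25-fold,
i.e. |log2 ratio| > log2 1.25 with negative sign) at FDR < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .longitudinal import fit_ratio_model
from .stats import adjust_fdr, welch_from_stats

__all__ = [
    "MissingCellError",
    "HCReference",
    "ComparisonRecord",
    "validate_serum_table",
    "log2_summarize",
    "compare_to_healthy",
    "comparison_table",
    "SerumPDModel",
    "PDEffectResults",
    "pd_effect_model",
    "responder_contrast",
    "responders_from_pasi",
    "correlate_with_pasi",
]


class MissingCellError(KeyError):
    """Raised when a requested (arm, week, analyte) cell has no data."""


def validate_serum_table(serum: pd.DataFrame, npx: bool = False) -> pd.DataFrame:
    """Check the long-format serum table schema and invariants."""
    value_col = "npx" if npx else "conc_pg_ml"
    required = {"subject_id", "arm", "week", "analyte", value_col}
    missing = required - set(serum.columns)
    if missing:
        raise ValueError(f"serum table missing columns: {sorted(missing)}")
    dup = serum.duplicated(subset=["subject_id", "week", "analyte"])
    if dup.any():
        first = serum.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (subject, week, analyte) measurement: "
            f"{first['subject_id']}/{first['week']}/{first['analyte']}"
        )
    if not npx and (serum[value_col] <= 0).any():
        raise ValueError("concentrations must be strictly positive on the linear scale")
    return serum


def _log2_values(serum: pd.DataFrame, npx: bool) -> pd.Series:
    if npx:
        return serum["npx"].astype(float)
    return np.log2(serum["conc_pg_ml"].astype(float))


@dataclass
class HCReference:
    """Healthy-control log2 summary per analyte: (n, mean_log2, var_log2)."""

    table: pd.DataFrame  # index analyte, columns n_hc, mean_log2, var_log2

    def __post_init__(self) -> None:
        need = {"n_hc", "mean_log2", "var_log2"}
        if not need <= set(self.table.columns):
            raise ValueError(f"HCReference needs columns {sorted(need)}")
        if (self.table["n_hc"] < 2).any():
            raise ValueError("healthy-control reference needs n >= 2 per analyte")
        if (self.table["var_log2"] < 0).any():
            raise ValueError("variances must be nonnegative")

    @classmethod
    def from_table(cls, hc_table: pd.DataFrame, npx: bool = False) -> "HCReference":
        value_col = "npx" if npx else "conc_pg_ml"
        if not npx and (hc_table[value_col] <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        x = hc_table.assign(log2=_log2_values(hc_table, npx))
        g = x.groupby("analyte")["log2"]
        table = pd.DataFrame(
            {"n_hc": g.size(), "mean_log2": g.mean(), "var_log2": g.var(ddof=1)}
        )
        return cls(table)

    @classmethod
    def from_summary(cls, rows: Dict[str, Tuple[int, float, float]]) -> "HCReference":
        table = pd.DataFrame.from_dict(
            {a: {"n_hc": n, "mean_log2": m, "var_log2": v} for a, (n, m, v) in rows.items()},
            orient="index",
        )
        table.index.name = "analyte"
        return cls(table)

    def __getitem__(self, analyte: str) -> Tuple[int, float, float]:
        if analyte not in self.table.index:
            raise MissingCellError(f"no healthy-control reference for {analyte!r}")
        row = self.table.loc[analyte]
        return int(row["n_hc"]), float(row["mean_log2"]), float(row["var_log2"])

    def analytes(self) -> List[str]:
        return list(self.table.index)


@dataclass
class ComparisonRecord:
    """One row of a treatment-group vs healthy-control comparison table."""

    arm: str
    week: int
    analyte: str
    n_grp: int
    mean_log2_grp: float
    mean_log2_hc: float
    log2ratio_vs_hc: float
    welch_t: float
    welch_df: float
    p_value: float
    degenerate: bool = False


def log2_summarize(
    serum: pd.DataFrame, arm: str, week: int, analyte: str, npx: bool = False
) -> Tuple[int, float, float]:
    """Return (n, mean, variance) of log2 values for one (arm, week, analyte) cell."""
    value_col = "npx" if npx else "conc_pg_ml"
    cell = serum[
        (serum["arm"] == arm) & (serum["week"] == week) & (serum["analyte"] == analyte)
    ]
    if len(cell) == 0:
        raise MissingCellError(f"no observations for arm={arm}, week={week}, analyte={analyte}")
    if len(cell) < 2:
        raise ValueError(f"cell arm={arm}, week={week}, analyte={analyte} has n < 2")
    if not npx and (cell[value_col] <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    x = _log2_values(cell, npx)
    return len(cell), float(x.mean()), float(x.var(ddof=1))


def compare_to_healthy(
    grp_summary: Tuple[int, float, float],
    hc_summary: Tuple[int, float, float],
    arm: str = "",
    week: int = 0,
    analyte: str = "",
) -> ComparisonRecord:
    """Welch comparison of a group log2 summary against the healthy-control one.

    ``log2ratio_vs_hc`` is exactly group mean minus healthy-control mean.
    """
    n_g, m_g, v_g = grp_summary
    n_h, m_h, v_h = hc_summary
    if n_g < 2 or n_h < 2:
        raise ValueError("both groups need n >= 2")
    t, dof, p = welch_from_stats(m_g, v_g, n_g, m_h, v_h, n_h)
    degenerate = (v_g == 0 or v_h == 0)
    return ComparisonRecord(
        arm=arm, week=week, analyte=analyte, n_grp=n_g,
        mean_log2_grp=m_g, mean_log2_hc=m_h,
        log2ratio_vs_hc=m_g - m_h,
        welch_t=t, welch_df=dof, p_value=p, degenerate=degenerate,
    )


def comparison_table(
    serum: pd.DataFrame,
    hc: HCReference,
    npx: bool = False,
    mask: Optional[Dict[str, List[str]]] = None,
) -> pd.DataFrame:
    """Tidy table of every (arm, week, analyte) cell vs healthy controls.

    ``mask`` maps analyte -> arms to omit (e.g. an analyte whose free level
    cannot be assayed in the presence of one arm's drug).
    """
    validate_serum_table(serum, npx=npx)
    mask = mask or {}
    rows = []
    for analyte in sorted(serum["analyte"].unique()):
        if analyte not in hc.table.index:
            continue
        for arm in sorted(serum["arm"].unique()):
            if arm in mask.get(analyte, []):
                continue
            for week in sorted(serum.loc[serum["arm"] == arm, "week"].unique()):
                try:
                    grp = log2_summarize(serum, arm, week, analyte, npx=npx)
                except MissingCellError:
                    continue
                rec = compare_to_healthy(grp, hc[analyte], arm=arm, week=week, analyte=analyte)
                rows.append(rec.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Longitudinal PD model
# ---------------------------------------------------------------------------


def _ratio_frame(
    serum: pd.DataFrame, analyte: str, baseline_week: int, npx: bool
) -> pd.DataFrame:
    """Per-subject log2 ratios to baseline for one analyte (long format)."""
    sub = serum[serum["analyte"] == analyte].copy()
    sub["log2"] = _log2_values(sub, npx)
    wide = sub.pivot_table(index=["subject_id", "arm"], columns="week", values="log2")
    if baseline_week not in wide.columns:
        raise ValueError(f"no baseline (week {baseline_week}) measurements for {analyte}")
    wide = wide.dropna(subset=[baseline_week])
    records = []
    for (subj, arm), row in wide.iterrows():
        base = row[baseline_week]
        for week in wide.columns:
            if week == baseline_week or math.isnan(row[week]):
                continue
            records.append((subj, arm, int(week), row[week] - base, base))
    return pd.DataFrame(records, columns=["subject_id", "arm", "week", "ratio", "baseline"])


@dataclass
class PDEffectResults:
    """Per-analyte pharmacodynamic effects on log2 ratios to baseline.

    ``effects`` has one row per analyte x arm x week (within-arm adjusted
    mean log2 ratio) and ``contrasts`` one row per analyte x week
    (between-arm difference). FDR columns are Benjamini-Hochberg adjusted
    across analytes within each (arm, week) / week family.
    """

    effects: pd.DataFrame
    contrasts: pd.DataFrame
    factor_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    baseline_week: int = 0

    def flag_proteins(
        self, fc_threshold: float = 1.25, fdr_threshold: float = 0.05,
        week: Optional[int] = None,
    ) -> Dict[str, List[str]]:
        """Per-arm lists of significantly *reduced* proteins and their overlap.

        A protein is flagged for an arm iff its log2 ratio is negative with
        |log2 ratio| > log2(fc_threshold) and FDR < fdr_threshold at the
        given week (default: last week).
        """
        eff = self.effects
        if week is None:
            week = int(eff["week"].max())
        cut = math.log2(fc_threshold)
        sel = eff[eff["week"] == week]
        arms = sorted(sel["arm"].unique())
        flagged = {
            arm: sorted(
                sel[(sel["arm"] == arm)
                    & (sel["estimate"] < 0)
                    & (sel["estimate"].abs() > cut)
                    & (sel["fdr"] < fdr_threshold)]["analyte"]
            )
            for arm in arms
        }
        out: Dict[str, List[str]] = {arm: flagged[arm] for arm in arms}
        if len(arms) == 2:
            a, b = arms
            both = sorted(set(flagged[a]) & set(flagged[b]))
            out["both"] = both
            out[f"{a}_only"] = sorted(set(flagged[a]) - set(both))
            out[f"{b}_only"] = sorted(set(flagged[b]) - set(both))
        return out

    def summary(self) -> str:
        lines = ["Longitudinal PD effects (log2 ratio to baseline week "
                 f"{self.baseline_week})", ""]
        lines.append(self.effects.to_string(index=False,
                                            float_format=lambda v: f"{v:.4g}"))
        if len(self.contrasts):
            lines.append("")
            lines.append("Between-arm contrasts:")
            lines.append(self.contrasts.to_string(index=False,
                                                  float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class SerumPDModel:
    """Longitudinal PD model over a panel of serum analytes.

    Parameters
    ----------
    serum : long-format table (subject_id, arm, week, analyte, conc_pg_ml
        or npx)
    baseline_week : visit used as the denominator of the log2 ratio
    npx : values are already log2 (Olink NPX) and are not re-logged
    mask : analyte -> arms whose measurements are excluded
    """

    def __init__(
        self,
        serum: pd.DataFrame,
        baseline_week: int = 0,
        npx: bool = False,
        mask: Optional[Dict[str, List[str]]] = None,
    ) -> None:
        self.serum = validate_serum_table(serum, npx=npx)
        self.baseline_week = baseline_week
        self.npx = npx
        self.mask = mask or {}

    def _frames(self, analytes: Optional[List[str]]):
        names = analytes or sorted(self.serum["analyte"].unique())
        for analyte in names:
            frame = _ratio_frame(self.serum, analyte, self.baseline_week, self.npx)
            for arm in self.mask.get(analyte, []):
                frame = frame[frame["arm"] != arm]
            yield analyte, frame

    def fit(self, analytes: Optional[List[str]] = None,
            extra_factors: Optional[List[str]] = None,
            factor_values: Optional[Dict[str, Dict[str, object]]] = None) -> PDEffectResults:
        eff_rows, con_rows, fac_rows = [], [], []
        for analyte, frame in self._frames(analytes):
            if extra_factors:
                for f in extra_factors:
                    frame[f] = frame["subject_id"].map(factor_values[f])
                    frame = frame.dropna(subset=[f])
            fit = fit_ratio_model(frame, extra_factors=extra_factors)
            for _, r in fit.cell_effects.iterrows():
                eff_rows.append((analyte, r["arm"], int(r["week"]), r["estimate"],
                                 r["se"], r["df"], r["p"]))
            for _, r in fit.contrasts.iterrows():
                con_rows.append((analyte, r["contrast"], int(r["week"]), r["estimate"],
                                 r["se"], r["df"], r["p"]))
            for _, r in fit.factor_effects.iterrows():
                fac_rows.append((analyte, r["factor"], r["level"], r["estimate"],
                                 r["se"], r["df"], r["p"]))
        cols = ["estimate", "se", "df", "p"]
        effects = pd.DataFrame(eff_rows, columns=["analyte", "arm", "week", *cols])
        contrasts = pd.DataFrame(con_rows, columns=["analyte", "contrast", "week", *cols])
        factors = pd.DataFrame(fac_rows, columns=["analyte", "factor", "level", *cols])
        # BH within each family (same arm/week across analytes)
        if len(effects):
            effects["fdr"] = effects.groupby(["arm", "week"])["p"].transform(adjust_fdr)
        if len(contrasts):
            contrasts["fdr"] = contrasts.groupby("week")["p"].transform(adjust_fdr)
        if len(factors):
            factors["fdr"] = factors.groupby(["factor", "level"])["p"].transform(adjust_fdr)
        return PDEffectResults(effects, contrasts, factors, self.baseline_week)


def pd_effect_model(
    serum: pd.DataFrame, baseline_week: int = 0, npx: bool = False,
    mask: Optional[Dict[str, List[str]]] = None,
) -> PDEffectResults:
    """Functional wrapper: fit the longitudinal PD model for every analyte."""
    return SerumPDModel(serum, baseline_week=baseline_week, npx=npx, mask=mask).fit()


def responders_from_pasi(
    pasi: pd.DataFrame, window: Tuple[int, int] = (20, 48), threshold: float = 3.0
) -> Dict[str, bool]:
    """Responder flag: absolute PASI below ``threshold`` at *every* visit in
    ``window`` (inclusive). Subjects with no visit in the window are omitted."""
    lo, hi = window
    sel = pasi[(pasi["week"] >= lo) & (pasi["week"] <= hi)]
    out: Dict[str, bool] = {}
    for subj, grp in sel.groupby("subject_id"):
        out[str(subj)] = bool((grp["pasi"] < threshold).all())
    return out


def responder_contrast(
    serum: pd.DataFrame,
    responder: Dict[str, bool],
    baseline_week: int = 0,
    npx: bool = False,
    arm: Optional[str] = None,
) -> pd.DataFrame:
    """Differential modulation between responders and inadequate responders.

    Fits the longitudinal model per analyte with responder status as an
    additional between-subject fixed factor and reports its effect with BH
    adjustment across analytes. ``arm`` restricts the analysis to one arm.
    """
    sub = serum if arm is None else serum[serum["arm"] == arm]
    flags = {k: bool(v) for k, v in responder.items()}
    present = set(sub["subject_id"].unique()) & set(flags)
    classes = {flags[s] for s in present}
    if len(classes) < 2:
        raise ValueError("responder flag has a single class; contrast undefined")
    model = SerumPDModel(sub, baseline_week=baseline_week, npx=npx)
    res = model.fit(extra_factors=["responder"], factor_values={"responder": flags})
    out = res.factor_effects[res.factor_effects["factor"] == "responder"].copy()
    return out.reset_index(drop=True)


def correlate_with_pasi(
    serum: pd.DataFrame, pasi: pd.DataFrame, analyte: str, npx: bool = False
) -> Tuple[float, float, int]:
    """Pearson correlation of log2 analyte level with PASI across pooled visits."""
    sub = serum[serum["analyte"] == analyte].copy()
    if len(sub) == 0:
        raise MissingCellError(f"no measurements for analyte {analyte!r}")
    sub["log2"] = _log2_values(sub, npx)
    merged = sub.merge(pasi, on=["subject_id", "week"], how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 paired (subject, week) observations")
    x = merged["log2"].to_numpy(float)
    y = merged["pasi"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in analyte or PASI; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), len(merged)
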