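"""Synthetic trial cohorts with known ground truth.

The generator plants exactly the structure the downstream estimators assume:

* serum analytes are log-normal; patients sit ``disease_offset`` log2 units
  above healthy controls at baseline, and each arm removes a configured
  fraction of that offset by each visit week;
* skin biopsy counts are negative binomial; a planted disease-gene set
  carries a lesional-vs-nonlesional log2 offset at baseline that decays by
  the arm's improvement fraction at later weeks;
* PASI severity scores are a linear function of designated analytes on the
  log2 scale plus Gaussian noise.

Every quantity a downstream stage estimates (offsets, decline fractions,
improvement fractions, disease-gene membership) is returned as ``truth`` so
tests can score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genesets import GeneSetCollection

__all__ = [
    "SyntheticBundle",
    "generate_serum_cohort",
    "generate_skin_cohort",
    "generate_gene_sets",
    "generate_bundle",
]

_SERUM_STREAM = 11
_SKIN_STREAM = 23
_SETS_STREAM = 37


@dataclass
class SyntheticBundle:
    """Everything one simulated trial produces, plus the planted truth."""

    serum_table: pd.DataFrame
    hc_table: pd.DataFrame
    pasi_table: pd.DataFrame
    counts: pd.DataFrame
    meta: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: dict


def _subject_ids(config: SimulationConfig) -> Dict[str, List[str]]:
    width = max(2, len(str(config.n_per_arm)))
    return {
        arm: [f"S{arm}{i + 1:0{width}d}" for i in range(config.n_per_arm)]
        for arm in config.norm_frac
    }


def generate_serum_cohort(
    config: SimulationConfig,
    responder_frac: float = 0.0,
    responder_extra_decline: Optional[Dict[str, float]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate serum analyte concentrations, healthy controls, and PASI.

    Returns ``(serum_table, hc_table, pasi_table, truth)``. Tables are long
    format with columns ``subject_id, arm, week, analyte, conc_pg_ml``
    (``subject_id, analyte, conc_pg_ml`` for healthy controls).

    ``responder_frac`` designates a random subset of subjects as responders;
    ``responder_extra_decline`` maps analyte -> additional decline fraction
    applied to responders at post-baseline weeks (capped at full decline).
    """
    config.validate()
    rng = np.random.default_rng([_SERUM_STREAM, config.seed])
    arms = list(config.norm_frac)
    subjects = _subject_ids(config)

    hc_rows = []
    hc_width = max(2, len(str(config.n_hc)))
    for analyte, ap in config.analyte_params.items():
        x = rng.normal(ap.hc_mean_log2, ap.hc_sd_log2, size=config.n_hc)
        for i, v in enumerate(x):
            hc_rows.append((f"HC{i + 1:0{hc_width}d}", analyte, float(2.0**v)))
    hc_table = pd.DataFrame(hc_rows, columns=["subject_id", "analyte", "conc_pg_ml"])

    responder: Dict[str, bool] = {}
    for arm in arms:
        for subj in subjects[arm]:
            responder[subj] = bool(rng.random() < responder_frac)
    extra = responder_extra_decline or {}

    serum_rows = []
    log2_by_subject_week: Dict[Tuple[str, int], Dict[str, float]] = {}
    for arm in arms:
        for subj in subjects[arm]:
            b_i = rng.normal(0.0, config.serum_subject_sd)
            for week in config.weeks:
                cell: Dict[str, float] = {}
                for analyte, ap in config.analyte_params.items():
                    decline = ap.decline_frac.get(arm, {}).get(week, 0.0)
                    if week > 0 and responder[subj]:
                        decline = min(1.0, decline + extra.get(analyte, 0.0))
                    mean = ap.hc_mean_log2 + ap.disease_offset * (1.0 - decline) + b_i
                    x = rng.normal(mean, config.serum_resid_sd)
                    cell[analyte] = x
                    serum_rows.append((subj, arm, week, analyte, float(2.0**x)))
                log2_by_subject_week[(subj, week)] = cell
    serum_table = pd.DataFrame(
        serum_rows, columns=["subject_id", "arm", "week", "analyte", "conc_pg_ml"]
    )

    pp = config.pasi_params
    pasi_rows = []
    for arm in arms:
        for subj in subjects[arm]:
            for week in config.weeks:
                cell = log2_by_subject_week[(subj, week)]
                val = pp.intercept + sum(
                    coef * cell[a] for a, coef in pp.coupling.items() if a in cell
                )
                val += rng.normal(0.0, pp.noise_sd)
                pasi_rows.append((subj, arm, week, float(max(0.0, val))))
    pasi_table = pd.DataFrame(pasi_rows, columns=["subject_id", "arm", "week", "pasi"])

    truth = {
        "disease_offset": {a: ap.disease_offset for a, ap in config.analyte_params.items()},
        "decline_frac": {
            a: {arm: dict(by_week) for arm, by_week in ap.decline_frac.items()}
            for a, ap in config.analyte_params.items()
        },
        "responder": responder,
        "responder_extra_decline": dict(extra),
    }
    return serum_table, hc_table, pasi_table, truth


def generate_skin_cohort(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate paired lesional/nonlesional RNA-seq counts.

    Nonlesional biopsies are taken at baseline only; lesional biopsies at
    every week in ``config.skin_weeks``. Counts are negative binomial with
    gene-specific means and the configured dispersion. Returns
    ``(counts, meta, truth)`` where ``counts`` is a genes x samples integer
    DataFrame and ``meta`` has columns
    ``sample_id, subject_id, arm, week, tissue``.
    """
    config.validate()
    if config.n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2 for paired statistics")
    rng = np.random.default_rng([_SKIN_STREAM, config.seed])
    arms = list(config.norm_frac)
    subjects = _subject_ids(config)

    width = len(str(config.n_genes))
    genes = np.array([f"G{i + 1:0{width}d}" for i in range(config.n_genes)])
    disease_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_disease_genes, replace=False)
    )
    signs = rng.choice([-1.0, 1.0], size=config.n_disease_genes)
    magnitudes = np.maximum(
        rng.normal(config.lfc_mean, config.lfc_sd, size=config.n_disease_genes), 0.1
    )
    offsets = signs * magnitudes  # lesional - nonlesional log2 offset at baseline

    base_log2 = rng.normal(config.base_log2_mean, config.base_log2_sd, size=config.n_genes)

    meta_rows = []
    sample_means = []  # per-sample log2 mean vectors
    sigma2 = np.log(1.0 + config.lib_size_cv**2)
    for arm in arms:
        for subj in subjects[arm]:
            s_i = rng.normal(0.0, config.skin_subject_sd)
            v_i = rng.normal(1.0, config.skin_severity_sd)
            # nonlesional baseline
            mu_nl = base_log2 + s_i
            meta_rows.append((f"{subj}_NL_w0", subj, arm, 0, "nonlesional"))
            sample_means.append(mu_nl)
            for week in config.skin_weeks:
                frac = 0.0 if week == 0 else config.norm_frac[arm].get(week, 0.0)
                mu = base_log2 + s_i
                mu = mu.copy()
                mu[disease_idx] = mu[disease_idx] + offsets * v_i * (1.0 - frac)
                meta_rows.append((f"{subj}_L_w{week}", subj, arm, week, "lesional"))
                sample_means.append(mu)

    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "arm", "week", "tissue"]
    )
    mean_mat = np.column_stack(sample_means)  # genes x samples, log2 scale
    weights = np.exp2(mean_mat)
    props = weights / weights.sum(axis=0, keepdims=True)
    lib_sizes = rng.lognormal(
        np.log(config.lib_size_mean) - sigma2 / 2.0,
        np.sqrt(sigma2),
        size=props.shape[1],
    )
    lam = props * lib_sizes[np.newaxis, :]
    r = 1.0 / config.dispersion
    p = r / (r + lam)
    counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=genes, columns=meta["sample_id"].to_numpy())
    counts_df.index.name = "gene"

    disease_genes = genes[disease_idx]
    truth = {
        "disease_genes": list(disease_genes),
        "direction": {g: ("up" if s > 0 else "down") for g, s in zip(disease_genes, signs)},
        "offset": {g: float(o) for g, o in zip(disease_genes, offsets)},
        "improvement_frac": {
            arm: {int(w): float(f) for w, f in by_week.items()}
            for arm, by_week in config.norm_frac.items()
        },
        "gene_improvement_frac": {
            g: {
                arm: {int(w): float(f) for w, f in by_week.items()}
                for arm, by_week in config.norm_frac.items()
            }
            for g in disease_genes
        },
    }
    return counts_df, meta, truth


def generate_gene_sets(
    truth: dict,
    universe,
    n_decoy_sets: int = 10,
    set_size_range: Tuple[int, int] = (20, 200),
    seed: int = 0,
) -> GeneSetCollection:
    """Truth-derived disease signatures plus random decoy sets.

    The planted disease genes are split by direction into ``disease_up`` and
    ``disease_down``; decoys are uniform random draws from ``universe``.
    """
    universe = list(universe)
    lo, hi = set_size_range
    if not (1 <= lo <= hi):
        raise ValueError("set_size_range must satisfy 1 <= lo <= hi")
    if hi > len(universe):
        raise ValueError("decoy set size exceeds gene universe")
    rng = np.random.default_rng([_SETS_STREAM, seed])
    direction = truth["direction"]
    up = [g for g in truth["disease_genes"] if direction[g] == "up"]
    down = [g for g in truth["disease_genes"] if direction[g] == "down"]
    sets: Dict[str, List[str]] = {}
    descriptions: Dict[str, str] = {}
    if up:
        sets["disease_up"] = up
        descriptions["disease_up"] = "planted disease genes, upregulated in lesional skin"
    if down:
        sets["disease_down"] = down
        descriptions["disease_down"] = "planted disease genes, downregulated in lesional skin"
    width = max(2, len(str(max(n_decoy_sets, 1))))
    for k in range(n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        name = f"decoy_{k + 1:0{width}d}"
        sets[name] = members
        descriptions[name] = "random decoy set"
    return GeneSetCollection(sets, descriptions, source="synthetic")


def generate_bundle(config: SimulationConfig, n_decoy_sets: int = 10) -> SyntheticBundle:
    """Generate a complete synthetic trial (serum + skin + gene sets)."""
    serum, hc, pasi, serum_truth = generate_serum_cohort(config)
    counts, meta, skin_truth = generate_skin_cohort(config)
    gene_sets = generate_gene_sets(
        skin_truth,
        counts.index,
        n_decoy_sets=n_decoy_sets,
        set_size_range=(20, min(200, config.n_genes)),
        seed=config.seed,
    )
    truth = {"serum": serum_truth, "skin": skin_truth}
    return SyntheticBundle(serum, hc, pasi, counts, meta, gene_sets, truth)
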