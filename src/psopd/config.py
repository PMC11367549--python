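"""Simulation and pipeline configuration objects.

`SimulationConfig` pins down every distributional choice of the synthetic
cohort generator. The defaults emulate a two-arm head-to-head biologic trial
in moderate-to-severe plaque psoriasis: arm "A" behaves like an IL-17A
blocker (rapid early normalization of effector readouts), arm "B" like an
IL-23 blocker (slower early, deeper sustained pathway suppression). Serum
analyte levels are log-normal; skin RNA-seq counts are negative binomial
with a planted disease-gene set whose lesional offset decays according to
per-arm, per-week improvement fractions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

__all__ = ["AnalyteParams", "PasiParams", "SimulationConfig", "PipelineConfig"]

ARMS = ("A", "B")


@dataclass
class AnalyteParams:
    """Generative parameters for one serum analyte (log2 pg/ml scale).

    ``decline_frac[arm][week]`` is the fraction of the disease offset removed
    by week ``week`` in that arm: 0 = untreated level, 1 = healthy-control
    level.
    """

    hc_mean_log2: float
    hc_sd_log2: float
    disease_offset: float
    decline_frac: Dict[str, Dict[int, float]]

    def validate(self, weeks: List[int]) -> None:
        if self.hc_sd_log2 <= 0:
            raise ValueError("hc_sd_log2 must be positive")
        for arm, by_week in self.decline_frac.items():
            for week, frac in by_week.items():
                if not (0.0 <= frac <= 1.0):
                    raise ValueError(
                        f"decline_frac[{arm}][{week}]={frac} outside [0, 1]"
                    )


@dataclass
class PasiParams:
    """Linear coupling of PASI to designated analytes on the log2 scale.

    ``PASI = intercept + sum_a coupling[a] * log2(conc_a) + N(0, noise_sd^2)``
    clipped at zero. With the default coupling to BD-2 this yields baseline
    PASI around 20 (moderate-to-severe disease) that falls as the analyte
    normalizes.
    """

    intercept: float = 4.0
    coupling: Dict[str, float] = field(default_factory=lambda: {"BD-2": 1.2})
    noise_sd: float = 4.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _default_analytes() -> Dict[str, AnalyteParams]:
    """Five-analyte panel mirroring the IL-23/Th17 axis readouts.

    Healthy-control means, disease offsets, and per-arm decline kinetics are
    set to the magnitudes reported for this trial design: the IL-17A-blocker
    arm (A) rapidly clears IL-23 and BD-2 but barely moves IL-17F/IL-22,
    while the IL-23-blocker arm (B) drives IL-17F near healthy-control
    levels by week 24.
    """
    return {
        "IL-23": AnalyteParams(
            -3.246, 1.0, 0.775,
            {"A": {0: 0.0, 4: 0.82, 24: 0.99, 48: 0.61},
             "B": {0: 0.0, 4: 0.24, 24: 0.44, 48: 0.51}},
        ),
        "IL-17A": AnalyteParams(
            -3.063, 1.0, 3.21,
            {"A": {0: 0.0, 4: 0.40, 24: 0.65, 48: 0.70},
             "B": {0: 0.0, 4: 0.39, 24: 0.66, 48: 0.69}},
        ),
        "IL-17F": AnalyteParams(
            -0.692, 1.0, 2.38,
            {"A": {0: 0.0, 4: 0.04, 24: 0.49, 48: 0.51},
             "B": {0: 0.0, 4: 0.50, 24: 1.00, 48: 0.99}},
        ),
        "IL-22": AnalyteParams(
            1.199, 1.0, 2.58,
            {"A": {0: 0.0, 4: 0.11, 24: 0.11, 48: 0.10},
             "B": {0: 0.0, 4: 0.33, 24: 0.56, 48: 0.58}},
        ),
        "BD-2": AnalyteParams(
            8.167, 1.0, 5.01,
            {"A": {0: 0.0, 4: 0.745, 24: 0.83, 48: 0.76},
             "B": {0: 0.0, 4: 0.47, 24: 0.835, 48: 0.84}},
        ),
    }


def _default_norm_frac() -> Dict[str, Dict[int, float]]:
    return {"A": {4: 0.80, 24: 0.85}, "B": {4: 0.45, 24: 0.85}}


@dataclass
class SimulationConfig:
    """Full description of a synthetic trial cohort.

    Serum visits default to weeks {0, 4, 24, 48}; skin biopsies to
    {0, 4, 24} with nonlesional tissue sampled at baseline only.
    """

    seed: int = 0
    n_per_arm: int = 17
    n_hc: int = 25
    weeks: List[int] = field(default_factory=lambda: [0, 4, 24, 48])
    skin_weeks: List[int] = field(default_factory=lambda: [0, 4, 24])
    n_genes: int = 10_000
    n_disease_genes: int = 300
    lfc_mean: float = 2.5
    lfc_sd: float = 0.7
    dispersion: float = 0.1
    lib_size_mean: float = 1.0e6
    norm_frac: Dict[str, Dict[int, float]] = field(default_factory=_default_norm_frac)
    analyte_params: Dict[str, AnalyteParams] = field(default_factory=_default_analytes)
    pasi_params: PasiParams = field(default_factory=PasiParams)
    # nuisance scales (log2)
    serum_subject_sd: float = 0.6
    serum_resid_sd: float = 0.5
    skin_subject_sd: float = 0.2
    skin_severity_sd: float = 0.15
    base_log2_mean: float = 4.0
    base_log2_sd: float = 2.0
    lib_size_cv: float = 0.2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.n_hc < 2:
            raise ValueError("n_hc must be >= 2")
        for name, wk in (("weeks", self.weeks), ("skin_weeks", self.skin_weeks)):
            if sorted(wk) != list(wk) or wk[0] != 0:
                raise ValueError(f"{name} must be sorted ascending and include 0")
        if self.n_disease_genes > self.n_genes:
            raise ValueError("n_disease_genes cannot exceed n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.lib_size_mean <= 0:
            raise ValueError("lib_size_mean must be positive")
        if self.lfc_sd < 0 or self.serum_resid_sd < 0:
            raise ValueError("scale parameters must be nonnegative")
        for arm, by_week in self.norm_frac.items():
            for week, frac in by_week.items():
                if not (0.0 <= frac <= 1.0):
                    raise ValueError(f"norm_frac[{arm}][{week}]={frac} outside [0, 1]")
        for name, ap in self.analyte_params.items():
            ap.validate(self.weeks)
        self.pasi_params.validate()

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "analyte_params" in d:
            d["analyte_params"] = {
                name: ap if isinstance(ap, AnalyteParams) else AnalyteParams(
                    hc_mean_log2=ap["hc_mean_log2"],
                    hc_sd_log2=ap["hc_sd_log2"],
                    disease_offset=ap["disease_offset"],
                    decline_frac={
                        arm: {int(w): float(f) for w, f in by_week.items()}
                        for arm, by_week in ap["decline_frac"].items()
                    },
                )
                for name, ap in d["analyte_params"].items()
            }
        if "pasi_params" in d and not isinstance(d["pasi_params"], PasiParams):
            d["pasi_params"] = PasiParams(**d["pasi_params"])
        if "norm_frac" in d:
            d["norm_frac"] = {
                arm: {int(w): float(f) for w, f in by_week.items()}
                for arm, by_week in d["norm_frac"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineConfig:
    """Threshold set and file locations for a full pipeline run."""

    counts: Optional[str] = None
    meta: Optional[str] = None
    serum: Optional[str] = None
    hc: Optional[str] = None
    pasi: Optional[str] = None
    gmt: Optional[str] = None
    out_dir: str = "psopd_run"
    seed: int = 0
    baseline_week: int = 0
    fc: float = 2.0
    de_fdr: float = 0.05
    pseudocount: float = 0.5
    norm_threshold: float = 75.0
    improvement_min: float = 50.0
    difference_min: float = 25.0
    olink_fc: float = 1.25
    olink_fdr: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fc", "de_fdr", "norm_threshold", "improvement_min",
                     "difference_min", "olink_fc", "olink_fdr", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))
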