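"""Bundled reference data.

`load_serum_reference` returns the published per-visit log2 mean serum
concentrations for five IL-23/Th17-axis analytes in a head-to-head trial of
an IL-23 blocker (GUS) versus an IL-17A blocker (SEC) in plaque psoriasis,
together with the healthy-control log2 means and the published log2 ratio
versus healthy controls and Welch p-value for each cell. IL-17A rows exist
only for the IL-23-blocker arm (antibody-bound IL-17A interferes with the
free-analyte assay in the other arm). These are summary statistics, not
subject-level data; the table is used to cross-check that the comparison
machinery reproduces each published log2 ratio as the difference of the two
published means.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_serum_reference"]

# analyte, arm, week, mean_log2_grp, mean_log2_hc, p_value, log2ratio_vs_hc
_ROWS = [
    ("IL-23", "GUS", 0, -2.370397548, -3.246324656, 0.003851, 0.875927108),
    ("IL-23", "GUS", 4, -2.579127111, -3.246324656, 0.018075, 0.667197545),
    ("IL-23", "GUS", 24, -2.758378704, -3.246324656, 0.086941, 0.487945952),
    ("IL-23", "GUS", 48, -2.818471928, -3.246324656, 0.135925, 0.427852728),
    ("IL-23", "SEC", 0, -2.572347183, -3.246324656, 0.01934, 0.673977473),
    ("IL-23", "SEC", 4, -3.122076846, -3.246324656, 0.664485, 0.12424781),
    ("IL-23", "SEC", 24, -3.240175902, -3.246324656, 0.982629, 0.006148754),
    ("IL-23", "SEC", 48, -2.980382305, -3.246324656, 0.364252, 0.26594235),
    ("IL-17A", "GUS", 0, 0.145772854, -3.062695292, 9.78e-11, 3.208468146),
    ("IL-17A", "GUS", 4, -1.095844909, -3.062695292, 4.03e-06, 1.966850383),
    ("IL-17A", "GUS", 24, -1.986971817, -3.062695292, 0.005180201, 1.075723475),
    ("IL-17A", "GUS", 48, -2.061706827, -3.062695292, 0.008698572, 1.000988464),
    ("IL-17F", "GUS", 0, 1.799332011, -0.691883724, 3.31e-12, 2.491215735),
    ("IL-17F", "GUS", 4, 0.563581197, -0.691883724, 2.39e-05, 1.255464922),
    ("IL-17F", "GUS", 24, -0.683238429, -0.691883724, 0.973063085, 0.008645295),
    ("IL-17F", "GUS", 48, -0.670057224, -0.691883724, 0.932420113, 0.0218265),
    ("IL-17F", "SEC", 0, 1.582500142, -0.691883724, 4.75e-11, 2.274383866),
    ("IL-17F", "SEC", 4, 1.494891141, -0.691883724, 1.55e-10, 2.186774866),
    ("IL-17F", "SEC", 24, 0.457503525, -0.691883724, 5.00e-05, 1.149387249),
    ("IL-17F", "SEC", 48, 0.433354001, -0.691883724, 6.43e-05, 1.125237725),
    ("IL-22", "GUS", 0, 3.931931452, 1.198637352, 2.67e-10, 2.7332941),
    ("IL-22", "GUS", 4, 3.029944805, 1.198637352, 1.30e-06, 1.831307453),
    ("IL-22", "GUS", 24, 2.403793282, 1.198637352, 0.00049697, 1.20515593),
    ("IL-22", "GUS", 48, 2.35715838, 1.198637352, 0.000741152, 1.158521028),
    ("IL-22", "SEC", 0, 3.623752611, 1.198637352, 4.63e-09, 2.425115259),
    ("IL-22", "SEC", 4, 3.348415998, 1.198637352, 6.19e-08, 2.149778646),
    ("IL-22", "SEC", 24, 3.357549244, 1.198637352, 5.70e-08, 2.158911892),
    ("IL-22", "SEC", 48, 3.386892767, 1.198637352, 4.34e-08, 2.188255415),
    ("BD-2", "GUS", 0, 13.34864101, 8.167054696, 4.90e-14, 5.181586318),
    ("BD-2", "GUS", 4, 10.9111621, 8.167054696, 1.60e-13, 2.744107402),
    ("BD-2", "GUS", 24, 9.023421849, 8.167054696, 0.236041845, 0.856367153),
    ("BD-2", "GUS", 48, 8.983609601, 8.167054696, 0.304972027, 0.816554906),
    ("BD-2", "SEC", 0, 12.99886891, 8.167054696, 4.90e-14, 4.839354007),
    ("BD-2", "SEC", 4, 9.403530987, 8.167054696, 0.006414729, 1.236476291),
    ("BD-2", "SEC", 24, 9.007794381, 8.167054696, 0.27052694, 0.836521839),
    ("BD-2", "SEC", 48, 9.344418366, 8.167054696, 0.012715225, 1.177363671),
]


def load_serum_reference() -> pd.DataFrame:
    """Published serum log2 summary statistics (see module docstring).

    Columns: ``analyte, arm, week, mean_log2_grp, mean_log2_hc, p_value,
    log2ratio_vs_hc``. Group sizes were n = 100 per arm and n = 25 healthy
    controls.
    """
    return pd.DataFrame(
        _ROWS,
        columns=["analyte", "arm", "week", "mean_log2_grp", "mean_log2_hc",
                 "p_value", "log2ratio_vs_hc"],
    )
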