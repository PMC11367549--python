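"""Tests for serum summaries, healthy-control comparisons, the longitudinal
PD model, responder contrasts, and PASI correlation."""

import numpy as np
import pandas as pd
import pytest

from psopd import SimulationConfig
from psopd.config import AnalyteParams
from psopd.serum import (HCReference, MissingCellError, SerumPDModel,
                         compare_to_healthy, comparison_table,
                         correlate_with_pasi, log2_summarize, pd_effect_model,
                         responder_contrast, responders_from_pasi,
                         validate_serum_table)
from psopd.simulate import generate_serum_cohort


def _table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "arm", "week", "analyte",
                                       "conc_pg_ml"])


class TestLog2Summarize:
    def test_constant_concentrations(self):
        t = _table([(f"s{i}", "A", 0, "X", 4.0) for i in range(3)])
        n, m, v = log2_summarize(t, "A", 0, "X")
        assert (n, m, v) == (3, 2.0, 0.0)

    def test_two_values(self):
        t = _table([("s1", "A", 0, "X", 1.0), ("s2", "A", 0, "X", 4.0)])
        assert log2_summarize(t, "A", 0, "X")[1] == pytest.approx(1.0)

    def test_missing_cell(self):
        t = _table([("s1", "A", 0, "X", 1.0), ("s2", "A", 0, "X", 4.0)])
        with pytest.raises(MissingCellError):
            log2_summarize(t, "B", 0, "X")

    def test_nonpositive_rejected(self):
        t = _table([("s1", "A", 0, "X", 0.0), ("s2", "A", 0, "X", 4.0)])
        with pytest.raises(ValueError):
            log2_summarize(t, "A", 0, "X")

    def test_npx_not_relogged(self):
        t = _table([("s1", "A", 0, "X", 0), ("s2", "A", 0, "X", 0)])
        t = t.rename(columns={"conc_pg_ml": "npx"})
        t["npx"] = [3.0, 5.0]
        assert log2_summarize(t, "A", 0, "X", npx=True)[1] == pytest.approx(4.0)

    def test_planted_mean_recovered(self, serum_small):
        serum, hc, pasi, truth = serum_small
        cfg = SimulationConfig(seed=12, n_per_arm=12)
        ap = cfg.analyte_params["IL-22"]
        n, m, v = log2_summarize(serum, "A", 0, "IL-22")
        mu = ap.hc_mean_log2 + ap.disease_offset
        assert abs(m - mu) < 3 * np.sqrt(v / n) + 0.3


class TestCompareToHealthy:
    def test_log2ratio_is_mean_difference(self):
        rec = compare_to_healthy((10, -2.37, 1.1), (25, -3.25, 0.9))
        assert rec.log2ratio_vs_hc == pytest.approx(-2.37 + 3.25, abs=1e-12)

    def test_identity_case(self):
        rec = compare_to_healthy((10, 1.5, 0.7), (10, 1.5, 0.7))
        assert rec.log2ratio_vs_hc == 0.0
        assert rec.p_value == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        rec = compare_to_healthy((5, 2.0, 0.0), (5, 1.0, 0.0))
        assert rec.p_value == 0.0 and rec.degenerate

    def test_table_masks_assay_interference(self, serum_small):
        serum, hc, _, _ = serum_small
        ref = HCReference.from_table(hc)
        tbl = comparison_table(serum, ref, mask={"IL-17A": ["A"]})
        sub = tbl[tbl["analyte"] == "IL-17A"]
        assert set(sub["arm"]) == {"B"}


class TestValidation:
    def test_duplicate_measurement_rejected(self):
        t = _table([("s1", "A", 0, "X", 1.0), ("s1", "A", 0, "X", 2.0)])
        with pytest.raises(ValueError, match="duplicate"):
            validate_serum_table(t)

    def test_hc_reference_needs_two(self):
        with pytest.raises(ValueError):
            HCReference.from_summary({"X": (1, 0.0, 1.0)})


class TestPDModel:
    def test_recovers_planted_decline(self, serum_small):
        serum, hc, pasi, truth = serum_small
        res = pd_effect_model(serum)
        for analyte in ("IL-17F", "IL-22"):
            for arm in ("A", "B"):
                planted = -truth["disease_offset"][analyte] * \
                    truth["decline_frac"][analyte][arm][48]
                row = res.effects[(res.effects["analyte"] == analyte)
                                  & (res.effects["arm"] == arm)
                                  & (res.effects["week"] == 48)].iloc[0]
                assert row["estimate"] == pytest.approx(planted, abs=4 * row["se"] + 0.1)

    def test_arm_permutation_flips_contrast(self, serum_small):
        serum, _, _, _ = serum_small
        res = pd_effect_model(serum)
        swapped = serum.copy()
        swapped["arm"] = swapped["arm"].map({"A": "B", "B": "A"})
        res2 = pd_effect_model(swapped)
        a = res.contrasts.set_index(["analyte", "week"])["estimate"]
        b = res2.contrasts.set_index(["analyte", "week"])["estimate"]
        np.testing.assert_allclose(a.to_numpy(), -b.loc[a.index].to_numpy(), atol=1e-6)

    def test_single_visit_reduces_to_ancova(self):
        """One post-baseline visit per subject: estimates equal the
        closed-form least-squares ANCOVA solution."""
        cfg = SimulationConfig(seed=41, n_per_arm=20, weeks=[0, 48])
        serum, _, _, _ = generate_serum_cohort(cfg)
        analyte = "IL-22"
        res = SerumPDModel(serum).fit(analytes=[analyte])
        from psopd.serum import _ratio_frame
        frame = _ratio_frame(serum, analyte, 0, False)
        X = np.column_stack([
            (frame["arm"] == "A").to_numpy(float),
            (frame["arm"] == "B").to_numpy(float),
            (frame["baseline"] - frame["baseline"].mean()).to_numpy(float),
        ])
        beta = np.linalg.lstsq(X, frame["ratio"].to_numpy(), rcond=None)[0]
        eff = res.effects.set_index("arm")["estimate"]
        assert eff["A"] == pytest.approx(beta[0], abs=1e-8)
        assert eff["B"] == pytest.approx(beta[1], abs=1e-8)

    def test_missing_design_cell_errors(self):
        cfg = SimulationConfig(seed=42, n_per_arm=4)
        serum, _, _, _ = generate_serum_cohort(cfg)
        broken = serum[~((serum["arm"] == "A") & (serum["week"] == 24))]
        with pytest.raises(ValueError, match="cell"):
            SerumPDModel(broken).fit(analytes=["IL-22"])

    def test_fdr_at_least_p(self, serum_small):
        serum, _, _, _ = serum_small
        res = pd_effect_model(serum)
        assert (res.effects["fdr"] >= res.effects["p"] - 1e-12).all()


class TestFlagProteins:
    @staticmethod
    def _fake_results(rows):
        from psopd.serum import PDEffectResults
        eff = pd.DataFrame(rows, columns=["analyte", "arm", "week", "estimate",
                                          "se", "df", "p", "fdr"])
        return PDEffectResults(eff, pd.DataFrame())

    def test_threshold_arithmetic(self):
        # |-0.30| < log2(1.25) ~ 0.322 -> not flagged despite tiny fdr
        res = self._fake_results([
            ("P1", "A", 48, -0.30, 0.1, 50, 1e-4, 1e-2),
            ("P2", "A", 48, -0.39, 0.1, 50, 1e-5, 1e-4),
            ("P2", "B", 48, -0.39, 0.1, 50, 1e-5, 1e-4),
            ("P3", "A", 48, 0.50, 0.1, 50, 1e-5, 1e-4),  # increase, not reduction
        ])
        flags = res.flag_proteins(1.25, 0.05)
        assert flags["A"] == ["P2"]
        assert flags["both"] == ["P2"]
        assert flags["A_only"] == [] and flags["B_only"] == []

    def test_partition_recovered_from_planted_effects(self):
        """7 shared + 6 A-only + 2 B-only planted reductions partition
        exactly."""
        rows = []
        names = [f"SH{i}" for i in range(7)] + [f"AO{i}" for i in range(6)] + \
                [f"BO{i}" for i in range(2)]
        for name in names:
            in_a = name.startswith(("SH", "AO"))
            in_b = name.startswith(("SH", "BO"))
            rows.append((name, "A", 48, -0.8 if in_a else -0.05, 0.1, 50,
                         1e-6 if in_a else 0.9, 1e-5 if in_a else 0.95))
            rows.append((name, "B", 48, -0.8 if in_b else -0.05, 0.1, 50,
                         1e-6 if in_b else 0.9, 1e-5 if in_b else 0.95))
        flags = self._fake_results(rows).flag_proteins(1.25, 0.05)
        assert len(flags["both"]) == 7
        assert len(flags["A_only"]) == 6
        assert len(flags["B_only"]) == 2


class TestResponders:
    def test_flag_from_pasi_window(self):
        pasi = pd.DataFrame({
            "subject_id": ["s1"] * 3 + ["s2"] * 3 + ["s3"],
            "week": [0, 24, 48] * 2 + [0],
            "pasi": [20, 1.0, 2.0, 18, 2.0, 5.0, 30],
        })
        flags = responders_from_pasi(pasi)
        assert flags == {"s1": True, "s2": False}  # s3 has no visit in window

    def test_one_class_errors(self, serum_small):
        serum, _, _, _ = serum_small
        flags = {s: True for s in serum["subject_id"].unique()}
        with pytest.raises(ValueError, match="single class"):
            responder_contrast(serum, flags)

    def test_planted_responder_decline_detected(self):
        """An analyte with a responder-specific extra decline is the only
        one flagged at FDR < 0.05."""
        cfg = SimulationConfig(seed=43, n_per_arm=40)
        serum, _, _, truth = generate_serum_cohort(
            cfg, responder_frac=0.5, responder_extra_decline={"IL-22": 0.4})
        out = responder_contrast(serum, truth["responder"])
        hit = set(out[out["fdr"] < 0.05]["analyte"])
        assert "IL-22" in hit
        assert len(hit) <= 2  # no systematic false positives

    def test_independent_flag_near_uniform_p(self):
        """Responder labels independent of the data give unremarkable
        interaction p-values (no small-p pile-up over replicates)."""
        ps = []
        for rep in range(20):
            cfg = SimulationConfig(seed=500 + rep, n_per_arm=16)
            serum, _, _, _ = generate_serum_cohort(cfg)
            subjects = sorted(serum["subject_id"].unique())
            flags = {s: (i % 2 == 0) for i, s in enumerate(subjects)}
            out = responder_contrast(serum, flags)
            ps.extend(out["p"].tolist())
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() < 0.15
        assert ps.mean() > 0.3


class TestPasiCorrelation:
    def test_perfect_linear_coupling(self):
        serum = _table([(f"s{i}", "A", 0, "X", 2.0 ** (i / 4)) for i in range(12)])
        pasi = pd.DataFrame({"subject_id": [f"s{i}" for i in range(12)],
                             "week": 0, "pasi": [5 + 3 * (i / 4) for i in range(12)]})
        r, p, n = correlate_with_pasi(serum, pasi, "X")
        assert r == pytest.approx(1.0, abs=1e-9)
        assert n == 12

    def test_recovers_generator_coupling(self):
        cfg = SimulationConfig(seed=44, n_per_arm=50)
        serum, _, pasi, _ = generate_serum_cohort(cfg)
        r, p, n = correlate_with_pasi(serum, pasi, "BD-2")
        assert r > 0.35 and p < 1e-6

    def test_permuted_pasi_kills_correlation(self):
        rs = []
        for rep in range(30):
            cfg = SimulationConfig(seed=600 + rep, n_per_arm=12, weeks=[0, 48])
            serum, _, pasi, _ = generate_serum_cohort(cfg)
            rng = np.random.default_rng(rep)
            pasi = pasi.assign(pasi=rng.permutation(pasi["pasi"].to_numpy()))
            rs.append(correlate_with_pasi(serum, pasi, "BD-2")[0])
        assert abs(np.mean(rs)) < 0.1

    def test_zero_variance_errors(self):
        serum = _table([(f"s{i}", "A", 0, "X", 4.0) for i in range(5)])
        pasi = pd.DataFrame({"subject_id": [f"s{i}" for i in range(5)],
                             "week": 0, "pasi": np.arange(5.0)})
        with pytest.raises(ValueError, match="variance"):
            correlate_with_pasi(serum, pasi, "X")
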