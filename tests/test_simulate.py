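"""Tests of the synthetic cohort generator: determinism, configuration
validation, planted-effect expectations, and count marginals."""

import numpy as np
import pandas as pd
import pytest

from psopd import SimulationConfig
from psopd.config import AnalyteParams
from psopd.simulate import (generate_bundle, generate_gene_sets,
                            generate_serum_cohort, generate_skin_cohort)


def _null_config(**kw):
    """Config with every decline fraction zero (no treatment effect)."""
    cfg = SimulationConfig(**kw)
    for ap in cfg.analyte_params.values():
        ap.decline_frac = {arm: {w: 0.0 for w in cfg.weeks} for arm in ("A", "B")}
    return cfg


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(seed=5, n_per_arm=4, n_genes=200, n_disease_genes=20)
        b1 = generate_bundle(cfg, n_decoy_sets=2)
        b2 = generate_bundle(cfg, n_decoy_sets=2)
        pd.testing.assert_frame_equal(b1.serum_table, b2.serum_table)
        pd.testing.assert_frame_equal(b1.hc_table, b2.hc_table)
        pd.testing.assert_frame_equal(b1.pasi_table, b2.pasi_table)
        pd.testing.assert_frame_equal(b1.counts, b2.counts)
        pd.testing.assert_frame_equal(b1.meta, b2.meta)
        assert b1.truth == b2.truth
        assert dict(b1.gene_sets.sets) == dict(b2.gene_sets.sets)

    def test_different_seed_differs(self):
        c1 = generate_skin_cohort(SimulationConfig(seed=1, n_per_arm=3, n_genes=100,
                                                   n_disease_genes=10))[0]
        c2 = generate_skin_cohort(SimulationConfig(seed=2, n_per_arm=3, n_genes=100,
                                                   n_disease_genes=10))[0]
        assert not c1.equals(c2)


class TestConfigValidation:
    def test_rejects_bad_fields(self):
        with pytest.raises(ValueError):
            SimulationConfig(dispersion=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_disease_genes=50, n_genes=10)
        with pytest.raises(ValueError):
            SimulationConfig(weeks=[4, 0, 24])
        with pytest.raises(ValueError):
            SimulationConfig(norm_frac={"A": {4: 1.4}})
        with pytest.raises(ValueError):
            SimulationConfig(analyte_params={
                "X": AnalyteParams(0.0, -1.0, 1.0, {"A": {4: 0.5}})})

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_per_arm=5)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_skin_needs_two_subjects(self):
        with pytest.raises(ValueError, match="paired"):
            generate_skin_cohort(SimulationConfig(n_per_arm=1, n_genes=50,
                                                  n_disease_genes=5))


class TestSerumGenerator:
    def test_concentrations_positive(self, serum_small):
        serum, hc, pasi, truth = serum_small
        assert (serum["conc_pg_ml"] > 0).all()
        assert (hc["conc_pg_ml"] > 0).all()

    def test_null_config_log2_ratio_constant_over_weeks(self):
        """With zero decline the expected log2 level is flat in time."""
        cfg = _null_config(seed=21, n_per_arm=60)
        serum, hc, _, _ = generate_serum_cohort(cfg)
        x = serum[serum["analyte"] == "IL-17F"].copy()
        x["log2"] = np.log2(x["conc_pg_ml"])
        by_week = x.groupby("week")["log2"].mean()
        assert by_week.max() - by_week.min() < 0.25  # sampling noise only

    def test_full_decline_reaches_healthy_level(self):
        """decline_frac = 1 at week 48 puts the group mean at the HC mean."""
        cfg = SimulationConfig(seed=22, n_per_arm=200)
        ap = cfg.analyte_params["IL-17F"]
        ap.decline_frac["B"][48] = 1.0
        serum, hc, _, _ = generate_serum_cohort(cfg)
        x = serum[(serum["analyte"] == "IL-17F") & (serum["arm"] == "B")
                  & (serum["week"] == 48)]
        grp_mean = np.log2(x["conc_pg_ml"]).mean()
        se = np.sqrt(cfg.serum_subject_sd**2 + cfg.serum_resid_sd**2) / np.sqrt(len(x))
        assert abs(grp_mean - ap.hc_mean_log2) < 4 * se

    def test_baseline_offset_above_hc(self):
        cfg = SimulationConfig(seed=23, n_per_arm=200)
        serum, hc, _, truth = generate_serum_cohort(cfg)
        for analyte, offset in truth["disease_offset"].items():
            base = serum[(serum["analyte"] == analyte) & (serum["week"] == 0)]
            grp = np.log2(base["conc_pg_ml"]).mean()
            hc_mean = cfg.analyte_params[analyte].hc_mean_log2
            assert grp - hc_mean == pytest.approx(offset, abs=0.15)

    def test_no_offset_nominal_type_one_rate(self):
        """Zero disease offset: week-0 Welch test vs HC rejects at ~alpha.

        Monte-Carlo calibration over 500 replicate cohorts of one analyte.
        """
        from psopd.stats import welch_from_stats

        rejections = 0
        n_rep = 500
        for rep in range(n_rep):
            cfg = SimulationConfig(
                seed=1000 + rep, n_per_arm=15, n_hc=15,
                analyte_params={"X": AnalyteParams(0.0, 0.781, 0.0, {})},
                serum_subject_sd=0.6, serum_resid_sd=0.5,
            )
            serum, hc, _, _ = generate_serum_cohort(cfg)
            grp = np.log2(serum[(serum["week"] == 0) & (serum["arm"] == "A")]["conc_pg_ml"])
            ref = np.log2(hc["conc_pg_ml"])
            _, _, p = welch_from_stats(grp.mean(), grp.var(ddof=1), len(grp),
                                       ref.mean(), ref.var(ddof=1), len(ref))
            rejections += p < 0.05
        rate = rejections / n_rep
        mc_err = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * mc_err + 0.005

    def test_pasi_couples_to_analyte(self, serum_small):
        serum, hc, pasi, _ = serum_small
        x = serum[serum["analyte"] == "BD-2"].merge(pasi, on=["subject_id", "week"])
        r = np.corrcoef(np.log2(x["conc_pg_ml"]), x["pasi"])[0, 1]
        assert r > 0.3


class TestSkinGenerator:
    def test_meta_counts_one_to_one(self, skin_small):
        counts, meta, truth = skin_small
        assert list(meta["sample_id"]) == list(counts.columns)
        assert not meta.duplicated(subset=["subject_id", "week", "tissue"]).any()
        # nonlesional only at baseline
        assert (meta.loc[meta["tissue"] == "nonlesional", "week"] == 0).all()

    def test_truth_genes_subset_of_matrix(self, skin_small):
        counts, meta, truth = skin_small
        assert set(truth["disease_genes"]) <= set(counts.index)

    def test_nondisease_genes_same_in_both_tissues(self, skin_small):
        """Non-disease genes carry no per-gene lesional offset: their L-NL
        gap is a single compositional constant (library share absorbed by
        planted up-genes), identical across genes up to counting noise."""
        counts, meta, truth = skin_small
        disease = set(truth["disease_genes"])
        other = [g for g in counts.index if g not in disease][:200]
        log2 = np.log2(counts.loc[other] + 0.5)
        les = meta[(meta["tissue"] == "lesional") & (meta["week"] == 0)]["sample_id"]
        non = meta[meta["tissue"] == "nonlesional"]["sample_id"]
        gap = log2[list(les)].mean(axis=1) - log2[list(non)].mean(axis=1)
        assert (gap - gap.median()).abs().mean() < 0.2

    def test_disease_genes_offset_at_baseline(self, skin_small):
        counts, meta, truth = skin_small
        genes = truth["disease_genes"][:20]
        log2 = np.log2(counts.loc[genes] + 0.5)
        les = meta[(meta["tissue"] == "lesional") & (meta["week"] == 0)]["sample_id"]
        non = meta[meta["tissue"] == "nonlesional"]["sample_id"]
        gap = log2[list(les)].mean(axis=1) - log2[list(non)].mean(axis=1)
        signs_ok = sum(
            np.sign(gap[g]) == (1 if truth["direction"][g] == "up" else -1)
            for g in genes
        )
        assert signs_ok >= 18  # allow sampling noise on small offsets

    def test_negative_binomial_mean_variance(self):
        """Across-subject count marginals match NB(mean, dispersion): the
        median of (var - mean)/mean^2 over high-expression genes recovers
        the configured dispersion within 10%."""
        cfg = SimulationConfig(
            seed=31, n_per_arm=100, n_genes=10_000, n_disease_genes=0,
            skin_subject_sd=0.0, skin_severity_sd=0.0, lib_size_cv=0.0,
            skin_weeks=[0],
        )
        counts, meta, _ = generate_skin_cohort(cfg)
        nl = meta[meta["tissue"] == "nonlesional"]["sample_id"]
        x = counts[list(nl)].to_numpy(float)
        mean = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
        keep = mean > 50
        phi = np.median((var[keep] - mean[keep]) / mean[keep] ** 2)
        assert phi == pytest.approx(cfg.dispersion, rel=0.10)


class TestEstimatorConsistency:
    def test_serum_offset_error_shrinks_with_n(self):
        """The week-0 log2 offset estimate converges to the planted truth:
        the median absolute error over 20 replicates shrinks from n=8 to
        n=64 subjects per arm."""
        errs = {}
        for n in (8, 64):
            e = []
            for rep in range(20):
                cfg = SimulationConfig(seed=700 + rep, n_per_arm=n)
                serum, _, _, truth = generate_serum_cohort(cfg)
                base = serum[(serum["analyte"] == "IL-17F") & (serum["week"] == 0)]
                est = np.log2(base["conc_pg_ml"]).mean() - \
                    cfg.analyte_params["IL-17F"].hc_mean_log2
                e.append(abs(est - truth["disease_offset"]["IL-17F"]))
            errs[n] = np.median(e)
        assert errs[64] < errs[8]

    def test_improvement_estimate_concentrates_with_n(self):
        """Mean percent improvement concentrates on 100*norm_frac as the
        arm grows: the replicate-to-replicate spread shrinks from n=8 to
        n=64 and the bias stays within 3 percentage points (the estimator
        carries a small n-independent bias from the log of noisy counts
        and the compositional shift, so total error plateaus at the bias)."""
        from psopd import normalize_counts, percent_improvement

        errs = {}
        for n in (8, 64):
            e = []
            for rep in range(20):
                cfg = SimulationConfig(seed=800 + rep, n_per_arm=n,
                                       n_genes=200, n_disease_genes=30)
                counts, meta, truth = generate_skin_cohort(cfg)
                expr = normalize_counts(counts)
                # restrict to genes the transcriptome FC gate would admit;
                # near-zero offsets make the improvement ratio heavy-tailed
                genes = [g for g in truth["disease_genes"]
                         if abs(truth["offset"][g]) > 1.0]
                impr = percent_improvement(expr, meta, genes, "B", 4)
                planted = 100.0 * truth["improvement_frac"]["B"][4]
                e.append(impr["improvement_pct"].mean() - planted)
            errs[n] = e
        assert np.std(errs[64]) < np.std(errs[8])
        assert abs(np.mean(errs[64])) < 3.0


class TestGeneSets:
    def test_truth_only_when_no_decoys(self, skin_small):
        counts, meta, truth = skin_small
        coll = generate_gene_sets(truth, counts.index, n_decoy_sets=0,
                                  set_size_range=(5, 20), seed=1)
        assert set(coll.names()) == {"disease_up", "disease_down"}
        assert set(coll.sets["disease_up"]) == {
            g for g in truth["disease_genes"] if truth["direction"][g] == "up"}

    def test_decoy_size_capped_by_universe(self, skin_small):
        counts, meta, truth = skin_small
        with pytest.raises(ValueError, match="universe"):
            generate_gene_sets(truth, counts.index[:10], n_decoy_sets=1,
                               set_size_range=(5, 50), seed=1)
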