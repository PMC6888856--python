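"""Hierarchical-model layer: design assembly, AIC structure selection,
likelihood-ratio and Wald inference, percent back-transforms."""

import numpy as np
import pandas as pd
import pytest

from lagshift import models
from lagshift.binning import UC
from lagshift.glmm import GLMMFit
from lagshift.models import (FitResult, build_design, compare_attribute_models,
                             fit_glmm, fit_two_stage, lrt, percent_difference,
                             select_random_structure, wald_tests)


def _tables(rng, ns=8, k=10, effect=0.0, bins=("loss>50%",), sd_study=0.3,
            sd_block=0.0, mean_rich=20.0):
    """Simulated measures/attributes/sites with known per-bin log effects."""
    rows_m, rows_a, rows_s = [], [], []
    for s in range(ns):
        b_s = rng.normal(0, sd_study)
        block_eff = {j: rng.normal(0, sd_block) if sd_block > 0 else 0.0
                     for j in range(3)}
        for i in range(k):
            sid = f"s{s}_{i}"
            block = f"b{s}_{i % 3}"
            binlab = UC if i % 2 == 0 else bins[i % len(bins)]
            eta = np.log(mean_rich) + b_s + block_eff[i % 3] + \
                (effect if binlab != UC else 0.0)
            rich = rng.poisson(np.exp(eta))
            rows_m.append({"site_id": sid, "richness": rich,
                           "log_abund": np.log10(1 + rng.poisson(np.exp(eta))),
                           "pie_asin": float(np.clip(
                               rng.normal(0.9, 0.1), 0, np.pi / 2))})
            rows_a.append({"site_id": sid, "magnitude_bin": binlab,
                           "trend_bin": binlab if binlab == UC else
                           "lower <=0.01", "time_bin": binlab if binlab == UC
                           else "<5y"})
            rows_s.append({"site_id": sid, "study_id": f"st{s}",
                           "block_id": block, "land_use": "PV",
                           "climate_zone": "temperate"})
    return (pd.DataFrame(rows_m), pd.DataFrame(rows_a), pd.DataFrame(rows_s))


class TestBuildDesign:
    def test_uc_only_studies_dropped(self, rng):
        m, a, s = _tables(rng, ns=4)
        only_uc = s["study_id"] == "st0"
        a.loc[a["site_id"].isin(s.loc[only_uc, "site_id"]),
              ["magnitude_bin", "trend_bin", "time_bin"]] = UC
        data = build_design(m, a, s, "magnitude")
        assert "st0" not in set(data.df["study_id"])
        assert {"st1", "st2", "st3"} <= set(data.df["study_id"])

    def test_presence_design_single_effect(self, rng):
        data = build_design(*_tables(rng), "presence")
        assert data.bin_levels == ["changed"]

    def test_reference_level_present(self, rng):
        data = build_design(*_tables(rng), "magnitude")
        assert (data.df["bin"] == UC).any()
        assert UC not in data.bin_levels

    def test_all_unchanged_rejected(self, rng):
        m, a, s = _tables(rng)
        a[["magnitude_bin", "trend_bin", "time_bin"]] = UC
        with pytest.raises(ValueError, match="changed site"):
            build_design(m, a, s, "magnitude")


class TestFitAndInference:
    def test_known_log_ratio_recovered(self, rng):
        m, a, s = _tables(rng, ns=20, k=14, effect=np.log(0.8))
        data = build_design(m, a, s, "magnitude")
        fit = fit_glmm(data, "richness", structure=("study",))
        est = fit.coef_series()["loss>50%"]
        assert est == pytest.approx(np.log(0.8), abs=3 * fit.se_series()["loss>50%"])

    def test_lrt_identical_models(self, rng):
        data = build_design(*_tables(rng), "presence")
        full = fit_glmm(data, "richness", structure=("study",))
        chi2, df, p = lrt(full, full)
        assert chi2 == 0.0 and df == 0 and p == 1.0
        null = fit_glmm(data, "richness", structure=("study",),
                        null_model=True)
        chi2, df, p = lrt(full, null)
        assert df == 1 and chi2 >= 0

    def test_lrt_df_equals_bin_count(self, rng):
        m, a, s = _tables(rng, ns=12, k=12,
                          bins=("loss>50%", "loss 25-50%", "gain <=25%"))
        data = build_design(m, a, s, "magnitude")
        full = fit_glmm(data, "richness", structure=("study",))
        null = fit_glmm(data, "richness", structure=("study",),
                        null_model=True)
        chi2, df, p = lrt(full, null)
        assert df == len(data.bin_levels) == 3
        assert 0 <= p <= 1

    def test_lrt_row_mismatch_rejected(self, rng):
        m, a, s = _tables(rng)
        d1 = build_design(m, a, s, "presence")
        d2 = build_design(m.iloc[:-4], a, s, "presence")
        f1 = fit_glmm(d1, "richness", structure=("study",))
        f2 = fit_glmm(d2, "richness", structure=("study",), null_model=True)
        with pytest.raises(ValueError, match="different rows"):
            lrt(f1, f2)

    def test_null_lrt_calibration(self, rng):
        """Simulation oracle: under no effect the LRT p-values are roughly
        uniform, so rejections at 5% stay near nominal."""
        rej = 0
        n_rep = 60
        for i in range(n_rep):
            r = np.random.default_rng(1000 + i)
            m, a, s = _tables(r, ns=8, k=8, effect=0.0)
            data = build_design(m, a, s, "presence")
            full = fit_glmm(data, "abundance", structure=("study",))
            null = fit_glmm(data, "abundance", structure=("study",),
                            null_model=True)
            _, _, p = lrt(full, null)
            rej += p < 0.05
        assert rej / n_rep <= 0.12

    def test_wald_examples(self):
        gf = GLMMFit(family="poisson", coef=np.array([1.0, 0.0, 0.0392]),
                     se=np.array([0.1, 0.1, 0.02]),
                     coef_names=["(Intercept)", "b1", "b2"], vcomp={},
                     resid_sd=None, loglik=-10.0, n_params=4, n_obs=50,
                     converged=True)
        fit = FitResult(gf, "richness", "magnitude", ["b1", "b2"], ("study",))
        w = wald_tests(fit).set_index("bin")
        assert w.loc["b1", "z"] == 0.0 and w.loc["b1", "p"] == 1.0
        assert w.loc["b2", "p"] == pytest.approx(0.05, abs=0.002)  # z = 1.96


class TestPercentDifference:
    def _fit(self, family, response, coef, se, intercept=1.0):
        gf = GLMMFit(family=family, coef=np.array([intercept, coef]),
                     se=np.array([0.1, se]),
                     coef_names=["(Intercept)", "bin1"], vcomp={},
                     resid_sd=None, loglik=0.0, n_params=3, n_obs=10,
                     converged=True)
        return FitResult(gf, response, "magnitude", ["bin1"], ("study",))

    def test_zero_effect_zero_percent(self):
        pct, _ = percent_difference(self._fit("poisson", "richness", 0.0, 0.1), "bin1")
        assert pct == 0.0

    def test_canonical_richness_backtransform(self):
        pct, _ = percent_difference(
            self._fit("poisson", "richness", np.log(0.958), 0.01), "bin1")
        assert pct == pytest.approx(-4.2, abs=1e-10)

    def test_delta_method_log_link(self):
        pct, pct_se = percent_difference(
            self._fit("poisson", "richness", -0.1, 0.02), "bin1")
        assert pct == pytest.approx(100 * (np.exp(-0.1) - 1), abs=1e-9)
        assert pct == pytest.approx(-9.52, abs=0.01)
        assert pct_se == pytest.approx(100 * np.exp(-0.1) * 0.02, abs=1e-9)
        assert pct_se == pytest.approx(1.81, abs=0.01)

    def test_log10_abundance_backtransform(self):
        pct, _ = percent_difference(
            self._fit("gaussian", "abundance", np.log10(0.9), 0.01), "bin1")
        assert pct == pytest.approx(-10.0, abs=1e-9)

    def test_pie_backtransform_is_relative_change_of_pie(self):
        m0, b = 0.9, -0.05
        pct, _ = percent_difference(
            self._fit("gaussian", "pie", b, 0.01, intercept=m0), "bin1")
        v0, v1 = np.sin(m0) ** 2, np.sin(m0 + b) ** 2
        assert pct == pytest.approx(100 * (v1 - v0) / v0, abs=1e-9)


class TestModelComparison:
    def _fit_with(self, coefs, aic):
        gf = GLMMFit(family="poisson",
                     coef=np.array([1.0] + list(coefs)),
                     se=np.ones(len(coefs) + 1),
                     coef_names=["(Intercept)"] + [f"b{i}" for i in
                                                   range(len(coefs))],
                     vcomp={}, resid_sd=None, loglik=-aic / 2,
                     n_params=0, n_obs=10, converged=True)
        return FitResult(gf, "richness", "magnitude",
                         [f"b{i}" for i in range(len(coefs))], ("study",))

    def test_identical_models(self):
        f = self._fit_with([0.1, -0.2, 0.3], 100.0)
        d, r = compare_attribute_models(f, f)
        assert d == 0.0 and r == 1.0

    def test_sign_flip_gives_minus_one(self):
        f1 = self._fit_with([0.1, -0.2, 0.3], 100.0)
        f2 = self._fit_with([-0.1, 0.2, -0.3], 90.0)
        d, r = compare_attribute_models(f1, f2)
        assert r == -1.0 and d == pytest.approx(10.0)

    def test_bin_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            compare_attribute_models(self._fit_with([0.1], 10),
                                     self._fit_with([0.1, 0.2], 10))


class TestStructureSelection:
    def test_single_candidate_returned_unchanged(self, rng):
        data = build_design(*_tables(rng), "presence")
        assert select_random_structure(
            data, "richness", candidates=[("study", "block")]) == \
            ("study", "block")

    def test_strong_block_variance_selects_block(self):
        """Simulation oracle: with large block variance the AIC ranking
        includes the block intercept almost always."""
        hits = 0
        for i in range(8):
            r = np.random.default_rng(3000 + i)
            m, a, s = _tables(r, ns=10, k=12, sd_block=0.8, sd_study=0.2)
            data = build_design(m, a, s, "presence")
            st = select_random_structure(
                data, "richness",
                candidates=[("study",), ("study", "block")])
            hits += "block" in st
        assert hits >= 7

    def test_tiny_data_zero_variance_prefers_simplest(self):
        r = np.random.default_rng(99)
        m, a, s = _tables(r, ns=4, k=6, sd_study=0.0)
        data = build_design(m, a, s, "presence")
        st = select_random_structure(
            data, "abundance", candidates=[("study",), ("study", "block"),
                                           ("study", "block", "land_use")])
        assert st == ("study",)


def test_two_stage_agrees_with_glmm_direction(rng):
    m, a, s = _tables(rng, ns=16, k=14, effect=np.log(0.8))
    data = build_design(m, a, s, "magnitude")
    ts = fit_two_stage(data, "richness").set_index("bin")
    assert ts.loc["loss>50%", "coef"] == pytest.approx(np.log(0.8), abs=0.15)


def test_climate_zone_from_latitude():
    assert models.climate_zone_from_latitude(-10) == "tropical"
    assert models.climate_zone_from_latitude(30) == "arid"
    assert models.climate_zone_from_latitude(45) == "temperate"
    assert models.climate_zone_from_latitude(60) == "continental"
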