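"""Generator contracts: determinism, truth alignment, injected effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lagshift import synthetic
from lagshift.binning import UC
from lagshift.config import BinEffect, SimulationConfig
from lagshift.diversity import sorensen
from lagshift.months import index_to_ym, ym_to_index


def test_month_roundtrip_examples():
    assert ym_to_index("1982-01") == 0
    assert ym_to_index("1999-01") == 204
    assert index_to_ym(204) == "1999-01"


@given(st.integers(min_value=-120, max_value=800))
def test_month_roundtrip_property(idx):
    assert ym_to_index(index_to_ym(idx)) == idx


class TestLandscape:
    def test_no_changed_sites_when_prop_zero(self):
        cfg = SimulationConfig(n_studies=2, sites_per_study=3,
                               prop_changed_sites=0.0, seed=1)
        _, truth = synthetic.simulate_landscape(cfg)
        assert not truth["has_break"].any()
        assert (truth["true_effect_bin"] == UC).all()

    def test_study_count_matches_request(self):
        cfg = SimulationConfig(n_studies=377, sites_per_study=2, seed=3)
        sites, _ = synthetic.simulate_landscape(cfg)
        assert sites["study_id"].nunique() == 377

    def test_same_seed_identical_tables(self, tiny_config):
        s1, t1 = synthetic.simulate_landscape(tiny_config)
        s2, t2 = synthetic.simulate_landscape(tiny_config)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_truth_aligned_one_to_one(self, tiny_landscape):
        sites, truth = tiny_landscape["sites"], tiny_landscape["truth"]
        assert sorted(sites["site_id"]) == sorted(truth["site_id"])
        assert truth["site_id"].is_unique

    def test_each_study_keeps_an_unchanged_reference(self):
        cfg = SimulationConfig(n_studies=5, sites_per_study=4,
                               prop_changed_sites=1.0, seed=9)
        sites, truth = synthetic.simulate_landscape(cfg)
        merged = sites.merge(truth, on="site_id")
        per_study = merged.groupby("study_id")["has_break"].agg(["sum", "count"])
        assert (per_study["sum"] < per_study["count"]).all()

    def test_unchanged_rows_have_neutral_truth(self, tiny_landscape):
        truth = tiny_landscape["truth"]
        uc = truth.loc[~truth["has_break"]]
        assert (uc["richness_multiplier"] == 1).all()
        assert (uc["turnover_fraction"] == 0).all()
        assert uc["true_magnitude"].isna().all()

    def test_invalid_config_names_field(self):
        cfg = SimulationConfig(prop_changed_sites=1.7)
        with pytest.raises(ValueError, match="prop_changed_sites"):
            cfg.validate()
        cfg = SimulationConfig(magnitude_range=(0.5, -0.5))
        with pytest.raises(ValueError, match="magnitude_range"):
            cfg.validate()

    def test_yaml_roundtrip(self, tiny_config, tmp_path):
        p = tmp_path / "cfg.yaml"
        tiny_config.to_yaml(p)
        back = SimulationConfig.from_yaml(p)
        assert back == tiny_config


class TestEviObservations:
    def _truth(self, **kw):
        base = {"site_id": "X", "has_break": False, "true_break_month": None,
                "true_magnitude": np.nan, "true_trend_diff": np.nan}
        base.update(kw)
        return base

    def test_no_break_series_has_flat_trend(self):
        cfg = SimulationConfig(base_trend_range=(0.0, 0.0), seed=5)
        obs = synthetic.simulate_evi_observations(self._truth(), cfg, 0)
        from lagshift.preprocess import compute_evi2
        evi = compute_evi2(obs["nir"].clip(0, 1), obs["red"])
        t = obs["date"].str.slice(0, 7).map(ym_to_index).to_numpy(float)
        X = np.column_stack([np.ones_like(t), t - t.mean()])
        coef, res, *_ = np.linalg.lstsq(X, evi, rcond=None)
        sigma2 = float(res[0]) / (len(t) - 2)
        se = np.sqrt(sigma2 / np.sum((t - t.mean()) ** 2))
        assert abs(coef[1]) < 2 * se + 1e-4

    def test_noiseless_composite_equals_analytic_signal(self):
        cfg = SimulationConfig(noise_sd=0.0, outlier_rate=0.0,
                               cloud_fraction=0.0, missing_block_rate=0.0,
                               seed=2)
        tr = self._truth(has_break=True, true_break_month="2006-06",
                         true_magnitude=-0.4, true_trend_diff=0.001)
        obs = synthetic.simulate_evi_observations(tr, cfg, 0)
        from lagshift.preprocess import preprocess_site
        t0, t1 = ym_to_index(cfg.series_start), ym_to_index(cfg.series_end)
        ser = preprocess_site(obs, start=t0, end=t1)
        # reconstruct the analytic signal from the generator's own substream
        rng = np.random.default_rng([cfg.seed, 2, 0])
        base = rng.uniform(*cfg.baseline_evi_range)
        btr = rng.uniform(*cfg.base_trend_range)
        ph1, ph2 = rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)
        sig = synthetic.evi_signal(ser.months, base, btr,
                                   cfg.seasonal_amplitude, ph1, ph2,
                                   break_month=ym_to_index(tr["true_break_month"]),
                                   magnitude=-0.4, trend_diff=0.001, t0=t0)
        ok = ~np.isnan(ser.values)
        assert ok.sum() > 150
        np.testing.assert_allclose(ser.values[ok], sig[ok], atol=5e-9)

    def test_break_outside_span_rejected(self, tiny_config):
        tr = self._truth(has_break=True, true_break_month="1995-01",
                         true_magnitude=-0.3, true_trend_diff=0.0)
        with pytest.raises(ValueError, match="outside the series span"):
            synthetic.simulate_evi_observations(tr, tiny_config, 0)

    def test_negative_magnitude_halves_post_break_level(self):
        """Monte-Carlo oracle: a -0.5 magnitude step halves the de-seasonalized
        post-break level relative to the pre-break level (12-month window
        means cancel the annual harmonics exactly)."""
        cfg = SimulationConfig(base_trend_range=(0.0, 0.0),
                               missing_block_rate=0.0, cloud_fraction=0.0,
                               outlier_rate=0.0)
        tb = "2007-01"
        ratios = []
        for i in range(40):
            c = SimulationConfig.from_dict({**cfg.to_dict(), "seed": 100 + i})
            tr = self._truth(has_break=True, true_break_month=tb,
                             true_magnitude=-0.5, true_trend_diff=0.0)
            obs = synthetic.simulate_evi_observations(tr, c, 0)
            from lagshift.preprocess import compute_evi2
            evi = compute_evi2(obs["nir"].clip(0, 1), obs["red"])
            t = obs["date"].str.slice(0, 7).map(ym_to_index).to_numpy()
            tbi = ym_to_index(tb)
            pre = evi[(t >= tbi - 12) & (t < tbi)].mean()
            post = evi[(t >= tbi) & (t < tbi + 12)].mean()
            ratios.append(post / pre)
        assert abs(np.mean(ratios) - 0.5) < 0.03


class TestAssemblages:
    def test_null_effects_exchangeable(self):
        cfg = SimulationConfig(seed=7)
        site = {"site_id": "s", "study_index": 0, "effort": 1.0}
        null = {"richness_multiplier": 1.0, "abundance_multiplier": 1.0,
                "evenness_shift": 0.0, "turnover_fraction": 0.0}
        rich = [len(synthetic.simulate_assemblage(site, null, cfg, i))
                for i in range(400)]
        rich2 = [len(synthetic.simulate_assemblage(site, null, cfg, 10_000 + i))
                 for i in range(400)]
        diff = np.mean(rich) - np.mean(rich2)
        pooled_se = np.sqrt(np.var(rich) / 400 + np.var(rich2) / 400)
        assert abs(diff) < 3 * pooled_se + 0.5

    def test_richness_multiplier_recovered(self):
        """Monte-Carlo oracle: occupancy thinning makes the expected richness
        exactly multiplicative, so the grand ratio lands near 0.9."""
        cfg = SimulationConfig(seed=8)
        site = {"site_id": "s", "study_index": 0, "effort": 1.0}
        base = {"richness_multiplier": 1.0, "abundance_multiplier": 1.0,
                "evenness_shift": 0.0, "turnover_fraction": 0.0}
        down = dict(base, richness_multiplier=0.9, abundance_multiplier=0.9)
        r1 = np.mean([len(synthetic.simulate_assemblage(site, base, cfg, i))
                      for i in range(1000)])
        r2 = np.mean([len(synthetic.simulate_assemblage(site, down, cfg,
                                                        50_000 + i))
                      for i in range(1000)])
        assert 0.88 <= r2 / r1 <= 0.92

    def test_full_turnover_matches_independent_draw_overlap(self):
        """Combinatorial oracle: with turnover 1 the expected Sørensen between
        a turned-over and a baseline site equals that of two independent
        random subsets of the pool (simulated here)."""
        cfg = SimulationConfig(seed=9, species_pool_size=80)
        site = {"site_id": "s", "study_index": 0, "effort": 1.0}
        base = {"richness_multiplier": 1.0, "abundance_multiplier": 1.0,
                "evenness_shift": 0.0, "turnover_fraction": 0.0}
        turned = dict(base, turnover_fraction=1.0)
        sims = []
        for i in range(300):
            a = synthetic.simulate_assemblage(site, base, cfg, i)
            b = synthetic.simulate_assemblage(site, turned, cfg, 90_000 + i)
            sims.append(sorensen(a["species_id"], b["species_id"]))
        # oracle: one abundance-weighted occupancy draw versus a fully
        # swapped draw (every present species replaced by a random absent
        # one), simulated independently of the generator's code path
        rng = np.random.default_rng(123)
        _, lam = synthetic.study_species_pool(cfg, 0)
        p = np.clip(cfg.occupancy * lam / lam.mean(), 0.0, 0.95)
        oracle = []
        for _ in range(300):
            sa = rng.random(80) < p
            sb = rng.random(80) < p
            ib = np.flatnonzero(sb)
            absent = np.flatnonzero(~sb)
            take = min(ib.size, absent.size)
            swapped = rng.choice(absent, size=take, replace=False)
            both = len(set(np.flatnonzero(sa)) & set(swapped))
            denom = len(set(np.flatnonzero(sa))) + take
            if denom:
                oracle.append(2 * both / denom)
        assert abs(np.mean(sims) - np.mean(oracle)) < 0.05

    def test_empty_pool_rejected(self):
        cfg = SimulationConfig(seed=1)
        cfg.species_pool_size = 0
        with pytest.raises(ValueError, match="pool"):
            synthetic.simulate_assemblage(
                {"site_id": "s", "study_index": 0, "effort": 1.0},
                {"richness_multiplier": 1.0, "abundance_multiplier": 1.0,
                 "evenness_shift": 0.0, "turnover_fraction": 0.0}, cfg, 0)


def test_simulate_all_is_deterministic(tiny_config, tiny_landscape):
    again = synthetic.simulate_all(tiny_config)
    for name, df in tiny_landscape.items():
        pd.testing.assert_frame_equal(df, again[name])
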