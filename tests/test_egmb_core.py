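"""SRT arithmetic and the steady-state growth-rate estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egmb import (
    GrowthStatus,
    OtuTable,
    ReactorConfig,
    assess_steady_state,
    compute_growth_rate,
    compute_growth_table,
    compute_srt,
    expI_config,
    expII_configs,
    to_relative_abundance,
)
from egmb.egmb_core import load_reactor_config, save_reactor_config, write_growth_table


class TestSrt:
    @pytest.mark.parametrize(
        "vc,vol,interval,srt",
        [
            (150, 3, 2, 100.0),       # experiment-I control schedule
            (150, 8, 2, 37.5),        # experiment-II gentlest schedule
            (150, 32, 0.5, 2.34375),  # experiment-II most aggressive schedule
            (150, 12, 1, 12.5),
            (200, 200, 1, 1.0),       # full exchange every day
        ],
    )
    def test_schedule_arithmetic(self, vc, vol, interval, srt):
        assert compute_srt(ReactorConfig(vc, vol, interval)) == pytest.approx(srt)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReactorConfig(0, 3, 2)
        with pytest.raises(ValueError):
            ReactorConfig(150, 151, 2)  # exchange volume > working volume
        with pytest.raises(ValueError):
            ReactorConfig(150, 3, 0)

    def test_presets(self):
        assert compute_srt(expI_config()) == pytest.approx(100.0)
        srts = sorted(compute_srt(c) for c in expII_configs().values())
        assert srts == pytest.approx([2.34375, 12.5, 37.5])
        assert round(srts[0], 1) == 2.3


class TestGrowthRateEstimator:
    def test_absent_from_feed_hits_dilution_ceiling(self, expI_cfg):
        rec = compute_growth_rate(0.004, 0.0, expI_cfg)
        assert rec.status is GrowthStatus.ESTIMATED
        assert rec.mu_per_d == pytest.approx(0.01, abs=0)  # exactly 1/SRT

    def test_balanced_influx_gives_zero(self, expI_cfg):
        # Qf*Cf*p_feed == Vc*Cc*p_reactor / SRT  =>  mu == 0
        srt = compute_srt(expI_cfg)
        p_reactor = 0.02
        p_feed = expI_cfg.vc_ml * expI_cfg.cc_g_per_l * p_reactor / (
            srt * expI_cfg.q_ml_per_d * expI_cfg.cf_g_per_l
        )
        rec = compute_growth_rate(p_reactor, p_feed, expI_cfg)
        assert rec.mu_per_d == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_example(self, expI_cfg):
        # 0.01 - (1.5*6.2*0.05)/(150*10*0.01) = -0.021 /d
        rec = compute_growth_rate(0.01, 0.05, expI_cfg)
        assert rec.mu_per_d == pytest.approx(-0.021, abs=1e-12)

    def test_washed_out_and_absent_statuses(self, expI_cfg):
        rec = compute_growth_rate(0.0, 0.02, expI_cfg)
        assert rec.status is GrowthStatus.WASHED_OUT and rec.mu_per_d is None
        rec = compute_growth_rate(0.0, 0.0, expI_cfg)
        assert rec.status is GrowthStatus.ABSENT_EVERYWHERE and rec.mu_per_d is None

    def test_zero_reactor_vss_is_config_error(self):
        cfg = ReactorConfig(150, 3, 2, cf_g_per_l=6.2, cc_g_per_l=0.0)
        with pytest.raises(ValueError, match="cc_g_per_l"):
            compute_growth_rate(0.01, 0.05, cfg)

    @given(
        p_reactor=st.floats(1e-6, 1.0),
        p_feed=st.one_of(st.just(0.0), st.floats(1e-9, 1.0)),
    )
    @settings(max_examples=200, deadline=None)
    def test_ceiling_with_equality_iff_no_feed(self, p_reactor, p_feed):
        cfg = ReactorConfig(150, 3, 2, cf_g_per_l=6.2, cc_g_per_l=10.0)
        mu = compute_growth_rate(p_reactor, p_feed, cfg).mu_per_d
        ceiling = 1.0 / compute_srt(cfg)
        if p_feed == 0.0:
            assert mu == ceiling
        else:
            assert mu < ceiling

    def test_monotone_in_abundances(self, expI_cfg):
        base = compute_growth_rate(0.01, 0.05, expI_cfg).mu_per_d
        assert compute_growth_rate(0.01, 0.06, expI_cfg).mu_per_d < base
        assert compute_growth_rate(0.02, 0.05, expI_cfg).mu_per_d > base

    def test_scale_invariance(self, expI_cfg):
        # multiplying Cf*Qf and Cc*Vc by a common factor leaves mu unchanged
        import dataclasses
        scaled = dataclasses.replace(
            expI_cfg, cf_g_per_l=expI_cfg.cf_g_per_l * 3.7, cc_g_per_l=expI_cfg.cc_g_per_l * 3.7
        )
        a = compute_growth_rate(0.013, 0.041, expI_cfg).mu_per_d
        b = compute_growth_rate(0.013, 0.041, scaled).mu_per_d
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("d", [0.01, 0.08, 0.4267])
    @pytest.mark.parametrize("mu_true", [-0.5, -0.05, 0.0, 0.005])
    def test_continuous_culture_identity(self, d, mu_true):
        """At the continuous steady state N* = F/(D - mu), the estimator
        recovers mu exactly (algebraic identity)."""
        if mu_true >= d:
            pytest.skip("unbounded steady state")
        vc, cc, cf = 150.0, 8.0, 6.2
        srt = 1.0 / d
        cfg = ReactorConfig(vc, vc / srt, 1.0, cf_g_per_l=cf, cc_g_per_l=cc)
        p_feed = 0.03
        influx = cfg.q_ml_per_d * cf * p_feed  # mg/d
        n_star = influx / (d - mu_true)  # mg
        p_reactor = n_star / (vc * cc)
        rec = compute_growth_rate(p_reactor, p_feed, cfg)
        assert rec.mu_per_d == pytest.approx(mu_true, abs=1e-12)


class TestGrowthTable:
    def test_matches_elementwise_calls(self, expI_cfg):
        reactor = {"a": 0.4, "b": 0.1, "c": 0.0}
        feed = {"a": 0.2, "c": 0.05, "d": 0.0}
        records = {r.otu_id: r for r in compute_growth_table(reactor, feed, expI_cfg)}
        assert set(records) == {"a", "b", "c", "d"}
        for otu in records:
            single = compute_growth_rate(reactor.get(otu, 0.0), feed.get(otu, 0.0), expI_cfg)
            assert records[otu].mu_per_d == single.mu_per_d
            assert records[otu].status == single.status

    def test_feed_all_zero_gives_ceiling_everywhere(self, expI_cfg):
        srt = compute_srt(expI_cfg)
        records = compute_growth_table({"a": 0.3, "b": 0.7}, {}, expI_cfg)
        assert all(r.mu_per_d == pytest.approx(1 / srt, abs=0) for r in records)

    def test_feed_only_otu_is_washed_out(self, expI_cfg):
        records = compute_growth_table({"a": 1.0}, {"ghost": 0.4, "a": 0.6}, expI_cfg)
        by_id = {r.otu_id: r for r in records}
        assert by_id["ghost"].status is GrowthStatus.WASHED_OUT

    def test_table_inputs_carry_taxonomy(self, small_rel, expI_cfg):
        records = compute_growth_table(
            small_rel, small_rel, expI_cfg, reactor_sample="s1", feed_sample="s2"
        )
        by_id = {r.otu_id: r for r in records}
        assert "Parabacteroides" in by_id["OTU1"].taxonomy

    def test_write_growth_table(self, expI_cfg, tmp_path):
        records = compute_growth_table({"a": 0.3}, {"a": 0.1, "b": 0.2}, expI_cfg)
        out = tmp_path / "growth.tsv"
        write_growth_table(records, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("otu_id\ttaxonomy")
        assert len(lines) == 3
        assert "washed_out" in lines[2]


class TestSteadyStateAssessment:
    def _series(self, rows):
        rows = np.asarray(rows, dtype=float)
        counts = (rows * 100_000).round().astype(int)
        # pad a filler OTU so columns are normalizable
        filler = (100_000 - counts.sum(axis=0))[None, :]
        t = OtuTable(
            tuple(f"o{i}" for i in range(rows.shape[0])) + ("filler",),
            ("",) * (rows.shape[0] + 1),
            np.vstack([counts, filler]),
            tuple(f"d{j}" for j in range(rows.shape[1])),
        )
        return to_relative_abundance(t)

    def test_constant_series_not_flagged(self):
        flags = assess_steady_state(self._series([[0.2, 0.2, 0.2, 0.2]]))
        assert flags["o0"] is False

    def test_doubling_series_flagged(self):
        # p doubling each day: CV(1,2,4,8) = sd/mean = 3.096/3.75 = 0.83 > 0.3
        flags = assess_steady_state(self._series([[0.01, 0.02, 0.04, 0.08]]))
        assert flags["o0"] is True

    def test_all_zero_series_is_stable_absent(self):
        flags = assess_steady_state(self._series([[0.0, 0.0, 0.0]]))
        assert flags["o0"] is False

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            assess_steady_state(self._series([[0.5, 0.5]]))


def test_reactor_config_yaml_round_trip(tmp_path, expI_cfg):
    path = tmp_path / "cfg.yml"
    save_reactor_config(expI_cfg, path)
    assert load_reactor_config(path) == expI_cfg
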