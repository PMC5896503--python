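import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coccotopo as ct
from coccotopo.morphometry import normality_diagnostic


class TestRecordInvariants:
    def test_valid_records_accepted(self):
        ct.CoccolithMorphometry(3.04, 2.45, 0.57)
        ct.CoccolithMorphometry(3.0, 2.4)  # OSW optional
        ct.ProtoCoccolith(1.86, 1.37)
        ct.CoccosphereRecord(5.54, visible_interlocked_count=8, total_count=16)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(dsl=3.0, dsw=3.5),  # DSW exceeds DSL
            dict(dsl=3.0, dsw=2.4, osw=1.3),  # OSW >= DSW/2: degenerate central area
            dict(dsl=-1.0, dsw=0.5),
        ],
    )
    def test_invalid_coccoliths_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ct.CoccolithMorphometry(**kwargs)

    def test_counting_rule_enforced(self):
        with pytest.raises(ValueError):
            ct.CoccosphereRecord(5.0, visible_interlocked_count=8, total_count=15)
        assert ct.CoccosphereRecord(5.0, visible_interlocked_count=8).count == 16


class TestSummarize:
    def test_identical_records(self):
        s = ct.summarize([ct.CoccolithMorphometry(3.0, 2.4)] * 2)
        assert s["dsl"]["mean"] == pytest.approx(3.0)
        assert s["dsw"]["mean"] == pytest.approx(2.4)
        assert s["dsl"]["sd"] == 0.0

    def test_two_point_sample_uses_sample_sd(self):
        s = ct.summarize([ct.CoccolithMorphometry(2.0, 1.9), ct.CoccolithMorphometry(4.0, 3.8)])
        assert s["dsl"]["mean"] == pytest.approx(3.0)
        assert s["dsl"]["sd"] == pytest.approx(math.sqrt(2))

    def test_recovers_generator_mean_at_large_n(self, large_coccolith_table, default_params):
        s = ct.summarize(large_coccolith_table)
        n = s["dsl"]["n"]
        sigma = default_params.dsl.truncated_sd
        mu_trunc = float(default_params.dsl.frozen().mean())  # asymmetric range shifts the mean slightly
        assert abs(s["dsl"]["mean"] - mu_trunc) < 4 * sigma / math.sqrt(n)
        assert s["dsl"]["mean"] == pytest.approx(3.04, abs=0.01)
        assert s["dsl"]["sd"] == pytest.approx(sigma, rel=0.05)
        # ratio columns are derived and summarised too
        assert s["osw/dsl"]["mean"] == pytest.approx(0.19, abs=0.005)

    def test_percentiles_nondecreasing(self, large_coccolith_table):
        s = ct.summarize(large_coccolith_table, percentiles=(0.05, 0.5, 0.95))
        row = s["dsl"]
        assert row["p5"] <= row["p50"] <= row["p95"]
        assert row["min"] <= row["mean"] <= row["max"]

    def test_rows_missing_osw_keep_dsl_statistics(self):
        df = pd.DataFrame({"dsl": [3.0, 3.2, 2.8], "dsw": [2.4, 2.6, 2.2], "osw": [0.5, np.nan, np.nan]})
        s = ct.summarize(df)
        assert s["dsl"]["n"] == 3
        assert "osw" not in s.table.index  # a single OSW value cannot be summarised

    def test_errors(self):
        with pytest.raises(ValueError):
            ct.summarize([ct.CoccolithMorphometry(3.0, 2.4)])
        bad = pd.DataFrame({"dsl": [3.0, np.inf], "dsw": [2.4, 2.4]})
        with pytest.raises(ValueError, match="row index 1"):
            ct.summarize(bad)


class TestCentralArea:
    def test_published_population_means(self):
        length, width = ct.central_area_dimensions(ct.CoccolithMorphometry(3.04, 2.45, 0.57))
        assert length == pytest.approx(1.90)
        assert width == pytest.approx(1.31)

    def test_plain_arithmetic(self):
        assert ct.central_area_dimensions(ct.CoccolithMorphometry(2.0, 1.6, 0.5)) == pytest.approx((1.0, 0.6))

    def test_vanishing_shield_width_limit(self):
        length, width = ct.central_area_dimensions(ct.CoccolithMorphometry(3.0, 2.4, 1e-9))
        assert (length, width) == pytest.approx((3.0, 2.4))

    def test_missing_osw_is_an_error(self):
        with pytest.raises(ValueError, match="OSW"):
            ct.central_area_dimensions(ct.CoccolithMorphometry(3.0, 2.4))

    def test_population_central_area_falls_in_proto_ring_range(self, large_coccolith_table):
        lengths = large_coccolith_table["dsl"] - 2 * large_coccolith_table["osw"]
        assert 1.45 < lengths.mean() < 2.38  # measured proto-coccolith length range


class TestNormalTail:
    def test_standard_normal_value(self):
        assert ct.normal_tail_probability(0, 1, 1, "upper") == pytest.approx(0.15865525393145707, abs=1e-12)

    def test_symmetry_at_mean(self):
        assert ct.normal_tail_probability(0.19, 0.02, 0.19, "upper") == pytest.approx(0.5)

    def test_far_tail_keeps_accuracy(self):
        p = ct.normal_tail_probability(0.19, 0.02, 0.37, "upper")
        assert 0 < p < 1e-15

    @given(mu=st.floats(-5, 5), sd=st.floats(0.01, 3), t=st.floats(-10, 10))
    @settings(max_examples=60, deadline=None)
    def test_tails_sum_to_one(self, mu, sd, t):
        up = ct.normal_tail_probability(mu, sd, t, "upper")
        lo = ct.normal_tail_probability(mu, sd, t, "lower")
        assert up + lo == pytest.approx(1.0, abs=1e-12)

    def test_invalid_sd(self):
        with pytest.raises(ValueError):
            ct.normal_tail_probability(0, 0, 1)


class TestRatioBandProbability:
    def test_certain_event(self):
        for interp in ("fixed_central", "shared_central", "independent_ratio"):
            r = ct.ratio_band_probability(3.04, 0.40, (1e-9, 1e4), 5, interp, mc_samples=10_000, seed=0)
            assert r.analytic == pytest.approx(1.0, abs=1e-6)

    def test_fixed_central_closed_form(self):
        from scipy.stats import norm

        r = ct.ratio_band_probability(3.04, 0.40, (0.75, 0.8), 7, "fixed_central", seed=1)
        q = norm.cdf(0.8 * 3.04, 3.04, 0.40) - norm.cdf(0.75 * 3.04, 3.04, 0.40)
        assert r.analytic == pytest.approx(q**7, rel=1e-12)
        assert abs(r.monte_carlo - r.analytic) < 4 * r.mc_standard_error

    def test_monotone_in_k_and_band_width(self):
        for interp in ("fixed_central", "shared_central", "independent_ratio"):
            probs_k = [
                ct.ratio_band_probability(3.04, 0.40, (0.75, 0.8), k, interp, seed=2).analytic
                for k in (1, 3, 7)
            ]
            assert probs_k[0] >= probs_k[1] >= probs_k[2]
            narrow = ct.ratio_band_probability(3.04, 0.40, (0.76, 0.79), 7, interp, seed=2).analytic
            wide = ct.ratio_band_probability(3.04, 0.40, (0.7, 0.9), 7, interp, seed=2).analytic
            assert narrow <= wide

    def test_input_validation_and_warning(self):
        with pytest.raises(ValueError):
            ct.ratio_band_probability(3.04, 0.4, (0.8, 0.75), 7, "fixed_central")
        with pytest.warns(UserWarning, match="mc_samples"):
            ct.ratio_band_probability(3.04, 0.4, (0.75, 0.8), 2, "fixed_central", mc_samples=100, seed=0)


def test_normality_diagnostic_on_gaussian_sample():
    rng = np.random.default_rng(5)
    stat, p = normality_diagnostic(rng.normal(0.19, 0.02, 2000))
    assert p > 0.001


class TestCsvReaders:
    def test_coccolith_csv_round_trip(self, tmp_path):
        path = tmp_path / "liths.csv"
        path.write_text("dsl_um,dsw_um,osw_um\n3.04,2.45,0.57\n2.9,2.3,0.5\n", encoding="utf-8")
        df = ct.read_coccolith_csv(path)
        assert list(df.columns) == ["dsl", "dsw", "osw"]
        assert len(df) == 2

    def test_coccosphere_csv_doubles_visible_count(self, tmp_path):
        path = tmp_path / "spheres.csv"
        path.write_text("diameter_um,visible_count\n5.5,8\n6.0,9\n", encoding="utf-8")
        df = ct.read_coccosphere_csv(path)
        assert list(df["count"]) == [16, 18]

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "liths.csv"
        path.write_text("dsl_um\n3.0\n", encoding="utf-8")
        with pytest.raises(ValueError, match="dsw_um"):
            ct.read_coccolith_csv(path)
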