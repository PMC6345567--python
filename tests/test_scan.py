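"""LHS sampling, dose grids, profile features and the classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from notchcis.models import scanned_parameters
from notchcis.scan import (
    ScanConfig,
    alpha_d_grid,
    classify_nonmonotonic,
    profile_features,
    response_profile,
    sample_parameters,
    scan,
)


class TestSampleParameters:
    def test_values_respect_bounds(self):
        cfg = ScanConfig(n_sets=4, seed=1)
        for p in sample_parameters(cfg, "M2c"):
            for name in scanned_parameters("M2c"):
                assert 1e-2 <= getattr(p, name) <= 1e2

    @pytest.mark.parametrize("scale", ["log", "linear"])
    def test_one_sample_per_stratum(self, scale):
        # The defining LHS property: each dimension has exactly one draw
        # per equal-width bin on the sampling scale.
        n = 10
        cfg = ScanConfig(n_sets=n, seed=7, sampling_scale=scale)
        psets = sample_parameters(cfg, "M2c")
        for name in scanned_parameters("M2c"):
            vals = np.array([getattr(p, name) for p in psets])
            if scale == "log":
                edges = np.linspace(-2, 2, n + 1)
                hist, _ = np.histogram(np.log10(vals), bins=edges)
            else:
                edges = np.linspace(1e-2, 1e2, n + 1)
                hist, _ = np.histogram(vals, bins=edges)
            assert np.all(hist == 1)

    def test_deterministic_under_seed(self):
        cfg = ScanConfig(n_sets=6, seed=42)
        assert sample_parameters(cfg, "M2c") == sample_parameters(cfg, "M2c")

    def test_m0_uses_reduced_dimensionality(self):
        cfg = ScanConfig(n_sets=3, seed=0)
        for p in sample_parameters(cfg, "M0"):
            # Non-scanned complex parameters stay at their defaults.
            assert p.gamma_Cminus == 1.0
            assert p.k_Cminus_on == 1.0

    def test_per_model_substreams_are_independent(self):
        cfg = ScanConfig(n_sets=5, seed=0)
        a = sample_parameters(cfg, "M2c")
        b = sample_parameters(cfg, "M2b")
        assert a != b
        # and unchanged when other models are (not) drawn first
        assert sample_parameters(cfg, "M2c") == a

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ScanConfig(n_sets=0)


class TestAlphaDGrid:
    def test_default_grid_spans_tenfold_each_way(self):
        g = alpha_d_grid(1.0, ScanConfig())
        assert g.size == 10
        assert g[0] == pytest.approx(0.1)
        assert g[-1] == pytest.approx(10.0)
        ratios = g[1:] / g[:-1]
        assert np.allclose(ratios, ratios[0])  # log-equispaced

    def test_scale_equivariance(self):
        cfg = ScanConfig()
        assert np.allclose(alpha_d_grid(5.0, cfg), 5.0 * alpha_d_grid(1.0, cfg))

    def test_three_point_grid(self):
        cfg = ScanConfig(n_alpha_d=3)
        assert np.allclose(alpha_d_grid(1.0, cfg), [0.1, 1.0, 10.0])


class TestProfileFeatures:
    def test_interior_peak_arithmetic(self):
        peak, incline, decline = profile_features([1.0, 4.0, 2.0])
        assert peak == 2
        assert incline == pytest.approx(0.75)
        assert decline == pytest.approx(0.5)

    def test_monotone_rise_has_no_decline(self):
        peak, incline, decline = profile_features([1.0, 2.0, 3.0, 4.0])
        assert peak == 4
        assert decline == 0.0

    def test_flat_profile_ties_break_to_first(self):
        assert profile_features([2.0, 2.0, 2.0]) == (1, 0.0, 0.0)

    def test_all_zero_profile_degenerate(self):
        assert profile_features([0.0, 0.0, 0.0]) == (1, 0.0, 0.0)

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            profile_features([1.0, 2.0])

    @given(st.lists(st.floats(min_value=0, max_value=1e6,
                              allow_nan=False), min_size=3, max_size=12))
    def test_features_always_bounded(self, values):
        peak, incline, decline = profile_features(values)
        assert 1 <= peak <= len(values)
        assert 0.0 <= incline <= 1.0
        assert 0.0 <= decline <= 1.0

    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3,
                              allow_nan=False), min_size=3, max_size=12),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_features_scale_invariant(self, values, c):
        # Incline/decline are ratios; rescaling the profile leaves them
        # (and the peak position) unchanged.
        p1 = profile_features(values)
        p2 = profile_features([c * v for v in values])
        assert p1[0] == p2[0]
        assert p1[1] == pytest.approx(p2[1], abs=1e-9)
        assert p1[2] == pytest.approx(p2[2], abs=1e-9)


class TestClassifier:
    @pytest.mark.parametrize("peak,expected", [
        (1, False), (2, True), (5, True), (8, True), (9, False), (10, False),
    ])
    def test_ten_point_rule(self, peak, expected):
        assert classify_nonmonotonic(peak, 10) is expected

    def test_generalizes_to_other_grid_sizes(self):
        assert classify_nonmonotonic(2, 4)
        assert not classify_nonmonotonic(3, 4)


class TestResponseProfile:
    def test_m0_profile_is_nondecreasing(self, all_ones):
        cfg = ScanConfig()
        prof = response_profile("M0", all_ones,
                                alpha_d_grid(all_ones.alpha_N, cfg))
        assert prof.all_converged
        assert np.all(np.diff(prof.c_plus) >= -1e-9)
        assert not prof.nonmonotonic

    def test_fixture_set_is_nonmonotonic(self, m2c_nonmono):
        cfg = ScanConfig()
        prof = response_profile("M2c", m2c_nonmono,
                                alpha_d_grid(m2c_nonmono.alpha_N, cfg))
        assert prof.all_converged
        assert prof.nonmonotonic
        assert prof.decline > 0.9

    def test_profile_matches_integration_oracle(self, m2c_nonmono):
        from notchcis.models import integrate_to_steady
        cfg = ScanConfig(n_alpha_d=5)
        grid = alpha_d_grid(m2c_nonmono.alpha_N, cfg)
        prof = response_profile("M2c", m2c_nonmono, grid)
        oracle = np.array([
            integrate_to_steady(
                "M2c", m2c_nonmono.replace(alpha_D=float(a)), tol=1e-10
            ).concentrations["C+"]
            for a in grid
        ])
        assert np.allclose(prof.c_plus, oracle, rtol=1e-4)


class TestScan:
    def test_small_scan_table_shape_and_determinism(self):
        cfg = ScanConfig(n_sets=8, seed=5, model_ids=("M0", "M2c"))
        tables, summary = scan(cfg)
        tables2, _ = scan(cfg)
        for m in ("M0", "M2c"):
            assert len(tables[m]) == 8
            pd.testing.assert_frame_equal(tables[m], tables2[m])
        assert set(summary["model_id"]) == {"M0", "M2c"}
        assert {"peak_index", "incline", "decline", "nonmonotonic",
                "n_converged"} <= set(tables["M2c"].columns)

    def test_nonmonotonic_rows_always_have_decline(self):
        cfg = ScanConfig(n_sets=40, seed=2, model_ids=("M2c",))
        tables, _ = scan(cfg)
        nm = tables["M2c"].query("nonmonotonic")
        assert len(nm) > 0
        assert (nm["decline"] > 0).all()
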