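import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikequant import (
    DilutionSeries,
    InsufficientDataError,
    OtuTable,
    SampleMetadata,
    build_dilution_series,
    calibrate_panel,
    detection_limit,
    detection_limit_from_line,
    fit_loglog,
    per_ml,
)


def series_from(spores, reads, min_reads=5.0):
    spores = np.asarray(spores, float)
    reads = np.asarray(reads, float)
    included = (reads > min_reads) & (reads > 0)
    return DilutionSeries(
        otu_id="O",
        spores=spores,
        reads=reads,
        included=included,
        sample_ids=[f"s{i}" for i in range(len(reads))],
        min_reads_for_fit=min_reads,
    )


def ols_oracle(x, y):
    """Normal-equations least squares, independent of the fit path."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    r = np.corrcoef(x, y)[0, 1]
    return beta[1], beta[0], r**2


def ref_table(values_by_sample, otu_ids):
    return OtuTable(
        counts=pd.DataFrame(values_by_sample, index=otu_ids, dtype=float),
        state="reference_normalized",
    )


class TestBuildSeries:
    def test_joint_exclusion_rules(self, spike_metadata):
        t = ref_table(
            {"d1": [0.0], "d2": [3.0], "d3": [40.0], "d4": [400.0], "c1": [9.0]},
            ["O"],
        )
        s = build_dilution_series(t, spike_metadata, "O")
        # control sample never enters; 0-read and <=5-read points not included
        assert s.sample_ids == ["d1", "d2", "d3", "d4"]
        assert list(s.included) == [False, False, True, True]
        assert [(sp, r) for sp, r, i in zip(s.spores, s.reads, s.included) if i] == [
            (850.0, 40.0),
            (8500.0, 400.0),
        ]
        rules = {sid: rule for sid, _, rule in s.exclusions()}
        assert rules["d1"] == "zero reads" and "5" in rules["d2"]

    def test_all_zero_reads_errors(self, spike_metadata):
        t = ref_table({s: [0.0] for s in spike_metadata}, ["O"])
        with pytest.raises(InsufficientDataError, match="insufficient points"):
            build_dilution_series(t, spike_metadata, "O")

    def test_min_reads_zero_drops_only_zero_read_points(self, spike_metadata):
        t = ref_table(
            {"d1": [0.0], "d2": [3.0], "d3": [40.0], "d4": [400.0], "c1": [1.0]},
            ["O"],
        )
        s = build_dilution_series(t, spike_metadata, "O", min_reads_for_fit=0.0)
        assert list(s.included) == [False, True, True, True]

    def test_point_at_exactly_cutoff_excluded(self, spike_metadata):
        t = ref_table(
            {"d1": [5.0], "d2": [6.0], "d3": [40.0], "d4": [400.0], "c1": [1.0]},
            ["O"],
        )
        s = build_dilution_series(t, spike_metadata, "O", min_reads_for_fit=5.0)
        assert list(s.included) == [False, True, True, True]


class TestFitLogLog:
    def test_identity_line(self):
        s = series_from([10, 100, 1000], [10, 100, 1000])
        fit = fit_loglog(s)
        assert math.isclose(fit.slope_a, 1.0, abs_tol=1e-12)
        assert math.isclose(fit.intercept_b, 0.0, abs_tol=1e-12)
        assert fit.r_squared == 1.0

    def test_two_point_exact_line(self):
        s = series_from([10, 1000], [1, 100], min_reads=0.0)
        fit = fit_loglog(s)
        assert math.isclose(fit.slope_a, 1.0, abs_tol=1e-12)
        assert math.isclose(fit.intercept_b, -1.0, abs_tol=1e-12)
        assert fit.r_squared == 1.0  # two points interpolate exactly

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(3, 51)
            spores = 10 ** rng.uniform(0.5, 6, size=n)
            reads = 10 ** rng.uniform(0.8, 4, size=n)
            s = series_from(spores, reads, min_reads=0.0)
            fit = fit_loglog(s)
            a, b, r2 = ols_oracle(np.log10(spores), np.log10(reads))
            assert math.isclose(fit.slope_a, a, rel_tol=1e-9, abs_tol=1e-9)
            assert math.isclose(fit.intercept_b, b, rel_tol=1e-9, abs_tol=1e-9)
            assert math.isclose(fit.r_squared, r2, rel_tol=1e-9, abs_tol=1e-9)

    def test_excluded_points_never_enter_fit(self):
        spores = [10.0, 100.0, 1000.0, 10000.0]
        reads = [2.0, 30.0, 300.0, 3000.0]
        s = series_from(spores, reads, min_reads=5.0)  # first point excluded
        fit = fit_loglog(s)
        a, b, r2 = ols_oracle(np.log10(spores[1:]), np.log10(reads[1:]))
        assert math.isclose(fit.slope_a, a, rel_tol=1e-12)
        assert math.isclose(fit.intercept_b, b, rel_tol=1e-12)
        assert fit.n_points == 3

    def test_no_spread_errors(self):
        s = series_from([100, 100, 100], [10, 20, 30], min_reads=0.0)
        with pytest.raises(InsufficientDataError, match="spread"):
            fit_loglog(s)

    @settings(max_examples=50, deadline=None)
    @given(
        xy=st.lists(
            st.tuples(
                st.floats(min_value=0.5, max_value=6.0),
                st.floats(min_value=-2.0, max_value=4.0),
            ),
            min_size=2,
            max_size=50,
            unique_by=lambda t: round(t[0], 6),
        )
    )
    def test_ols_oracle_property(self, xy):
        x = np.array([p[0] for p in xy])
        y = np.array([p[1] for p in xy])
        s = series_from(10**x, 10**y, min_reads=0.0)
        fit = fit_loglog(s)
        a, b, _ = ols_oracle(x, y)
        assert math.isclose(fit.slope_a, a, rel_tol=1e-9, abs_tol=1e-9)
        assert math.isclose(fit.intercept_b, b, rel_tol=1e-9, abs_tol=1e-9)
        if len(xy) == 2:
            assert fit.r_squared == 1.0


class TestDetectionLimit:
    def test_unit_line_gives_one_spore(self):
        s = series_from([10, 100, 1000], [10, 100, 1000])
        fit = detection_limit(fit_loglog(s), read_threshold=1.0)
        assert math.isclose(fit.detection_limit_spores, 1.0, rel_tol=1e-12)

    def test_limit_is_functional_inverse_of_line(self):
        s = series_from([20, 300, 5000, 80000], [9, 60, 900, 21000], min_reads=0.0)
        fit = detection_limit(fit_loglog(s), read_threshold=1.0)
        predicted = fit.slope_a * fit.detection_limit_log10 + fit.intercept_b
        assert math.isclose(10**predicted, 1.0, rel_tol=1e-9)

    def test_limit_linear_in_threshold_on_log_scale(self):
        a, b = 0.9669, -1.9271
        _, at_one = detection_limit_from_line(a, b, read_threshold=1.0)
        _, at_ten = detection_limit_from_line(a, b, read_threshold=10.0)
        assert math.isclose(at_ten / at_one, 10 ** (1 / a), rel_tol=1e-12)

    def test_exponential_identity(self):
        log10_limit, spores = detection_limit_from_line(0.644, -0.5384)
        assert math.isclose(spores, 10**log10_limit, rel_tol=1e-9)

    def test_negative_limit_reported_and_flagged(self):
        s = series_from([10, 100, 1000], [9000, 9100, 9050], min_reads=0.0)
        fit = detection_limit(fit_loglog(s), endogenous=True)
        assert fit.detection_limit_log10 < 0
        assert fit.non_physical

    def test_zero_slope_errors(self):
        s = series_from([10, 1000], [50, 50])
        with pytest.raises(InsufficientDataError, match="slope|dose"):
            detection_limit(fit_loglog(s))


class TestPerMl:
    def test_division(self):
        from dataclasses import replace

        s = series_from([10, 1000], [10, 1000])
        fit = replace(detection_limit(fit_loglog(s)), detection_limit_spores=252.0)
        assert math.isclose(per_ml(fit, 0.85), 296.470588235, rel_tol=1e-9)

    def test_identity_volume(self):
        s = series_from([10, 1000], [10, 1000])
        fit = detection_limit(fit_loglog(s))
        assert per_ml(fit, 1.0) == fit.detection_limit_spores

    def test_algebraic_inverse(self):
        s = series_from([30, 400, 9000], [11, 150, 3000], min_reads=0.0)
        fit = detection_limit(fit_loglog(s))
        for v in (0.1, 0.85, 3.0):
            assert math.isclose(
                per_ml(fit, v) * v, fit.detection_limit_spores, rel_tol=1e-12
            )


class TestPanel:
    def _table_and_md(self):
        md = {
            f"d{i}": SampleMetadata(f"d{i}", group="spiked",
                                    spike_spores_per_sample=10.0**i)
            for i in range(1, 5)
        }
        cols = {
            "d1": [10.0, 30.0, 1.0],
            "d2": [100.0, 300.0, 2.0],
            "d3": [1000.0, 3000.0, 1.0],
            "d4": [10000.0, 30000.0, 2.0],
        }
        return ref_table(cols, ["A", "B", "C"]), md

    def test_single_otu_summary_equals_its_limit(self):
        table, md = self._table_and_md()
        panel = calibrate_panel(table, md, ["A"])
        assert panel.mean_detection_limit_spores == pytest.approx(
            panel.fits[0].detection_limit_spores
        )

    def test_mean_of_two_limits(self):
        table, md = self._table_and_md()
        panel = calibrate_panel(table, md, ["A", "B"])
        la, lb = (f.detection_limit_spores for f in panel.fits)
        assert panel.mean_detection_limit_spores == pytest.approx((la + lb) / 2)
        assert panel.mean_detection_limit_per_ml == pytest.approx(
            (la + lb) / 2 / 0.85
        )

    def test_panel_continues_past_failures(self):
        table, md = self._table_and_md()
        panel = calibrate_panel(table, md, ["A", "C", "missing"])
        assert [f.otu_id for f in panel.fits] == ["A"]
        assert set(panel.failures) == {"C", "missing"}

    def test_endogenous_otus_excluded_from_mean(self):
        table, md = self._table_and_md()
        panel = calibrate_panel(table, md, ["A", "B"], endogenous_otu_ids=["B"])
        assert panel.mean_detection_limit_spores == pytest.approx(
            next(f for f in panel.fits if f.otu_id == "A").detection_limit_spores
        )
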