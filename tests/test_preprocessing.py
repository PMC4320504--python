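"""Preprocessing tests: CSV ingestion, smoothing, segmentation, references."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermofit import Protocol, ReferenceSignal, ROI_LABELS, TemperatureSeries, TimeGrid
from thermofit.cohort import default_group_params, generate_cohort, write_cohort
from thermofit.preprocessing import (
    FormatError,
    LabelingError,
    ProtocolError,
    compute_reference,
    concat_phases,
    deviation_transform,
    moving_average,
    read_roi_csv,
    segment_phases,
    smooth,
)


def make_series(values, dt=1.0, t0=0.0, **meta):
    values = np.asarray(values, dtype=float)
    return TemperatureSeries(
        grid=TimeGrid(n_samples=values.size, dt=dt, t0=t0), values=values, **meta
    )


class TestReadRoiCsv:
    def _write(self, tmp_path, protocol, columns=None, mutate=None):
        rng = np.random.default_rng(0)
        n = protocol.recorded_samples
        data = {"time_s": np.arange(n) * protocol.dt_seconds}
        for label in columns or ROI_LABELS:
            data[label] = 30.0 + 0.1 * rng.standard_normal(n)
        df = pd.DataFrame(data)
        if mutate is not None:
            df = mutate(df)
        path = tmp_path / "subject.csv"
        df.to_csv(path, index=False)
        return path

    def test_well_formed_file_gives_14_series(self, tmp_path, protocol):
        path = self._write(tmp_path, protocol)
        series = read_roi_csv(path, protocol)
        assert len(series) == 14
        assert {s.roi_label for s in series} == set(ROI_LABELS)

    def test_column_order_is_irrelevant(self, tmp_path, protocol):
        path = self._write(tmp_path, protocol)
        shuffled = list(ROI_LABELS)[::-1]
        path2 = self._write(tmp_path, protocol, columns=shuffled)
        by_label = {s.roi_label: s for s in read_roi_csv(path, protocol)}
        by_label2 = {s.roi_label: s for s in read_roi_csv(path2, protocol)}
        assert set(by_label) == set(by_label2)

    def test_synthetic_export_roundtrips_exactly(self, tmp_path, protocol):
        records = generate_cohort(
            default_group_params(), n_psa=1, n_hc=1, rng_seed=11
        )
        write_cohort(records, tmp_path, protocol)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            series = read_roi_csv(tmp_path / "PsA01.csv", protocol)
        by_label = {s.roi_label: s for s in series}
        lo, hi = 15.0, 42.0
        checked = 0
        for rec in records:
            if rec.subject_id != "PsA01":
                continue
            v = rec.series.values
            if v.min() < lo or v.max() > hi:
                continue  # implausible excursions are dropout-bridged on read
            assert np.array_equal(by_label[rec.roi_label].values, v)
            checked += 1
        assert checked >= 10

    def test_nonuniform_time_rejected(self, tmp_path, protocol):
        def mutate(df):
            df.loc[3, "time_s"] += 1.0
            return df

        path = self._write(tmp_path, protocol, mutate=mutate)
        with pytest.raises(FormatError):
            read_roi_csv(path, protocol)

    def test_unknown_roi_name_rejected(self, tmp_path, protocol):
        path = self._write(tmp_path, protocol, columns=["left elbow"])
        with pytest.raises(LabelingError):
            read_roi_csv(path, protocol)

    def test_out_of_window_sample_masked_and_interpolated(self, tmp_path, protocol):
        def mutate(df):
            df.loc[5, "I MCP"] = 80.0  # far outside [15, 42] degC
            return df

        path = self._write(tmp_path, protocol, mutate=mutate)
        with pytest.warns(UserWarning, match="masked"):
            series = read_roi_csv(path, protocol)
        s = {x.roi_label: x for x in series}["I MCP"]
        assert np.all(np.isfinite(s.values))
        assert abs(s.values[5] - 0.5 * (s.values[4] + s.values[6])) < 1e-12

    def test_wrong_length_rejected(self, tmp_path):
        protocol = Protocol()
        path = self._write(tmp_path, Protocol(recovery_samples=31))
        with pytest.raises(ProtocolError):
            read_roi_csv(path, protocol)


class TestSmooth:
    def test_constant_unchanged(self):
        s = make_series(np.full(20, 31.5))
        assert np.array_equal(smooth(s).values, s.values)

    def test_impulse_with_shrinking_edge_windows(self):
        out = moving_average(np.array([0.0, 0, 1, 0, 0]), span=5)
        assert np.allclose(out, [0, 1 / 3, 1 / 5, 1 / 3, 0])

    def test_linear_ramp_preserved(self):
        ramp = np.linspace(20, 30, 15)
        out = moving_average(ramp, span=5)
        assert np.allclose(out, ramp, atol=1e-12)

    def test_even_span_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_average(np.zeros(10), span=4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=5, max_size=60),
        st.sampled_from([1, 3, 5, 7]),
    )
    def test_never_widens_value_range(self, values, span):
        values = np.asarray(values)
        if span > values.size:
            span = 1
        out = moving_average(values, span)
        assert out.min() >= values.min() - 1e-12
        assert out.max() <= values.max() + 1e-12

    def test_idempotent_on_affine(self):
        ramp = 2.0 + 0.3 * np.arange(30)
        once = moving_average(ramp, 5)
        twice = moving_average(once, 5)
        assert np.allclose(once, twice, atol=1e-12)


class TestSegmentation:
    def test_default_protocol_splits_9_plus_30(self, protocol):
        s = make_series(np.linspace(29, 31, 39))
        baseline, recovery = segment_phases(s, protocol)
        assert baseline.grid.n_samples == 9
        assert recovery.grid.n_samples == 30
        assert recovery.grid.t0 == 0.0

    def test_recovery_only_protocol(self):
        protocol = Protocol(baseline_samples=0, recovery_samples=30)
        s = make_series(np.linspace(29, 31, 30))
        baseline, recovery = segment_phases(s, protocol)
        assert baseline is None
        assert recovery.grid.n_samples == 30

    def test_split_concat_roundtrip(self, protocol):
        rng = np.random.default_rng(3)
        s = make_series(30 + rng.normal(size=39))
        baseline, recovery = segment_phases(s, protocol)
        back = concat_phases(baseline, recovery)
        assert np.array_equal(back.values, s.values)
        assert back.grid == s.grid

    def test_length_mismatch_rejected(self, protocol):
        with pytest.raises(ProtocolError):
            segment_phases(make_series(np.zeros(38)), protocol)


class TestReference:
    def test_constant_baseline(self):
        baseline = make_series(np.full(9, 30.0))
        recovery = make_series(np.r_[29.2, np.full(29, 29.5)])
        ref = compute_reference(baseline, recovery)
        assert ref.T == 30.0
        assert ref.y0 == 29.2
        assert ref.r == pytest.approx(0.8)

    def test_baseline_mean(self):
        baseline = make_series([29.0, 31.0])
        recovery = make_series(np.zeros(30) + 29)
        assert compute_reference(baseline, recovery).T == 30.0

    def test_generator_roundtrip_recovers_reference(self, protocol):
        from thermofit import ModelParams
        from thermofit.cohort import generate_curve

        ref = ReferenceSignal(T=30.4, y0=29.55)
        params = ModelParams(5, 0.2, -0.1, 0.4)
        series = generate_curve(params, ref, protocol, noise_sd=0.0)
        baseline, recovery = segment_phases(series, protocol)
        got = compute_reference(baseline, recovery)
        assert got.T == pytest.approx(30.4, abs=1e-12)
        assert got.y0 == pytest.approx(29.55, abs=1e-12)
        assert got.r == pytest.approx(0.85, abs=1e-12)

    def test_empty_baseline_requires_explicit_T(self):
        recovery = make_series(np.zeros(30) + 29)
        with pytest.raises(ValueError, match="baseline"):
            compute_reference(None, recovery)

    def test_constant_shift_moves_T_y0_not_r(self, protocol):
        rng = np.random.default_rng(5)
        vals = 30 + rng.normal(size=39)
        b1, r1 = segment_phases(make_series(vals), protocol)
        b2, r2 = segment_phases(make_series(vals + 2.5), protocol)
        ref1, ref2 = compute_reference(b1, r1), compute_reference(b2, r2)
        assert ref2.T - ref1.T == pytest.approx(2.5, abs=1e-12)
        assert ref2.y0 - ref1.y0 == pytest.approx(2.5, abs=1e-12)
        assert ref2.r == pytest.approx(ref1.r, abs=1e-12)


class TestDeviationTransform:
    def test_first_sample_zero_and_constant_zeroed(self):
        recovery = make_series(np.r_[29.2, 29.5 + np.zeros(9)])
        ref = ReferenceSignal(T=30.0, y0=29.2)
        dev = deviation_transform(recovery, ref)
        assert dev.values[0] == 0.0
        const = make_series(np.full(10, 29.2))
        assert np.all(deviation_transform(const, ref).values == 0.0)
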