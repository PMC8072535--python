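"""Trial ingestion, COP derivation and zero-lag filtering."""

import numpy as np
import pytest

from swayemd import (
    CHANNELS,
    CsvDialect,
    FilterSpec,
    TrialSeries,
    compute_cop,
    read_metadata,
    read_trial,
    write_trial,
    zero_lag_lowpass,
)
from swayemd.errors import (
    DegenerateLoadError,
    FormatError,
    LabelError,
    LengthError,
    ValidationError,
)

from oracles import butter_lowpass_gain

FS = 100.0


def _series(name, values, fs=FS):
    return TrialSeries(name, fs, np.asarray(values, dtype=float))


def _write_csv(path, header, rows):
    lines = [",".join(header)]
    lines += [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadTrial:
    def test_reads_five_channel_file(self, tmp_path):
        p = tmp_path / "BDS00001.csv"
        n = 50
        _write_csv(
            p,
            ["Fx", "Fy", "Fz", "COPx", "COPy"],
            [[i, i + 1, 700 + i, 0.1 * i, -0.1 * i] for i in range(n)],
        )
        rec = read_trial(p)
        assert rec.subject_id == "BDS00001"
        assert set(rec.channels) == set(CHANNELS)
        assert rec.n_samples == n
        assert rec.fs == FS

    def test_derives_cop_from_moments(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_csv(
            p,
            ["Fx", "Fy", "Fz", "Mx", "My"],
            [[0, 0, 700, 0, -70] for _ in range(10)],
        )
        rec = read_trial(p)
        assert np.allclose(rec.channels["COPx"].values, 0.1)
        assert np.allclose(rec.channels["COPy"].values, 0.0)

    def test_missing_channel_error_names_column(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_csv(p, ["Fx", "Fy", "COPx", "COPy"], [[1, 2, 3, 4]] * 5)
        with pytest.raises(FormatError, match="Fz"):
            read_trial(p)

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("Fx,Fy,Fz,COPx,COPy\n")
        with pytest.raises(FormatError):
            read_trial(p)

    def test_alias_resolution_case_insensitive(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_csv(p, ["FX", "fy", "Fz", "COP_X", "cop_y"], [[1, 2, 3, 4, 5]] * 5)
        rec = read_trial(p)
        assert rec.channels["COPx"].values[0] == 4

    def test_roundtrip_is_bit_identical(self, tmp_path, rng):
        channels = {
            c: _series(c, rng.standard_normal(64) * 100) for c in CHANNELS
        }
        from swayemd import TrialRecording

        rec = TrialRecording("s1", "fall", channels)
        p = tmp_path / "s1.csv"
        write_trial(rec, p)
        back = read_trial(p, subject_id="s1", group="fall")
        for c in CHANNELS:
            assert np.array_equal(back.channels[c].values, rec.channels[c].values)
        assert back.fs == rec.fs


class TestComputeCop:
    def test_closed_form(self):
        fz = _series("Fz", [700.0] * 10)
        my = _series("My", [-70.0] * 10)
        mx = _series("Mx", [0.0] * 10)
        copx, copy = compute_cop(fz, mx, my)
        assert np.allclose(copx.values, 0.1)
        assert np.allclose(copy.values, 0.0)

    def test_zero_moments_give_zero_cop(self):
        fz = _series("Fz", [650.0] * 8)
        zero = _series("M", [0.0] * 8)
        copx, copy = compute_cop(fz, zero, zero)
        assert np.all(copx.values == 0) and np.all(copy.values == 0)

    def test_zero_fz_sample_is_degenerate(self):
        fz = _series("Fz", [700.0, 0.0, 700.0])
        m = _series("M", [1.0, 1.0, 1.0])
        with pytest.raises(DegenerateLoadError):
            compute_cop(fz, m, m)

    def test_pad_height_correction_term(self):
        fz = _series("Fz", [700.0] * 5)
        mx = _series("Mx", [0.0] * 5)
        my = _series("My", [0.0] * 5)
        fx = _series("Fx", [70.0] * 5)
        fy = _series("Fy", [-35.0] * 5)
        copx, copy = compute_cop(fz, mx, my, pad_height=0.06, fx=fx, fy=fy)
        assert np.allclose(copx.values, -70 * 0.06 / 700)
        assert np.allclose(copy.values, 35 * 0.06 / 700)


class TestZeroLagFilter:
    def test_dc_gain_is_unity(self):
        s = _series("Fz", np.full(500, 3.7))
        out = zero_lag_lowpass(s, FilterSpec())
        assert np.allclose(out.values, 3.7, atol=1e-9)

    @pytest.mark.parametrize(
        "freq, check",
        [
            (1.0, "pass"),  # two-pass |H| at 1 Hz is within 1% of unity
            (30.0, "stop"),  # two-pass |H| at 30 Hz is ~1.5e-4
        ],
    )
    def test_band_behavior_matches_squared_magnitude(self, freq, check):
        t = np.arange(6000) / FS
        s = _series("COPx", np.sin(2 * np.pi * freq * t))
        out = zero_lag_lowpass(s, FilterSpec(cutoff=10.0, order=4)).values
        interior = out[500:-500]
        amp = np.max(np.abs(interior))
        gain = butter_lowpass_gain(freq, 10.0, 4, passes=2)
        if check == "pass":
            assert gain > 0.99
            assert abs(amp - 1.0) < 0.01
        else:
            assert gain < 0.05
            assert amp < 0.05

    def test_linearity(self, rng):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        spec = FilterSpec()
        fa = zero_lag_lowpass(_series("Fx", 2.0 * x + 3.0 * y), spec).values
        fb = (
            2.0 * zero_lag_lowpass(_series("Fx", x), spec).values
            + 3.0 * zero_lag_lowpass(_series("Fx", y), spec).values
        )
        assert np.allclose(fa, fb, rtol=1e-8, atol=1e-10)

    def test_symmetric_pulse_stays_symmetric(self):
        n = 501
        t = np.arange(n)
        pulse = np.exp(-((t - 250) ** 2) / (2 * 15.0**2))
        out = zero_lag_lowpass(_series("Fz", pulse), FilterSpec()).values
        assert np.allclose(out, out[::-1], atol=1e-9)

    def test_too_short_series_raises(self):
        with pytest.raises(LengthError):
            zero_lag_lowpass(_series("Fz", np.ones(10)), FilterSpec())

    def test_cutoff_above_nyquist_rejected(self):
        s = _series("Fz", np.ones(500))
        with pytest.raises(ValidationError):
            zero_lag_lowpass(s, FilterSpec(cutoff=60.0))


class TestMetadata:
    def test_reads_and_normalizes_groups(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("subject_id,group\na,fall\nb,nonfall\nc,non-fall\n")
        meta = read_metadata(p)
        assert list(meta["group"]) == ["fall", "non_fall", "non_fall"]

    def test_unknown_label_rejected(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("subject_id,group\na,unknown\n")
        with pytest.raises(LabelError):
            read_metadata(p)

    def test_duplicate_subjects_rejected(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("subject_id,group\na,fall\na,fall\n")
        with pytest.raises(FormatError):
            read_metadata(p)
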