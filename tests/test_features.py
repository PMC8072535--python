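"""Time-domain and entropy features, and per-subject extraction layout."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swayemd import (
    EntropyParams,
    SiftConfig,
    approximate_entropy,
    cv,
    decompose_recording,
    extract_features,
    feature_names,
    mean_abs,
    sample_entropy,
    std,
)
from swayemd.errors import LengthError, UndefinedFeatureError, ValidationError

from oracles import brute_apen, brute_sampen


class TestTimeDomain:
    @pytest.mark.parametrize(
        "func, data, expected",
        [
            (mean_abs, [1, -1, 1, -1], 1.0),
            (mean_abs, [0, 0, 0], 0.0),
            (mean_abs, [3, -4], 3.5),
            (std, [5, 5, 5, 5], 0.0),
            (std, [1, -1, 1, -1], math.sqrt(4 / 3)),
            (std, [0, 2], math.sqrt(2)),
            (cv, [1, -1, 1, -1], math.sqrt(4 / 3)),
            (cv, [7, 7, 7], 0.0),
        ],
    )
    def test_closed_forms(self, func, data, expected):
        assert func(np.asarray(data, dtype=float)) == pytest.approx(expected, abs=1e-12)

    def test_cv_undefined_on_all_zeros(self):
        with pytest.raises(UndefinedFeatureError):
            cv(np.zeros(10))

    def test_length_contracts(self):
        with pytest.raises(LengthError):
            mean_abs(np.array([]))
        with pytest.raises(LengthError):
            std(np.array([1.0]))


class TestEntropies:
    def test_periodic_series_with_absolute_tolerance(self):
        x = np.array([1.0, 2.0] * 30)
        p = EntropyParams(m=2, r_absolute=0.5)
        assert sample_entropy(x, p) == pytest.approx(0.0, abs=1e-12)
        # every m-match extends to an (m+1)-match, so ApEn is only the
        # small self-match edge bias
        assert approximate_entropy(x, p) == pytest.approx(0.0, abs=1e-2)

    def test_constant_series_degenerate_rule(self):
        x = np.full(50, 2.5)
        assert approximate_entropy(x) == 0.0
        assert sample_entropy(x) == 0.0

    def test_too_short_raises(self):
        with pytest.raises(LengthError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), EntropyParams(m=2))

    def test_matches_brute_force_oracle(self):
        """Both entropies equal O(n^2) direct counting to 1e-12 on a
        seeded battery covering lengths 20-200 and several (m, lag)."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(20, 200))
            x = rng.standard_normal(n)
            m = int(rng.integers(1, 4))
            lag = int(rng.integers(1, 3))
            r = 0.2 * np.std(x, ddof=1)
            p = EntropyParams(m=m, r_absolute=r, lag=lag)
            assert approximate_entropy(x, p) == pytest.approx(
                brute_apen(x, m, r, lag), abs=1e-12
            )
            s_mine = sample_entropy(x, p)
            s_ref = brute_sampen(x, m, r, lag)
            if math.isnan(s_ref):
                assert math.isnan(s_mine)
            else:
                assert s_mine == pytest.approx(s_ref, abs=1e-12)

    @given(st.floats(0.1, 100.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance_with_relative_tolerance(self, scale, seed):
        x = np.random.default_rng(seed).standard_normal(80)
        p = EntropyParams(m=2, r_fraction=0.2)
        s1, s2 = sample_entropy(scale * x, p), sample_entropy(x, p)
        if math.isnan(s2):  # no (m+1)-matches at this length: both undefined
            assert math.isnan(s1)
        else:
            assert s1 == pytest.approx(s2, abs=1e-9)
        assert approximate_entropy(scale * x, p) == pytest.approx(
            approximate_entropy(x, p), abs=1e-9
        )

    def test_regular_below_noise_ordering(self):
        """SampEn(periodic) < SampEn(white noise) in >=99/100 seeded trials."""
        wins = 0
        t = np.arange(300)
        for seed in range(100):
            rr = np.random.default_rng(seed)
            f = rr.uniform(0.01, 0.05)
            periodic = np.sin(2 * np.pi * f * t + rr.uniform(0, 2 * np.pi))
            noise = rr.standard_normal(t.size)
            wins += sample_entropy(periodic) < sample_entropy(noise)
        assert wins >= 99

    def test_sorting_regularizes(self, rng):
        x = rng.uniform(size=200)
        p = EntropyParams(m=2, r_fraction=0.2)
        assert sample_entropy(x, p) > sample_entropy(np.sort(x), p)


class TestExtractFeatures:
    def test_feature_layout_and_naming(self, short_trial):
        imfsets = decompose_recording(short_trial)
        records = extract_features(short_trial, imfsets)
        assert len(records) == 200  # 5 channels x 8 series x 5 features
        names = [r.name for r in records]
        assert names == feature_names(7)
        assert "COPx_0_ApEn" in names
        assert "Fz_7_STD" in names
        assert "COPx_3_sample entropy" in names

    def test_missing_deep_levels_recorded_as_nan(self, short_trial):
        shallow = decompose_recording(short_trial, SiftConfig(max_imf=5))
        records = extract_features(short_trial, shallow, max_imf=7)
        assert len(records) == 200
        missing = [r for r in records if math.isnan(r.value)]
        by_level = {(r.name.split("_")[1]) for r in missing}
        assert by_level <= {"6", "7"}
        assert len(missing) == 5 * 2 * 5  # 5 channels x levels 6,7 x 5 features

    def test_missing_channel_is_error(self, short_trial):
        imfsets = decompose_recording(short_trial)
        del imfsets["Fz"]
        with pytest.raises(ValidationError):
            extract_features(short_trial, imfsets)

    def test_each_imf_uses_its_own_sd_for_tolerance(self, short_trial):
        """Scaling one channel leaves its entropy features unchanged."""
        imfsets = decompose_recording(short_trial)
        records = {r.name: r.value for r in extract_features(short_trial, imfsets)}
        from dataclasses import replace as dc_replace

        from swayemd import TrialRecording, TrialSeries

        scaled_ch = {
            name: TrialSeries(name, s.fs, 3.0 * s.values)
            for name, s in short_trial.channels.items()
        }
        scaled = TrialRecording(short_trial.subject_id, short_trial.group, scaled_ch)
        imfsets2 = decompose_recording(scaled)
        records2 = {r.name: r.value for r in extract_features(scaled, imfsets2)}
        for name in records:
            if name.endswith("ApEn") or name.endswith("sample entropy"):
                assert records2[name] == pytest.approx(records[name], abs=1e-6)
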