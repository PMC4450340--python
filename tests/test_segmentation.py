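"""SSE envelope, smoothing, sound picking and segment serialization."""

import numpy as np
import pytest
from hypothesis import assume, given, strategies as st

from conftest import make_burst
from stresspcg import (
    DegenerateInputError,
    DomainError,
    InvalidInputError,
    SSEEnvelope,
    SoundSegment,
    TimeSignal,
    detect_sounds,
    match_segments,
    read_segments_csv,
    read_segments_json,
    s_transform,
    segment_recording,
    smooth_envelope,
    sse_envelope,
    write_segments_csv,
    write_segments_json,
)
from stresspcg.stockwell import STMatrix


def _matrix(values):
    values = np.asarray(values, dtype=complex)
    return STMatrix(values, np.arange(1.0, values.shape[0] + 1),
                    np.arange(float(values.shape[1])), 1.0)


class TestSSEEnvelope:
    def test_peak_coefficient_contributes_zero(self):
        """A normalized coefficient of exactly 1 contributes -1*log(1) = 0."""
        m = np.zeros((3, 4))
        m[1, 2] = 5.0  # becomes 1 after normalization; only nonzero entry
        env = sse_envelope(_matrix(m))
        assert env.values[2] == pytest.approx(0.0)

    def test_zero_columns_are_zero(self):
        m = np.zeros((3, 4))
        m[0, 1] = 1.0
        m[1, 1] = 0.3
        env = sse_envelope(_matrix(m))
        assert env.values[0] == 0.0
        assert env.values[3] == 0.0
        assert env.values[1] > 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            sse_envelope(_matrix(np.zeros((3, 3))))
        with pytest.raises(DomainError):
            sse_envelope(_matrix(np.ones((3, 3))), exponent_n=-1.0)

    def test_envelope_nonnegative_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = np.abs(rng.standard_normal((8, 30))) * rng.uniform(0.01, 100)
            env = sse_envelope(_matrix(m))
            assert np.all(env.values >= 0)

    @given(
        st.floats(min_value=1e-6, max_value=1.0, exclude_max=True),
        st.floats(min_value=1e-6, max_value=1.0),
    )
    def test_lower_exponent_favours_faint_coefficients(self, x, y):
        """For 0 < x < y <= 1 the ratio x^n / y^n grows as n drops from 2
        to 1.5 — the compression that rescues faint sounds."""
        assume(x < y)
        assert x**1.5 / y**1.5 > x**2 / y**2

    def test_faint_sound_relatively_enhanced_at_low_exponent(self):
        """A faint snap next to a loud boom keeps a larger envelope
        fraction with n = 1.5 than with the classical n = 2."""
        fs = 2000.0
        t = np.arange(int(fs)) / fs
        loud = np.exp(-0.5 * ((t - 0.3) / 0.02) ** 2) * np.sin(2 * np.pi * 45 * t)
        faint = 0.15 * np.exp(-0.5 * ((t - 0.7) / 0.01) ** 2) * np.sin(
            2 * np.pi * 95 * t
        )
        mat = s_transform(TimeSignal(loud + faint, fs), 1.0, 250.0, include_dc=False)
        ratios = {}
        for n in (1.5, 2.0):
            env = sse_envelope(mat, n).values
            ratios[n] = env[(t > 0.6) & (t < 0.8)].max() / env[(t > 0.2) & (t < 0.4)].max()
        assert ratios[1.5] > ratios[2.0]


class TestSmoothing:
    def _env(self, values, fs=1000.0):
        values = np.asarray(values, dtype=float)
        return SSEEnvelope(values, np.arange(values.size) / fs)

    def test_constant_is_unchanged(self):
        env = smooth_envelope(self._env(np.full(500, 2.5)), 0.02)
        assert np.allclose(env.values, 2.5)

    def test_impulse_becomes_rectangle(self):
        x = np.zeros(501)
        x[250] = 1.0
        out = smooth_envelope(self._env(x), 0.021)  # 21-sample window
        inside = out.values[out.values > 0]
        assert inside.size == 21
        assert np.allclose(inside, 1.0 / 21)

    def test_noise_variance_is_reduced_and_mass_kept(self):
        rng = np.random.default_rng(3)
        x = np.abs(rng.standard_normal(2000))
        out = smooth_envelope(self._env(x), 0.02)
        assert out.values.var() < x.var()
        assert out.values.sum() == pytest.approx(x.sum(), rel=0.01)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(InvalidInputError):
            smooth_envelope(self._env(np.ones(10)), 1.0)


class TestDetectSounds:
    def _env(self, values, fs=1000.0):
        values = np.asarray(values, dtype=float)
        return SSEEnvelope(values, np.arange(values.size) / fs)

    def test_structureless_envelopes_yield_nothing(self):
        # constant envelope: nothing rises above the adaptive threshold
        assert detect_sounds(self._env(np.full(2000, 0.7))) == []
        assert detect_sounds(self._env(np.zeros(2000))) == []
        # a single excursion shorter than min_dur is discarded
        v = np.zeros(2000)
        v[1000:1020] = 1.0  # 20 ms < 40 ms minimum
        assert detect_sounds(self._env(v)) == []

    def test_two_close_bursts_merge(self):
        v = np.zeros(1000)
        v[300:350] = 1.0
        v[360:410] = 1.0  # 10 ms gap < 15 ms min_gap
        segs = detect_sounds(self._env(v))
        assert len(segs) == 1

    def test_output_is_ordered_bounded_nonoverlapping(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            v = np.abs(rng.standard_normal(3000)) * (rng.random(3000) > 0.7)
            segs = detect_sounds(self._env(v))
            for a, b in zip(segs, segs[1:]):
                assert a.offset <= b.onset
            for s in segs:
                assert 0.04 - 1e-9 <= s.duration <= 0.25 + 1e-9

    def test_clean_beats_are_located_accurately(self, clean_recording):
        """Four noiseless resting beats: all 8 sounds found, onsets within
        25 ms of the generator's ground truth."""
        segs = segment_recording(clean_recording.signal)
        assert len(segs) == 8
        matches, fps, missed = match_segments(segs, clean_recording.annotations)
        assert len(matches) == 8 and not fps and not missed
        for det, tru in matches:
            assert abs(det.onset - tru.onset) < 0.025

    def test_parameter_validation(self):
        env = self._env(np.ones(100))
        with pytest.raises(InvalidInputError):
            detect_sounds(env, thresh_frac=1.5)
        with pytest.raises(InvalidInputError):
            detect_sounds(env, min_dur=0.3, max_dur=0.2)


class TestSerialization:
    SEGS = [
        SoundSegment(0.1234567890123, 0.2987654321098, "S1"),
        SoundSegment(0.5, 0.6111111111111111, "S2"),
        SoundSegment(1.0 / 3.0, 0.42, "unknown"),
    ]

    def test_csv_round_trip_is_bit_exact(self, tmp_path):
        path = tmp_path / "segs.csv"
        write_segments_csv(path, self.SEGS)
        back = read_segments_csv(path)
        assert [(s.onset, s.offset, s.label) for s in back] == [
            (s.onset, s.offset, s.label) for s in self.SEGS
        ]

    def test_json_round_trip_is_bit_exact(self, tmp_path):
        path = tmp_path / "segs.json"
        write_segments_json(path, self.SEGS)
        back = read_segments_json(path)
        assert [(s.onset, s.offset, s.label) for s in back] == [
            (s.onset, s.offset, s.label) for s in self.SEGS
        ]

    def test_invalid_segment_rejected(self):
        with pytest.raises(InvalidInputError):
            SoundSegment(0.5, 0.4)
        with pytest.raises(InvalidInputError):
            SoundSegment(0.1, 0.2, "S3")
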