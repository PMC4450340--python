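"""Shared fixtures and reference (oracle) implementations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stresspcg import (
    BenchmarkConfig,
    SyntheticBeatConfig,
    TimeSignal,
    generate_recording,
    run_benchmark,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def direct_s_transform(
    x: np.ndarray, fs: float, alpha: float, freqs: np.ndarray, reps: int = 8
) -> np.ndarray:
    """Slow reference transform: direct Riemann-sum integration of the
    defining time-domain integral, with the unit-area Gaussian window
    wrapped periodically (the FFT algorithm is circular).  Independent of
    the production FFT path; O(n_freq * n^2)."""
    n = x.size
    dt = 1.0 / fs
    t = np.arange(n) * dt
    total = n * dt
    out = np.zeros((len(freqs), n), dtype=complex)
    for i, f in enumerate(freqs):
        sigma = alpha / f
        phase = x * np.exp(-2j * np.pi * f * t)
        for j in range(n):
            w = np.zeros(n)
            for rep in range(-reps, reps + 1):
                w += np.exp(-0.5 * ((t - t[j] + rep * total) / sigma) ** 2)
            w /= sigma * np.sqrt(2.0 * np.pi)
            out[i, j] = np.sum(phase * w) * dt
    return out


def brute_force_auc(scores, labels) -> float:
    """Pair-counting AUC oracle: fraction of (positive, negative) pairs
    where the positive outscores the negative, ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def clean_recording():
    """Four resting beats with no jitter or noise: 8 sounds, exact grid."""
    return generate_recording(
        4.0, SyntheticBeatConfig(hr=60.0, jitter=0.0), None, seed=3
    )


@pytest.fixture(scope="session")
def rest_and_stress_recordings():
    """One jittered recording each at 60 and 180 bpm (shared across tests)."""
    return {
        hr: generate_recording(10.0, SyntheticBeatConfig(hr=float(hr)), None, seed=11)
        for hr in (60, 180)
    }


@pytest.fixture(scope="session")
def benchmark_report():
    """The full seeded synthetic benchmark (shared by the acceptance suite).

    Covers the heart-rate ladder 60-198 bpm, six synthetic subjects, the
    10/5/0 dB noise sweep and the HR/high-frequency-ratio curve.
    """
    return run_benchmark(BenchmarkConfig(seed=1))


def make_burst(
    freq: float,
    ring: float,
    fs: float = 2000.0,
    window: float = 0.4,
    amplitude: float = 1.0,
    center: float | None = None,
) -> np.ndarray:
    """Gaussian-windowed sinusoid of effective duration ``ring`` (4 sigma)
    centred in a quiet window — the elementary heart-sound surrogate."""
    n = int(round(window * fs))
    t = np.arange(n) / fs
    c = window / 2 if center is None else center
    sigma = ring / 4.0
    return amplitude * np.exp(-0.5 * ((t - c) / sigma) ** 2) * np.sin(
        2 * np.pi * freq * (t - c)
    )


def s1_like_signal(fs: float = 2000.0) -> TimeSignal:
    """Booming multi-component low-frequency transient (S1 surrogate)."""
    x = (
        make_burst(38.0, 0.065, fs, center=0.16)
        + 0.85 * make_burst(55.0, 0.055, fs, center=0.21)
    )
    return TimeSignal(x, fs)


def s2_like_signal(fs: float = 2000.0) -> TimeSignal:
    """Short sharp higher-pitched snap (S2 surrogate)."""
    x = make_burst(95.0, 0.028, fs, center=0.18) + 0.5 * make_burst(
        130.0, 0.02, fs, center=0.215
    )
    return TimeSignal(x, fs)
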