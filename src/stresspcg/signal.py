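"""Sampled audio container and WAV input/output.

A phonocardiogram is a single-channel pressure signal recorded at the chest
wall.  Heart sounds carry essentially all of their energy below ~200 Hz, so
recordings made at audio rates (typically 44.1–48 kHz) are decimated to a
2 kHz working rate before time-frequency analysis; the decimator applies a
polyphase anti-aliasing filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import InvalidInputError

#: Internal working sampling rate (Hz) for heart-sound analysis.
DEFAULT_WORKING_RATE = 2000.0


@dataclass(frozen=True)
class TimeSignal:
    """A finite, uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        1-D float array of amplitudes (arbitrary units).
    sampling_rate : float
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise InvalidInputError("samples must be one-dimensional")
        if samples.size < 2:
            raise InvalidInputError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("samples must all be finite")
        if not (np.isfinite(self.sampling_rate) and self.sampling_rate > 0):
            raise InvalidInputError("sampling_rate must be positive and finite")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample instants in seconds, starting at 0."""
        return np.arange(self.n) / self.sampling_rate

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    def slice_time(self, t0: float, t1: float) -> "TimeSignal":
        """Extract the sub-signal covering [t0, t1] seconds (inclusive bounds,
        clipped to the recording)."""
        if t1 <= t0:
            raise InvalidInputError(f"empty time slice [{t0}, {t1}]")
        i0 = max(0, int(np.floor(t0 * self.sampling_rate)))
        i1 = min(self.n, int(np.ceil(t1 * self.sampling_rate)) + 1)
        if i1 - i0 < 2:
            raise InvalidInputError("time slice contains fewer than 2 samples")
        return TimeSignal(self.samples[i0:i1], self.sampling_rate)


def decimate_to(signal: TimeSignal, target_rate: float = DEFAULT_WORKING_RATE) -> TimeSignal:
    """Resample ``signal`` down to ``target_rate`` with anti-alias filtering.

    Signals already at or below the target rate are returned unchanged.  The
    rational resampling factor is realised with a polyphase FIR filter
    (:func:`scipy.signal.resample_poly`), which low-passes below the new
    Nyquist frequency before decimation.
    """
    if target_rate <= 0:
        raise InvalidInputError("target_rate must be positive")
    if signal.sampling_rate <= target_rate:
        return signal
    ratio = Fraction(target_rate / signal.sampling_rate).limit_denominator(10_000)
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    actual_rate = signal.sampling_rate * ratio.numerator / ratio.denominator
    return TimeSignal(out, actual_rate)


def read_wav(path: str | Path) -> TimeSignal:
    """Read a mono WAV file (PCM 16/24/32-bit or float) as a :class:`TimeSignal`.

    Integer PCM is rescaled to [-1, 1); stereo files are rejected.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise InvalidInputError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return TimeSignal(samples, float(rate))


def write_wav(path: str | Path, signal: TimeSignal, *, normalize: bool = True) -> None:
    """Write ``signal`` as 16-bit PCM WAV.

    With ``normalize`` (default) the waveform is scaled so its peak sits at
    ~0.999 full scale, preserving shape; quantization is to 16-bit precision.
    """
    x = signal.samples
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    if normalize and peak > 0:
        x = x / peak * 0.999
    x = np.clip(x, -1.0, 0.999969482421875)
    pcm = np.round(x * 32768.0).astype(np.int16)
    wavfile.write(str(path), int(round(signal.sampling_rate)), pcm)
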