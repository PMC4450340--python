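"""Synthetic stress-test phonocardiograms with ground-truth annotations.

Real stress-test PCG corpora with beat-level ECG-verified labels are rarely
shareable, so this module generates annotated surrogates with the
statistical structure such recordings exhibit:

* each beat carries an S1 at its start and an S2 at the systolic fraction
  of the beat period;
* S1 is longer (~120 ms), lower pitched (30–80 Hz) and multi-component;
  S2 is shorter (~70 ms), higher pitched (60–150 Hz) and simpler;
* systole occupies ~35% of the beat at rest and converges toward ~50% as
  heart rate approaches 200 bpm — exactly the regime where interval-based
  S1/S2 discrimination breaks down;
* as heart rate rises, S2's amplitude and center frequencies soften
  (``hr_hf_coupling``), reproducing the observed decline of the S2/S1
  high-frequency-content ratio under stress;
* optional additive white Gaussian noise at a prescribed SNR.

Each sound component is a Gaussian-windowed sinusoid — a minimal transient
whose S-transform is analytically predictable, which keeps the generator
useful as a test oracle.  Generation is a pure function of (config, seed):
identical inputs reproduce the waveform bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .segmentation import SoundSegment, write_segments_csv, write_segments_json
from .signal import TimeSignal, write_wav

#: Heart-rate ladder mirroring a workload-stepped stress protocol, capped at
#: the ~198 bpm maximum such tests reach.
DEFAULT_HR_LADDER = (60.0, 90.0, 120.0, 150.0, 180.0, 198.0)


@dataclass(frozen=True)
class BeatComponent:
    """One Gaussian-windowed sinusoid inside a heart sound.

    ``duration`` is the effective width (4 sigma); ``center_offset`` places
    the component's center relative to the sound's onset.
    """

    center_freq: float  # Hz
    duration: float  # s
    amplitude: float  # relative
    center_offset: float  # s


#: Default S1: three sustained, booming low-frequency components (the
#: mitral/tricuspid closure complex rings for tens of milliseconds),
#: 30-80 Hz, ~125 ms total span.
DEFAULT_S1_COMPONENTS = (
    BeatComponent(32.0, 0.065, 1.00, 0.038),
    BeatComponent(52.0, 0.050, 0.85, 0.072),
    BeatComponent(42.0, 0.045, 0.50, 0.102),
)
#: Default S2: two short sharp snaps (aortic then pulmonary closure), higher
#: pitched (90-130 Hz) with much shorter ring time than S1's components,
#: ~62 ms total span, softer than S1.
DEFAULT_S2_COMPONENTS = (
    BeatComponent(92.0, 0.026, 0.75, 0.024),
    BeatComponent(130.0, 0.018, 0.45, 0.063),
)


def _span(components: Sequence[BeatComponent]) -> tuple[float, float]:
    """[start, end] of the sound relative to its onset (centers +/- 2 sigma)."""
    starts = [c.center_offset - c.duration / 2 for c in components]
    ends = [c.center_offset + c.duration / 2 for c in components]
    return min(starts), max(ends)


@dataclass(frozen=True)
class SyntheticBeatConfig:
    """Parameters of one synthetic cardiac cycle.

    ``jitter`` is the coefficient of variation applied per beat to the beat
    period, component timings, amplitudes and frequencies.
    ``hr_hf_coupling`` scales how strongly S2's amplitude and pitch soften
    as heart rate rises above rest (0 disables the effect).
    ``hr_duration_coupling`` compresses both sounds in time as heart rate
    rises — at high rates valve closure is brisker and the sounds shorten,
    which is also what keeps S1 clear of S2 when systole shrinks.
    ``systole_fraction=None`` selects the physiological default: 0.35 at
    60 bpm rising linearly to 0.5 at 200 bpm.
    """

    hr: float = 60.0
    s1_components: tuple[BeatComponent, ...] = DEFAULT_S1_COMPONENTS
    s2_components: tuple[BeatComponent, ...] = DEFAULT_S2_COMPONENTS
    systole_fraction: float | None = None
    jitter: float = 0.15
    hr_hf_coupling: float = 0.3
    hr_duration_coupling: float = 0.3
    sampling_rate: float = 2000.0

    def __post_init__(self) -> None:
        if not (40.0 <= self.hr <= 220.0):
            raise ConfigurationError(f"hr must lie in [40, 220] bpm, got {self.hr}")
        if self.systole_fraction is not None and not (
            0.2 <= self.systole_fraction <= 0.6
        ):
            raise ConfigurationError("systole_fraction must lie in [0.2, 0.6]")
        if self.jitter < 0 or self.hr_hf_coupling < 0 or self.hr_duration_coupling < 0:
            raise ConfigurationError("jitter and coupling slopes must be >= 0")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        for comps, name in ((self.s1_components, "s1"), (self.s2_components, "s2")):
            if not comps:
                raise ConfigurationError(f"{name}_components must be nonempty")
            for c in comps:
                if c.duration <= 0 or c.center_freq <= 0 or c.amplitude <= 0:
                    raise ConfigurationError(f"invalid {name} component {c}")

    @property
    def beat_period(self) -> float:
        return 60.0 / self.hr

    def resolved_systole_fraction(self) -> float:
        """Systole/beat fraction: 0.35 at rest converging to 0.5 at 200 bpm."""
        if self.systole_fraction is not None:
            return self.systole_fraction
        frac = 0.35 + 0.15 * np.clip((self.hr - 60.0) / 140.0, 0.0, 1.0)
        return float(frac)

    def s2_softening(self) -> tuple[float, float]:
        """(frequency, amplitude) multipliers (<= 1) for S2 at this HR.

        Both ramp linearly from rest (60 bpm) with slope ``hr_hf_coupling``;
        the pitch drops with the full slope (the observed loss of S2
        high-frequency content under stress) while the amplitude is dimmed
        at only half that slope — under exercise S2 loses treble, not
        loudness.  Both factors are floored at 0.3."""
        ramp = max(0.0, (self.hr - 60.0) / 140.0)
        freq = float(np.clip(1.0 - self.hr_hf_coupling * ramp, 0.3, 1.0))
        amp = float(np.clip(1.0 - 0.5 * self.hr_hf_coupling * ramp, 0.3, 1.0))
        return freq, amp

    def time_compression(self) -> float:
        """Multiplier (<= 1) on component durations and offsets at this HR."""
        ramp = max(0.0, (self.hr - 60.0) / 140.0)
        return float(np.clip(1.0 - self.hr_duration_coupling * ramp, 0.5, 1.0))


def vary_morphology(
    config: SyntheticBeatConfig,
    seed: int,
    *,
    cv_freq: float = 0.15,
    cv_dur: float = 0.20,
    cv_amp: float = 0.20,
) -> SyntheticBeatConfig:
    """Derive a per-subject sound morphology from ``config``.

    Real subjects differ in chest-wall transmission and valve mechanics, so
    component center frequencies, ring times and relative amplitudes vary
    between individuals far more than between a subject's own beats.  Each
    component parameter is scaled by a lognormal-like factor (1 + cv * z,
    floored at 0.5) drawn once per subject; the same morphology then holds
    across that subject's whole workload ladder.
    """
    rng = np.random.default_rng(seed)

    def perturb(components: tuple[BeatComponent, ...]) -> tuple[BeatComponent, ...]:
        out = []
        for c in components:
            f = c.center_freq * max(0.5, 1.0 + cv_freq * rng.standard_normal())
            d = c.duration * max(0.5, 1.0 + cv_dur * rng.standard_normal())
            a = c.amplitude * max(0.5, 1.0 + cv_amp * rng.standard_normal())
            out.append(BeatComponent(f, d, a, c.center_offset))
        return tuple(out)

    return replace(
        config,
        s1_components=perturb(config.s1_components),
        s2_components=perturb(config.s2_components),
    )


def _render_components(
    t: np.ndarray,
    components: Sequence[BeatComponent],
    group_onset: float,
    rng: np.random.Generator,
    jitter: float,
    freq_scale: float = 1.0,
    amp_scale: float = 1.0,
    time_scale: float = 1.0,
) -> tuple[np.ndarray, float, float]:
    """Sum Gaussian-windowed sinusoids; returns (waveform, onset, offset)."""
    wave = np.zeros_like(t)
    starts, ends = [], []
    for comp in components:
        jit = lambda v: v * max(0.2, 1.0 + jitter * rng.standard_normal())
        freq = jit(comp.center_freq) * freq_scale
        amp = jit(comp.amplitude) * amp_scale
        dur = jit(comp.duration) * time_scale
        center = group_onset + jit(comp.center_offset) * time_scale
        sigma = dur / 4.0
        envelope = np.exp(-0.5 * ((t - center) / sigma) ** 2)
        wave += amp * envelope * np.sin(2.0 * np.pi * freq * (t - center))
        starts.append(center - 2.0 * sigma)
        ends.append(center + 2.0 * sigma)
    return wave, min(starts), max(ends)


def generate_beat(
    config: SyntheticBeatConfig, rng: np.random.Generator
) -> tuple[TimeSignal, tuple[SoundSegment, SoundSegment]]:
    """Render one beat: waveform over a full beat period plus its two truths.

    S1 starts at the beat onset; S2 at ``systole_fraction x period``.  The
    returned segments carry true labels and onsets relative to beat start.
    Raises :class:`ConfigurationError` if the nominal layout would overlap
    sounds at this heart rate.
    """
    period = config.beat_period
    fs = config.sampling_rate
    sysfrac = config.resolved_systole_fraction()
    tscale = config.time_compression()
    s1_start, s1_end = (x * tscale for x in _span(config.s1_components))
    s2_start, s2_end = (x * tscale for x in _span(config.s2_components))
    s2_onset = sysfrac * period
    soft_freq, soft_amp = config.s2_softening()
    if s1_end >= s2_onset + s2_start:
        raise ConfigurationError(
            f"S1 (ends {s1_end:.3f}s) overlaps S2 (starts {s2_onset + s2_start:.3f}s) "
            f"at {config.hr:.0f} bpm"
        )
    if s2_onset + s2_end > period:
        raise ConfigurationError(
            f"S2 extends past the beat period ({period:.3f}s) at {config.hr:.0f} bpm"
        )

    n = int(round(period * fs))
    t = np.arange(n) / fs
    pad = 0.01  # small onset pad so S1 never precedes t=0
    s1_wave, s1_on, s1_off = _render_components(
        t, config.s1_components, pad, rng, config.jitter, time_scale=tscale
    )
    s2_wave, s2_on, s2_off = _render_components(
        t, config.s2_components, s2_onset, rng, config.jitter,
        freq_scale=soft_freq, amp_scale=soft_amp, time_scale=tscale,
    )
    wave = s1_wave + s2_wave
    if s1_off >= s2_on:  # jitter pushed the sounds together; keep truth ordered
        mid = 0.5 * (s1_off + s2_on)
        s1_off, s2_on = mid - 1e-3, mid + 1e-3
    seg1 = SoundSegment(max(0.0, s1_on), s1_off, "S1")
    seg2 = SoundSegment(s2_on, min(s2_off, period - 1.0 / fs), "S2")
    return TimeSignal(wave, fs), (seg1, seg2)


@dataclass(frozen=True)
class SyntheticRecording:
    """A generated recording, its ground truth, and how it was made."""

    signal: TimeSignal
    annotations: tuple[SoundSegment, ...]
    config: SyntheticBeatConfig
    snr_db: float | None
    seed: int

    def measured_snr_db(self, clean: TimeSignal) -> float:
        """Realized SNR (dB) against the provided clean waveform."""
        noise = self.signal.samples - clean.samples
        p_noise = float(np.mean(noise**2))
        if p_noise == 0:
            return np.inf
        p_sig = float(np.mean(clean.samples**2))
        return 10.0 * np.log10(p_sig / p_noise)


def generate_recording(
    duration: float = 10.0,
    config: SyntheticBeatConfig | None = None,
    snr_db: float | None = None,
    seed: int = 0,
) -> SyntheticRecording:
    """Concatenate beats to fill ``duration`` seconds, optionally add noise.

    Beats are generated until the next full beat would overrun the duration;
    the remainder is silence.  With ``snr_db`` set, white Gaussian noise is
    added with power ``P_signal / 10^(snr_db/10)`` measured over the whole
    clean record.  Annotations alternate S1, S2, ... and never overlap.
    """
    config = config or SyntheticBeatConfig()
    if duration < config.beat_period:
        raise InvalidInputError("duration must cover at least one beat period")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n_total = int(round(duration * fs))
    samples = np.zeros(n_total)
    annotations: list[SoundSegment] = []

    t0 = 0.0
    while True:
        period = config.beat_period
        if config.jitter > 0:
            period *= max(0.5, 1.0 + config.jitter * rng.standard_normal())
        if t0 + period > duration + 1e-9:
            break
        beat_cfg = config if period == config.beat_period else replace(
            config, hr=float(np.clip(60.0 / period, 40.0, 220.0))
        )
        beat, (seg1, seg2) = generate_beat(beat_cfg, rng)
        i0 = int(round(t0 * fs))
        i1 = min(n_total, i0 + beat.n)
        samples[i0:i1] += beat.samples[: i1 - i0]
        annotations.append(SoundSegment(seg1.onset + t0, seg1.offset + t0, "S1"))
        annotations.append(SoundSegment(seg2.onset + t0, seg2.offset + t0, "S2"))
        t0 += period

    if not annotations:
        raise InvalidInputError("duration too short to fit a single beat")

    if snr_db is not None:
        p_sig = float(np.mean(samples**2))
        sigma = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
        samples = samples + sigma * rng.standard_normal(n_total)

    return SyntheticRecording(
        TimeSignal(samples, fs), tuple(annotations), config, snr_db, seed
    )


def write_recording(
    rec: SyntheticRecording,
    wav_path: str | Path,
    annotations_path: str | Path | None = None,
) -> None:
    """Write the waveform as 16-bit WAV plus a sidecar annotation file.

    The sidecar format follows its extension (.csv or .json) and matches the
    segmentation module's segment schema exactly.
    """
    write_wav(wav_path, rec.signal)
    if annotations_path is None:
        annotations_path = Path(wav_path).with_suffix(".segments.csv")
    annotations_path = Path(annotations_path)
    if annotations_path.suffix == ".json":
        write_segments_json(annotations_path, rec.annotations)
    else:
        write_segments_csv(annotations_path, rec.annotations)
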