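"""Heart-sound localization via the Shannon-energy envelope of the S-matrix.

The SSE envelope condenses the S-transform into one nonnegative value per
time column:

    SSE(tau) = - sum_f |S(tau, f)|^n log |S(tau, f)|^n  df

with magnitudes first normalized by the global matrix maximum so every
coefficient lies in [0, 1] (making each -v log v term nonnegative) and with
the 0 log 0 := 0 convention.  The exponent n defaults to 1.5 rather than
the classical Shannon value 2: for magnitudes below 1, v^1.5 decays more
slowly than v^2, so faint sounds — typically S2 at high heart rate — are
attenuated less relative to loud ones and survive thresholding.

The envelope is smoothed with a centered moving average, thresholded at a
fraction of a robust scale (the 98th percentile, immune to single spikes),
and maximal above-threshold runs become candidate sound segments subject to
physiological duration and gap constraints.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, DomainError, InvalidInputError
from .signal import DEFAULT_WORKING_RATE, TimeSignal, decimate_to
from .stockwell import DEFAULT_MAX_FREQ, STMatrix, s_transform

if TYPE_CHECKING:  # pragma: no cover
    from .features import FeatureVector

#: Default Shannon-energy exponent.
DEFAULT_EXPONENT = 1.5
#: Default moving-average smoothing window (s).
DEFAULT_SMOOTH_S = 0.02
#: Physiological duration / spacing defaults (s).
DEFAULT_MIN_DUR = 0.04
DEFAULT_MAX_DUR = 0.25
#: Minimum envelope gap between distinct sounds.  Under stress the systolic
#: S1->S2 gap shrinks to ~25 ms, so the merge distance must sit below it.
DEFAULT_MIN_GAP = 0.015
#: Segmentation envelope band floor (Hz).  Rejects baseline rumble and,
#: because a voice at frequency f smears time by sigma = alpha/f, bounds the
#: S-transform's temporal smear so the envelope still dips between S1 and S2
#: in short-systole (high heart rate) beats.
DEFAULT_ENV_MIN_FREQ = 50.0
#: Default threshold as a fraction of the 98th-percentile envelope scale.
DEFAULT_THRESH_FRAC = 0.2


@dataclass(frozen=True)
class SSEEnvelope:
    """Nonnegative Shannon-energy envelope over time."""

    values: np.ndarray
    times: np.ndarray
    exponent_n: float = DEFAULT_EXPONENT
    smooth_len: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        if values.size != times.size:
            raise InvalidInputError("values and times must have equal length")
        if values.size == 0:
            raise InvalidInputError("empty envelope")
        if np.any(values < -1e-12):
            raise InvalidInputError("envelope values must be nonnegative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0


@dataclass
class SoundSegment:
    """A located heart sound: [onset, offset] in seconds plus a label."""

    onset: float
    offset: float
    label: str = "unknown"
    features: "FeatureVector | None" = None

    VALID_LABELS = ("S1", "S2", "unknown")

    def __post_init__(self) -> None:
        self.onset = float(self.onset)
        self.offset = float(self.offset)
        if not (0 <= self.onset < self.offset):
            raise InvalidInputError(
                f"need 0 <= onset < offset, got [{self.onset}, {self.offset}]"
            )
        if self.label not in self.VALID_LABELS:
            raise InvalidInputError(f"label must be one of {self.VALID_LABELS}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def overlap(self, other: "SoundSegment") -> float:
        """Length (s) of the intersection with ``other``."""
        return max(0.0, min(self.offset, other.offset) - max(self.onset, other.onset))


def shannon_energy_columns(matrix: np.ndarray, exponent_n: float, df: float) -> np.ndarray:
    """Per-column Shannon energy of a nonnegative matrix.

    The matrix is normalized by its global maximum; each column tau then
    contributes -sum_f v^n log(v^n) * df with 0 log 0 := 0.  Shared by the
    segmentation envelope (on |S|) and the kurtosis feature (on the
    normalized ST-spectrogram).
    """
    if exponent_n <= 0:
        raise DomainError("exponent n must be positive")
    peak = float(matrix.max(initial=0.0))
    if peak <= 0:
        raise DegenerateInputError("all-zero matrix has no Shannon-energy envelope")
    v = np.asarray(matrix, dtype=np.float64) / peak
    p = v**exponent_n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=0) * df


def sse_envelope(st: STMatrix, exponent_n: float = DEFAULT_EXPONENT) -> SSEEnvelope:
    """Shannon-energy envelope of an S-transform matrix (DC row excluded)."""
    mags = st.magnitudes(exclude_dc=True)
    if mags.size == 0:
        raise DegenerateInputError("matrix has no nonzero-frequency rows")
    values = shannon_energy_columns(mags, exponent_n, st.df)
    return SSEEnvelope(values, st.times, exponent_n, 0.0)


def smooth_envelope(env: SSEEnvelope, window_s: float = DEFAULT_SMOOTH_S) -> SSEEnvelope:
    """Centered moving average with reflective edge padding.

    Output length equals input length; the window is forced to an odd sample
    count so the filter is symmetric.
    """
    if window_s <= 0:
        raise InvalidInputError("window_s must be positive")
    w = max(1, int(round(window_s / env.dt)))
    if w % 2 == 0:
        w += 1
    n = env.values.size
    if w > n:
        raise InvalidInputError(
            f"smoothing window of {w} samples exceeds envelope length {n}"
        )
    if w == 1:
        return replace(env, smooth_len=window_s)
    half = w // 2
    padded = np.pad(env.values, half, mode="reflect")
    smoothed = np.convolve(padded, np.full(w, 1.0 / w), mode="valid")
    return SSEEnvelope(smoothed, env.times, env.exponent_n, window_s)


def detect_sounds(
    env: SSEEnvelope,
    min_dur: float = DEFAULT_MIN_DUR,
    max_dur: float = DEFAULT_MAX_DUR,
    min_gap: float = DEFAULT_MIN_GAP,
    thresh_frac: float = DEFAULT_THRESH_FRAC,
) -> list[SoundSegment]:
    """Pick candidate heart sounds from a (smoothed) SSE envelope.

    The envelope's median — a robust estimate of its stationary noise
    floor, since heart sounds occupy well under half of any recording — is
    subtracted first, so additive background noise does not lift the whole
    envelope over the threshold and bridge distinct sounds.  The threshold
    is then ``thresh_frac`` times the 98th percentile of the floor-corrected
    envelope — a robust per-recording scale.  Maximal above-threshold runs
    are found and their boundaries relaxed outward while the envelope stays
    above half the threshold (dual-threshold hysteresis, which recovers the
    low-energy onset/offset skirts of each sound); runs separated by less
    than ``min_gap`` then merge (a multi-lobed sound is one sound), runs
    shorter than ``min_dur`` are dropped, and runs longer than ``max_dur``
    are truncated symmetrically about their envelope peak.  The result is
    time-ordered, non-overlapping and may legitimately be empty.
    """
    if not (0 < thresh_frac < 1):
        raise InvalidInputError("thresh_frac must lie in (0, 1)")
    if not (0 < min_dur < max_dur):
        raise InvalidInputError("need 0 < min_dur < max_dur")
    if min_gap < 0:
        raise InvalidInputError("min_gap must be nonnegative")

    v = np.maximum(env.values - float(np.median(env.values)), 0.0)
    dt = env.dt
    scale = float(np.percentile(v, 98))
    if scale <= 0:
        return []
    threshold = thresh_frac * scale
    above = v > threshold
    if not above.any():
        return []

    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1) if edges.size else []
    ends = list(edges[above[edges]] + 1) if edges.size else []
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(v.size)
    runs = list(zip(starts, ends))  # half-open sample index runs

    # 1. hysteresis: relax boundaries outward above the lower threshold
    low = 0.5 * threshold
    relaxed = []
    for s, e in runs:
        while s > 0 and v[s - 1] > low:
            s -= 1
        while e < v.size and v[e] > low:
            e += 1
        relaxed.append((s, e))
    runs = relaxed

    # 2. merge runs separated by < min_gap (hysteresis may abut or overlap runs)
    merged: list[list[int]] = []
    gap_n = min_gap / dt
    for s, e in runs:
        if merged and (s - merged[-1][1]) < gap_n:
            merged[-1][1] = max(e, merged[-1][1])
        else:
            merged.append([s, e])

    # 3. drop runs shorter than min_dur
    min_n = min_dur / dt
    kept = [(s, e) for s, e in merged if (e - s) >= min_n]

    # 4. truncate runs longer than max_dur symmetrically about their peak,
    #    clamped so recentred runs never back into their predecessor
    max_n = int(round(max_dur / dt))
    segments: list[SoundSegment] = []
    t0 = float(env.times[0])
    prev_end = 0
    for s, e in kept:
        if e - s > max_n:
            peak = s + int(np.argmax(v[s:e]))
            half = max_n // 2
            s = max(s, peak - half)
            e = min(v.size, s + max_n)
            s = max(0, e - max_n)
        s = max(s, prev_end)
        if e - s < min_dur / dt:
            continue
        prev_end = e
        segments.append(
            SoundSegment(onset=t0 + s * dt, offset=t0 + (e - 1) * dt)
        )
    return segments


def segment_recording(
    signal: TimeSignal,
    *,
    alpha: float = 1.0,
    exponent_n: float = DEFAULT_EXPONENT,
    max_freq: float = DEFAULT_MAX_FREQ,
    min_freq: float = DEFAULT_ENV_MIN_FREQ,
    working_rate: float = DEFAULT_WORKING_RATE,
    envelope_df: float = 2.0,
    smooth_s: float = DEFAULT_SMOOTH_S,
    min_dur: float = DEFAULT_MIN_DUR,
    max_dur: float = DEFAULT_MAX_DUR,
    min_gap: float = DEFAULT_MIN_GAP,
    thresh_frac: float = DEFAULT_THRESH_FRAC,
) -> list[SoundSegment]:
    """End-to-end localization: decimate, transform, envelope, smooth, pick.

    ``envelope_df`` sets the frequency spacing (Hz) of the voices used for
    the envelope; 2 Hz is ample resolution for 20–250 Hz heart sounds and
    keeps long recordings cheap.
    """
    work = decimate_to(signal, working_rate)
    native_df = work.sampling_rate / work.n
    step = max(1, int(round(envelope_df / native_df)))
    st = s_transform(work, alpha, max_freq, freq_step=step, include_dc=False)
    env = sse_envelope(st.band(min_freq, max_freq), exponent_n)
    env = smooth_envelope(env, smooth_s)
    return detect_sounds(env, min_dur, max_dur, min_gap, thresh_frac)


# ---------------------------------------------------------------------------
# Segment list serialization (CSV and JSON, bit-exact round trip)
# ---------------------------------------------------------------------------

def write_segments_csv(path: str | Path, segments: Iterable[SoundSegment]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_s", "offset_s", "label"])
        for seg in segments:
            writer.writerow([repr(seg.onset), repr(seg.offset), seg.label])


def read_segments_csv(path: str | Path) -> list[SoundSegment]:
    segments = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            segments.append(
                SoundSegment(float(row["onset_s"]), float(row["offset_s"]), row["label"])
            )
    return segments


def write_segments_json(path: str | Path, segments: Iterable[SoundSegment]) -> None:
    payload = [
        {"onset_s": seg.onset, "offset_s": seg.offset, "label": seg.label}
        for seg in segments
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_segments_json(path: str | Path) -> list[SoundSegment]:
    payload = json.loads(Path(path).read_text())
    return [
        SoundSegment(item["onset_s"], item["offset_s"], item["label"])
        for item in payload
    ]
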