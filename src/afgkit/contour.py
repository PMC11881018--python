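"""Speech pitch-contour processing and synthesis.

A pitch contour is a fundamental-frequency (F0) trajectory sampled on a
regular frame grid (100 frames/s by default), with unvoiced frames marked as
gaps.  The module cleans raw pitch-tracker output (out-of-band artifact
removal), conjoins voiced stretches into one continuous trajectory, smooths
the seams left by gap removal, and averages the trajectory into 50 ms chord
values that drive the dynamic figure-ground stimuli.  A seeded synthetic
generator produces sentence-like contours (slow modulation over a mild
downward declination) matching the descriptive statistics of F0 tracks
extracted from read English sentences: range 74.94-295.44 Hz, mean
131.59 Hz, s.d. 15.61 Hz.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "PitchContour",
    "ChordF0Series",
    "ContourStats",
    "EmptyContourError",
    "ContourTooShortError",
    "default_contour_stats",
    "strip_artifacts",
    "conjoin_voiced",
    "smooth_contour",
    "chunk_to_chords",
    "synth_contour",
    "read_contour_csv",
    "write_contour_csv",
]


class EmptyContourError(ValueError):
    """Raised when an operation would leave no voiced frame."""


class ContourTooShortError(ValueError):
    """Raised when a contour is too short for the requested operation."""


@dataclass(frozen=True)
class PitchContour:
    """An F0 trajectory on a regular frame grid.

    Parameters
    ----------
    f0 : ndarray of float
        One value per frame, in Hz.  Unvoiced frames are ``nan``.
    frame_rate : float
        Frames per second (default 100, i.e. one pitch value per 10 ms).
    source_id : str
        Opaque label identifying the source sentence or generator draw.
    """

    f0: np.ndarray
    frame_rate: float = 100.0
    source_id: str = ""

    def __post_init__(self) -> None:
        f0 = np.asarray(self.f0, dtype=float)
        object.__setattr__(self, "f0", f0)
        if f0.ndim != 1:
            raise ValueError("f0 must be one-dimensional")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        voiced = f0[~np.isnan(f0)]
        if voiced.size and np.any(voiced <= 0):
            raise ValueError("voiced F0 values must be positive")

    @property
    def n_frames(self) -> int:
        return self.f0.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def voiced_mask(self) -> np.ndarray:
        return ~np.isnan(self.f0)

    @property
    def is_gap_free(self) -> bool:
        return bool(self.voiced_mask.all()) and self.n_frames > 0

    @property
    def gap_fraction(self) -> float:
        if self.n_frames == 0:
            return 0.0
        return float(np.isnan(self.f0).mean())


@dataclass(frozen=True)
class ChordF0Series:
    """Per-chord figure F0 values: one frequency per 50 ms chord."""

    f0_per_chord: np.ndarray
    chord_ms: float = 50.0
    source_id: str = ""

    def __post_init__(self) -> None:
        f0 = np.asarray(self.f0_per_chord, dtype=float)
        object.__setattr__(self, "f0_per_chord", f0)
        if f0.ndim != 1 or f0.size < 1:
            raise ValueError("f0_per_chord must be a non-empty 1-d sequence")
        if np.any(~np.isfinite(f0)) or np.any(f0 <= 0):
            raise ValueError("chord F0 values must be finite and positive")
        if self.chord_ms <= 0:
            raise ValueError("chord_ms must be positive")

    @property
    def n_chords(self) -> int:
        return self.f0_per_chord.size


@dataclass(frozen=True)
class ContourStats:
    """Descriptive statistics a contour population should match."""

    f_min: float = 74.94
    f_max: float = 295.44
    mean: float = 131.59
    sd: float = 15.61
    gap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.f_min <= self.mean <= self.f_max):
            raise ValueError("require f_min <= mean <= f_max")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not (0 <= self.gap_fraction < 1):
            raise ValueError("gap_fraction must be in [0, 1)")


def default_contour_stats() -> ContourStats:
    """Statistics of the F0 tracks the synthetic generator emulates."""
    return ContourStats()


def strip_artifacts(contour: PitchContour, lo: float = 10.0, hi: float = 300.0) -> PitchContour:
    """Mark pitch-tracker artifacts outside ``(lo, hi)`` Hz as unvoiced.

    Periodicity analysis of speech introduces spurious very low values
    (sub-10 Hz) and octave-error-like high values (above 300 Hz); both are
    removed here.  The frame grid is unchanged: stripped frames become gaps.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    f0 = contour.f0.copy()
    with np.errstate(invalid="ignore"):
        bad = (f0 <= lo) | (f0 >= hi)
    f0[bad] = np.nan
    if not np.any(~np.isnan(f0)):
        raise EmptyContourError("no voiced frame survives artifact stripping")
    return replace(contour, f0=f0)


def conjoin_voiced(contour: PitchContour, gap_bridge_ms: float = 50.0) -> PitchContour:
    """Remove unvoiced gaps, concatenating voiced runs onto one grid.

    Gaps shorter than ``gap_bridge_ms`` that sit inside a voiced stretch are
    linearly interpolated (they are usually stop closures or single dropped
    frames), while longer gaps and leading/trailing silence are deleted so
    the voiced segments abut.
    """
    f0 = contour.f0.copy()
    voiced = ~np.isnan(f0)
    if not voiced.any():
        raise EmptyContourError("contour has no voiced frames")

    max_bridge = int(round(gap_bridge_ms * contour.frame_rate / 1000.0))
    idx = np.flatnonzero(voiced)
    first, last = idx[0], idx[-1]
    # bridge short interior gaps by linear interpolation
    gap_start = None
    for i in range(first, last + 1):
        if not voiced[i]:
            if gap_start is None:
                gap_start = i
        elif gap_start is not None:
            length = i - gap_start
            if length < max_bridge:
                x0, x1 = gap_start - 1, i
                span = np.arange(gap_start, i)
                f0[span] = np.interp(span, [x0, x1], [f0[x0], f0[x1]])
            gap_start = None
    out = f0[~np.isnan(f0)]
    return replace(contour, f0=out)


def _design_lowpass(cutoff: float, stop_atten: float, fs: float) -> np.ndarray:
    """Minimum-order FIR low-pass (Kaiser) with the given stopband attenuation.

    The stopband edge follows the common convention of placing it 15% of the
    way from the cutoff to Nyquist (transition steepness 0.85).
    """
    nyq = fs / 2.0
    f_stop = cutoff + 0.15 * (nyq - cutoff)
    width = (f_stop - cutoff) / nyq
    ntaps, beta = signal.kaiserord(stop_atten, width)
    ntaps += (ntaps + 1) % 2  # force odd for a symmetric, zero-phase-able filter
    taps = signal.firwin(ntaps, cutoff, window=("kaiser", beta), fs=fs)
    return taps / taps.sum()  # exact unit DC gain


def smooth_contour(
    contour: PitchContour,
    cutoff: float = 2000.0,
    stop_atten: float = 60.0,
    upsample_rate: float = 44100.0,
) -> PitchContour:
    """Low-pass a conjoined contour to remove seam spikes, preserving drift.

    The contour is demeaned and linearly detrended, linearly interpolated up
    to ``upsample_rate``, filtered with a minimum-order FIR low-pass
    (``stop_atten`` dB stopband) at ``cutoff`` Hz applied forward and
    backward (zero phase), then sampled back onto the original frame grid
    with the trend and mean restored.  The mean is preserved exactly: the
    detrended residual is recentred after filtering before restoration.
    """
    if not contour.is_gap_free:
        raise ValueError("smooth_contour requires a gap-free contour")
    if cutoff >= upsample_rate / 2:
        raise ValueError("cutoff must be below the upsampled Nyquist frequency")

    x = contour.f0
    n = x.size
    frames = np.arange(n)
    # least-squares linear trend (incl. mean)
    coeffs = np.polyfit(frames, x, 1)
    trend = np.polyval(coeffs, frames)
    resid = x - trend

    step = contour.frame_rate / upsample_rate
    t_up = np.arange(0.0, n - 1 + 0.5 * step, step)
    resid_up = np.interp(t_up, frames, resid)

    taps = _design_lowpass(cutoff, stop_atten, upsample_rate)
    padlen = 3 * len(taps)
    if resid_up.size <= padlen:
        raise ContourTooShortError(
            f"contour too short for the smoothing filter ({resid_up.size} <= {padlen} samples)"
        )
    filtered = signal.filtfilt(taps, [1.0], resid_up)
    # back to the frame grid; recentre so the restored mean is exact
    resid_out = np.interp(frames, t_up, filtered)
    resid_out -= resid_out.mean()
    out = resid_out + trend
    return replace(contour, f0=out)


def chunk_to_chords(contour: PitchContour, chord_ms: float = 50.0) -> ChordF0Series:
    """Average a gap-free contour into consecutive ``chord_ms`` windows.

    Chord ``i`` takes the arithmetic mean of the frames falling in
    ``[i*chord_ms, (i+1)*chord_ms)``.  A trailing partial window is dropped
    when shorter than half a chord and averaged otherwise.
    """
    if not contour.is_gap_free:
        raise ValueError("chunk_to_chords requires a gap-free contour")
    if chord_ms <= 0:
        raise ValueError("chord_ms must be positive")
    frames_per_chord = chord_ms * contour.frame_rate / 1000.0
    if frames_per_chord < 1:
        raise ValueError("chord_ms is shorter than one frame")
    n = contour.n_frames
    fpc = int(round(frames_per_chord))
    n_full = n // fpc
    if n_full < 1:
        raise ContourTooShortError("contour shorter than one chord")
    means = contour.f0[: n_full * fpc].reshape(n_full, fpc).mean(axis=1)
    tail = contour.f0[n_full * fpc :]
    if tail.size >= fpc / 2.0:
        means = np.append(means, tail.mean())
    return ChordF0Series(means, chord_ms=chord_ms, source_id=contour.source_id)


def synth_contour(
    rng: np.random.Generator,
    n_chords: int,
    stats: ContourStats | None = None,
    frame_rate: float = 100.0,
    chord_ms: float = 50.0,
    source_id: str = "",
) -> PitchContour:
    """Generate a gap-free, sentence-like synthetic pitch contour.

    The contour is the sum of the target mean (jittered per sentence), a
    linear declination of 10% of the mean across the sentence (the downward
    drift of read speech), and three random-phase sinusoids with modulation
    frequencies drawn from 0.5-3 Hz.  Values are clipped into
    ``[stats.f_min, stats.f_max]``.  Deterministic for a fixed generator
    state.
    """
    stats = stats or default_contour_stats()
    if stats.f_min >= stats.f_max:
        raise ValueError("infeasible stats: f_min >= f_max")
    if n_chords < 1:
        raise ValueError("n_chords must be >= 1")
    n_frames = int(round(n_chords * chord_ms * frame_rate / 1000.0))
    t = np.arange(n_frames) / frame_rate
    dur = n_frames / frame_rate

    centre = stats.mean + rng.normal(0.0, 8.0)
    declination = stats.mean * 0.10
    drift = declination * (0.5 - t / dur)

    # split the target variance between sentence-level jitter, declination and
    # the three modulation sinusoids (var of each sinusoid = amp^2 / 2)
    mod_var = max(stats.sd**2 - 8.0**2 - declination**2 / 12.0, 9.0)
    amp = np.sqrt(2.0 * mod_var / 3.0)
    f_mod = rng.uniform(0.5, 3.0, size=3)
    phase = rng.uniform(0.0, 2 * np.pi, size=3)
    wobble = sum(amp * np.sin(2 * np.pi * f * t + ph) for f, ph in zip(f_mod, phase))

    f0 = np.clip(centre + drift + wobble, stats.f_min, stats.f_max)
    return PitchContour(f0, frame_rate=frame_rate, source_id=source_id or "synthetic")


# ---------------------------------------------------------------------------
# CSV interchange: header `time_s,f0_hz`, unvoiced frames as an empty field.


def write_contour_csv(contour: PitchContour, path_or_buf) -> None:
    """Write a contour as CSV (``time_s,f0_hz``; unvoiced rows empty)."""

    def _write(fh) -> None:
        w = csv.writer(fh)
        w.writerow(["time_s", "f0_hz"])
        for i, v in enumerate(contour.f0):
            t = i / contour.frame_rate
            w.writerow([repr(t), "" if np.isnan(v) else repr(float(v))])

    if isinstance(path_or_buf, io.IOBase):
        _write(path_or_buf)
    else:
        with open(path_or_buf, "w", newline="") as fh:
            _write(fh)


def read_contour_csv(path_or_buf, source_id: str = "") -> PitchContour:
    """Read a contour written by :func:`write_contour_csv` (exact round-trip).

    Unvoiced frames may be an empty field or ``0``.
    """

    def _read(fh) -> PitchContour:
        rows = list(csv.reader(fh))
        if not rows or rows[0][:2] != ["time_s", "f0_hz"]:
            raise ValueError("expected a contour CSV with header time_s,f0_hz")
        times, values = [], []
        for row in rows[1:]:
            if not row:
                continue
            times.append(float(row[0]))
            raw = row[1].strip() if len(row) > 1 else ""
            v = float(raw) if raw else np.nan
            values.append(np.nan if (not np.isnan(v) and v == 0.0) else v)
        if len(times) > 1:
            dt = np.diff(times)
            frame_rate = 1.0 / np.median(dt)
        else:
            frame_rate = 100.0
        return PitchContour(np.array(values), frame_rate=float(frame_rate), source_id=source_id)

    if isinstance(path_or_buf, io.IOBase):
        return _read(path_or_buf)
    with open(path_or_buf, newline="") as fh:
        return _read(fh)
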