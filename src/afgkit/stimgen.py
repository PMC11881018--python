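"""Figure-ground stimulus construction and audio rendering.

Stimuli are sequences of 50 ms "chords" of simultaneous pure tones.  The
*figure* is either a fixed set of frequencies repeating across chords
(AFG-Fixed, with a silent gap inserted in one interval of a trial) or a
harmonic complex riding on a speech pitch contour (AFG-Low: F0 x {2,3,4};
AFG-High: F0 x {5,10,20,30}).  The *ground* is a tone cloud: per chord, a
random number of tones drawn log-uniformly from the variant's frequency
range (180-7246 Hz for fixed/high, 90-3623 Hz for low).  Rendering gates
every tone with 10 ms raised-cosine ramps and mixes figure against ground at
a commanded SNR defined as the per-tone amplitude ratio in dB.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .contour import ChordF0Series, ContourStats, default_contour_stats, synth_contour, chunk_to_chords

__all__ = [
    "StimulusConfig",
    "FigureTrack",
    "GroundTrack",
    "RenderedStimulus",
    "FigureExceedsMaskError",
    "build_fixed_figure",
    "insert_gap",
    "build_dynamic_figure",
    "build_ground",
    "render_stimulus",
    "render_raw",
    "make_pattern_pair",
    "draw_dynamic_series",
    "write_wav",
    "read_wav",
]

VARIANTS = ("fixed", "dynamic_low", "dynamic_high")


class FigureExceedsMaskError(ValueError):
    """A dynamic figure component exceeds the masking frequency range."""


@dataclass(frozen=True)
class StimulusConfig:
    """All stimulus-level constants of the three figure-ground variants."""

    chord_ms: float = 50.0
    ramp_ms: float = 10.0
    sample_rate: int = 44100
    coherence: int = 3                       # figure components per chord, AFG-Fixed
    n_chords_fixed: int = 42
    gap_chords: int = 6
    gap_margin_chords: int = 5
    ground_range_high: tuple[float, float] = (180.0, 7246.0)
    ground_range_low: tuple[float, float] = (90.0, 3623.0)
    multipliers_low: tuple[int, ...] = (2, 3, 4)
    multipliers_high: tuple[int, ...] = (5, 10, 20, 30)
    ground_density: tuple[int, int] = (9, 21)  # tones per chord, uniform integer
    dynamic_chord_range: tuple[int, int] = (15, 29)
    isi_fixed_ms: float = 400.0
    isi_dynamic_ms: float = 200.0
    peak_norm: float = 0.95

    def __post_init__(self) -> None:
        for rng_ in (self.ground_range_high, self.ground_range_low):
            if not rng_[0] < rng_[1]:
                raise ValueError("ground ranges must have min < max")
        for mult in (self.multipliers_low, self.multipliers_high):
            if tuple(sorted(mult)) != tuple(mult):
                raise ValueError("multipliers must be sorted ascending")
        if self.coherence < 1:
            raise ValueError("coherence must be >= 1")
        if self.ground_density[0] > self.ground_density[1] or self.ground_density[0] < 1:
            raise ValueError("invalid ground_density range")
        if self.chord_ms <= 0 or self.ramp_ms < 0 or 2 * self.ramp_ms > self.chord_ms:
            raise ValueError("need 0 <= 2*ramp_ms <= chord_ms")

    def ground_range(self, variant: str) -> tuple[float, float]:
        if variant in ("fixed", "dynamic_high"):
            return self.ground_range_high
        if variant == "dynamic_low":
            return self.ground_range_low
        raise ValueError(f"unknown variant {variant!r}")

    def multipliers(self, variant: str) -> tuple[int, ...]:
        if variant == "dynamic_low":
            return self.multipliers_low
        if variant == "dynamic_high":
            return self.multipliers_high
        raise ValueError(f"no harmonic multipliers for variant {variant!r}")


@dataclass(frozen=True)
class FigureTrack:
    """Symbolic figure: per chord, the set of component frequencies (Hz).

    Gap chords carry an empty frequency set; the gap never applies to the
    ground, which continues through it.
    """

    chords: tuple[tuple[float, ...], ...]
    variant: str
    gap: tuple[int, int] | None = None  # (start_chord, length_chords)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for ch in self.chords:
            if any(f <= 0 for f in ch):
                raise ValueError("figure frequencies must be positive")
        if self.gap is not None:
            start, length = self.gap
            if length > 0 and not (0 < start and start + length < len(self.chords)):
                raise ValueError("gap must lie strictly inside the track")

    @property
    def n_chords(self) -> int:
        return len(self.chords)


@dataclass(frozen=True)
class GroundTrack:
    """Symbolic tone cloud: per chord, a multiset of frequencies (Hz)."""

    chords: tuple[tuple[float, ...], ...]
    freq_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.freq_range
        for ch in self.chords:
            if len(ch) == 0:
                raise ValueError("ground chords must not be empty")
            if any(not (lo <= f <= hi) for f in ch):
                raise ValueError("ground frequency outside configured range")

    @property
    def n_chords(self) -> int:
        return len(self.chords)


@dataclass(frozen=True)
class RenderedStimulus:
    """Rendered audio with its commanded SNR and construction metadata."""

    samples: np.ndarray
    sample_rate: int
    snr_db: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-12:
            raise ValueError("samples must lie in [-1, 1]")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def build_fixed_figure(rng: np.random.Generator, cfg: StimulusConfig | None = None) -> FigureTrack:
    """Draw a fixed-frequency figure: ``coherence`` distinct log-uniform
    frequencies from the high ground range, repeated over 42 chords."""
    cfg = cfg or StimulusConfig()
    if cfg.coherence > 20:
        raise ValueError("coherence > 20 not supported")
    lo, hi = cfg.ground_range_high
    freqs: list[float] = []
    while len(freqs) < cfg.coherence:
        f = float(_log_uniform(rng, lo, hi, 1)[0])
        if f not in freqs:
            freqs.append(f)
    chord = tuple(sorted(freqs))
    return FigureTrack(chords=(chord,) * cfg.n_chords_fixed, variant="fixed")


def insert_gap(
    figure: FigureTrack,
    gap_chords: int,
    rng: np.random.Generator,
    margin_chords: int = 5,
) -> FigureTrack:
    """Silence ``gap_chords`` consecutive figure chords at a uniform position.

    The gap start is drawn uniformly over positions leaving at least
    ``margin_chords`` intact chords on each side, so onsets/offsets are never
    truncated and the gap is always detectable.  ``gap_chords=0`` is the
    identity.  The ground is unaffected (it is a separate track).
    """
    if gap_chords == 0:
        return figure
    n = figure.n_chords
    lo = margin_chords
    hi = n - gap_chords - margin_chords  # inclusive last admissible start
    if hi < lo:
        raise ValueError(
            f"figure of {n} chords cannot host a {gap_chords}-chord gap "
            f"with {margin_chords}-chord margins"
        )
    start = int(rng.integers(lo, hi + 1))
    chords = list(figure.chords)
    for i in range(start, start + gap_chords):
        chords[i] = ()
    return replace(figure, chords=tuple(chords), gap=(start, gap_chords))


def build_dynamic_figure(
    f0: ChordF0Series,
    multipliers: tuple[int, ...],
    mask_max: float,
    variant: str = "dynamic_low",
) -> FigureTrack:
    """Build a harmonic figure: chord i carries ``{m * F0_i}``.

    Raises :class:`FigureExceedsMaskError` if any component would exceed
    ``mask_max`` (the top of the masking ground range) — the feasibility
    check applied when pairing contours with a frequency variant.
    """
    if not multipliers:
        raise ValueError("multipliers must be non-empty")
    comps = np.asarray(f0.f0_per_chord)[:, None] * np.asarray(multipliers)[None, :]
    top = float(comps.max())
    if top > mask_max:
        raise FigureExceedsMaskError(
            f"figure component {top:.1f} Hz exceeds masking limit {mask_max:.1f} Hz"
        )
    chords = tuple(tuple(sorted(row)) for row in comps)
    return FigureTrack(chords=chords, variant=variant)


def build_ground(
    rng: np.random.Generator,
    n_chords: int,
    cfg: StimulusConfig | None = None,
    freq_range: tuple[float, float] | None = None,
) -> GroundTrack:
    """Draw a tone cloud: per chord, a uniform-integer number of tones with
    i.i.d. log-uniform frequencies over ``freq_range``."""
    cfg = cfg or StimulusConfig()
    if n_chords < 1:
        raise ValueError("n_chords must be >= 1")
    lo, hi = freq_range or cfg.ground_range_high
    d0, d1 = cfg.ground_density
    chords = []
    for _ in range(n_chords):
        k = int(rng.integers(d0, d1 + 1))
        chords.append(tuple(float(f) for f in _log_uniform(rng, lo, hi, k)))
    return GroundTrack(chords=tuple(chords), freq_range=(lo, hi))


def _chord_wave(
    freqs: tuple[float, ...],
    amp: float,
    n_samp: int,
    sample_rate: int,
    ramp_ms: float,
) -> np.ndarray:
    t = np.arange(n_samp) / sample_rate
    out = np.zeros(n_samp)
    for f in freqs:
        out += amp * np.sin(2 * np.pi * f * t)
    n_ramp = int(round(ramp_ms * sample_rate / 1000.0))
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        out[:n_ramp] *= ramp
        out[-n_ramp:] *= ramp[::-1]
    return out


def render_raw(
    figure: FigureTrack,
    ground: GroundTrack,
    snr_db: float,
    cfg: StimulusConfig | None = None,
) -> np.ndarray:
    """Unnormalized mixture: ground tones at unit amplitude, figure tones at
    ``10**(snr_db/20)``, all gated with raised-cosine ramps."""
    cfg = cfg or StimulusConfig()
    if figure.n_chords != ground.n_chords:
        raise ValueError("figure and ground chord counts differ")
    n_per_chord = int(round(cfg.chord_ms * cfg.sample_rate / 1000.0))
    fig_amp = 10.0 ** (snr_db / 20.0)
    chunks = []
    for f_ch, g_ch in zip(figure.chords, ground.chords):
        w = _chord_wave(g_ch, 1.0, n_per_chord, cfg.sample_rate, cfg.ramp_ms)
        if f_ch:
            w = w + _chord_wave(f_ch, fig_amp, n_per_chord, cfg.sample_rate, cfg.ramp_ms)
        chunks.append(w)
    return np.concatenate(chunks)


def render_stimulus(
    figure: FigureTrack,
    ground: GroundTrack,
    snr_db: float,
    cfg: StimulusConfig | None = None,
) -> RenderedStimulus:
    """Render figure + ground to audio at the commanded SNR.

    SNR is defined on per-tone amplitudes: ground tones have unit amplitude
    and figure tones ``10**(snr_db/20)`` before the final peak normalization,
    making the commanded SNR independent of the ground density.  Every tone
    is gated with raised-cosine on/off ramps.
    """
    cfg = cfg or StimulusConfig()
    samples = render_raw(figure, ground, snr_db, cfg)
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples * (cfg.peak_norm / peak)
    meta = {
        "variant": figure.variant,
        "n_chords": figure.n_chords,
        "gap": figure.gap,
        "snr_db": snr_db,
        "chord_map": [list(ch) for ch in figure.chords],
    }
    return RenderedStimulus(samples, cfg.sample_rate, snr_db, meta)


def draw_dynamic_series(
    rng: np.random.Generator,
    cfg: StimulusConfig,
    variant: str,
    n_chords: int | None = None,
    stats: ContourStats | None = None,
    max_tries: int = 100,
) -> ChordF0Series:
    """Draw a synthetic chord-F0 series feasible for ``variant``.

    Contours whose top harmonic would exceed the masking range (possible for
    the high variant, where F0 x 30 approaches the 7246 Hz limit) are
    rejected and redrawn.
    """
    stats = stats or default_contour_stats()
    mask_max = cfg.ground_range(variant)[1]
    mult_max = max(cfg.multipliers(variant))
    if n_chords is None:
        n_chords = int(rng.integers(cfg.dynamic_chord_range[0], cfg.dynamic_chord_range[1] + 1))
    for _ in range(max_tries):
        contour = synth_contour(rng, n_chords, stats=stats, chord_ms=cfg.chord_ms)
        series = chunk_to_chords(contour, chord_ms=cfg.chord_ms)
        if float(series.f0_per_chord.max()) * mult_max <= mask_max:
            return series
    raise FigureExceedsMaskError(
        f"could not draw a mask-feasible contour for {variant} in {max_tries} tries"
    )


def make_pattern_pair(
    rng: np.random.Generator,
    contours: list[ChordF0Series] | None,
    same: bool,
    cfg: StimulusConfig | None = None,
    variant: str = "dynamic_low",
    snr_db: float = 12.0,
) -> tuple[RenderedStimulus, RenderedStimulus]:
    """Build the two intervals of a same/different pattern trial.

    Both stimuli have the same chord count.  With ``same=True`` they share
    one F0 series; otherwise two distinct series of matched length are used.
    Each interval receives an independently drawn ground.  When ``contours``
    is None, feasible synthetic series are drawn internally.
    """
    cfg = cfg or StimulusConfig()
    mult = cfg.multipliers(variant)
    g_range = cfg.ground_range(variant)
    mask_max = g_range[1]

    if contours is None:
        n_chords = int(rng.integers(cfg.dynamic_chord_range[0], cfg.dynamic_chord_range[1] + 1))
        series_a = draw_dynamic_series(rng, cfg, variant, n_chords=n_chords)
        if same:
            series_b = series_a
        else:
            series_b = draw_dynamic_series(rng, cfg, variant, n_chords=n_chords)
    else:
        if same:
            series_a = series_b = contours[int(rng.integers(len(contours)))]
        else:
            by_len: dict[int, list[ChordF0Series]] = {}
            for s in contours:
                by_len.setdefault(s.n_chords, []).append(s)
            eligible = [v for v in by_len.values() if len(v) >= 2]
            if not eligible:
                raise ValueError("no matched-length contour pair available")
            group = eligible[int(rng.integers(len(eligible)))]
            i, j = rng.choice(len(group), size=2, replace=False)
            series_a, series_b = group[int(i)], group[int(j)]

    fig_a = build_dynamic_figure(series_a, mult, mask_max, variant)
    fig_b = build_dynamic_figure(series_b, mult, mask_max, variant)
    # "tailored to different figures": independent ground draw per interval
    ground_a = build_ground(rng, fig_a.n_chords, cfg, g_range)
    ground_b = build_ground(rng, fig_b.n_chords, cfg, g_range)
    stim_a = render_stimulus(fig_a, ground_a, snr_db, cfg)
    stim_b = render_stimulus(fig_b, ground_b, snr_db, cfg)
    for s in (stim_a, stim_b):
        s.meta["same_pattern"] = bool(same)
        s.meta["isi_ms"] = cfg.isi_dynamic_ms
    return stim_a, stim_b


def write_wav(stim: RenderedStimulus, path: str | Path) -> None:
    """Write 16-bit PCM WAV plus a JSON metadata sidecar (`<path>.json`)."""
    path = Path(path)
    pcm = np.round(stim.samples * 32767.0).astype(np.int16)
    wavfile.write(path, stim.sample_rate, pcm)
    side = {
        "snr_db": stim.snr_db,
        "sample_rate": stim.sample_rate,
        "meta": _jsonable(stim.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))


def read_wav(path: str | Path) -> RenderedStimulus:
    """Read a stimulus written by :func:`write_wav` (<= 1 LSB round-trip error)."""
    path = Path(path)
    rate, pcm = wavfile.read(path)
    samples = pcm.astype(float) / 32767.0
    sidecar = path.with_suffix(path.suffix + ".json")
    snr_db, meta = 0.0, {}
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        snr_db = side.get("snr_db", 0.0)
        meta = side.get("meta", {})
    return RenderedStimulus(np.clip(samples, -1.0, 1.0), int(rate), float(snr_db), meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
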