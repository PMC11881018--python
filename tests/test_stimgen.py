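"""Figure/ground track construction, SNR mixing and audio rendering."""

import numpy as np
import pytest
from scipy import stats

from afgkit import stimgen as sg
from afgkit.contour import ChordF0Series


class TestFixedFigure:
    def test_default_shape(self, rng, cfg):
        fig = sg.build_fixed_figure(rng, cfg)
        assert fig.n_chords == 42
        assert all(len(ch) == 3 for ch in fig.chords)
        assert len(set(fig.chords)) == 1  # identical frequency set per chord
        assert len(set(fig.chords[0])) == 3

    def test_coherence_one(self, rng):
        cfg = sg.StimulusConfig(coherence=1)
        fig = sg.build_fixed_figure(rng, cfg)
        assert all(len(ch) == 1 for ch in fig.chords)

    def test_frequencies_log_uniform(self, cfg):
        rng = np.random.default_rng(2024)
        lo, hi = cfg.ground_range_high
        draws = np.concatenate(
            [sg.build_fixed_figure(rng, cfg).chords[0] for _ in range(1000)])
        u = (np.log(draws) - np.log(lo)) / (np.log(hi) - np.log(lo))
        assert stats.kstest(u, "uniform").pvalue > 1e-3


class TestInsertGap:
    def test_gap_leaves_36_figure_chords(self, rng, cfg):
        fig = sg.insert_gap(sg.build_fixed_figure(rng, cfg), 6, rng)
        assert sum(1 for ch in fig.chords if ch) == 36
        start, length = fig.gap
        assert length == 6

    def test_zero_gap_identity(self, rng, cfg):
        fig = sg.build_fixed_figure(rng, cfg)
        assert sg.insert_gap(fig, 0, rng) is fig

    def test_margins_respected(self, cfg):
        rng = np.random.default_rng(3)
        for _ in range(200):
            fig = sg.insert_gap(sg.build_fixed_figure(rng, cfg), 6, rng, margin_chords=5)
            start, length = fig.gap
            assert start >= 5 and start + length <= 42 - 5

    def test_start_position_uniform(self, cfg):
        rng = np.random.default_rng(4)
        base = sg.build_fixed_figure(rng, cfg)
        starts = [sg.insert_gap(base, 6, rng).gap[0] for _ in range(10_000)]
        lo, hi = 5, 42 - 6 - 5  # inclusive admissible range
        counts = np.bincount(starts, minlength=hi + 1)[lo : hi + 1]
        expected = len(starts) / (hi - lo + 1)
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
        # chi-square on (hi-lo) dof; generous quantile to keep the test sharp but stable
        assert chi2 < stats.chi2.ppf(0.9999, hi - lo)

    def test_too_short_raises(self, rng):
        fig = sg.FigureTrack(chords=((440.0,),) * 10, variant="fixed")
        with pytest.raises(ValueError):
            sg.insert_gap(fig, 6, rng)


class TestDynamicFigure:
    def test_harmonic_multiples(self):
        series = ChordF0Series(np.full(10, 100.0))
        fig = sg.build_dynamic_figure(series, (2, 3, 4), mask_max=3623.0)
        assert all(ch == (200.0, 300.0, 400.0) for ch in fig.chords)

    def test_identity_multiplier(self):
        series = ChordF0Series(np.array([100.0, 120.0]))
        fig = sg.build_dynamic_figure(series, (1,), mask_max=3623.0)
        assert [ch[0] for ch in fig.chords] == [100.0, 120.0]

    def test_mask_violation_raises(self):
        series = ChordF0Series(np.full(5, 250.0))
        assert 30 * 250.0 > 7246.0
        with pytest.raises(sg.FigureExceedsMaskError):
            sg.build_dynamic_figure(series, (5, 10, 20, 30), mask_max=7246.0)

    def test_low_variant_bounded_by_top_harmonic(self, rng, cfg):
        for _ in range(50):
            series = sg.draw_dynamic_series(rng, cfg, "dynamic_low")
            fig = sg.build_dynamic_figure(series, cfg.multipliers_low, 3623.0, "dynamic_low")
            top = max(max(ch) for ch in fig.chords)
            assert top <= 4 * 295.44


class TestGround:
    def test_range_and_chord_count(self, rng, cfg):
        g = sg.build_ground(rng, 42, cfg, cfg.ground_range_high)
        assert g.n_chords == 42
        for ch in g.chords:
            assert 9 <= len(ch) <= 21
            assert all(180.0 <= f <= 7246.0 for f in ch)

    def test_density_one(self, rng):
        cfg = sg.StimulusConfig(ground_density=(1, 1))
        g = sg.build_ground(rng, 10, cfg)
        assert all(len(ch) == 1 for ch in g.chords)

    def test_median_near_geometric_mean(self, cfg):
        rng = np.random.default_rng(5)
        lo, hi = cfg.ground_range_low
        tones = []
        while len(tones) < 100_000:
            tones.extend(f for ch in sg.build_ground(rng, 100, cfg, (lo, hi)).chords for f in ch)
        med = float(np.median(tones))
        assert med == pytest.approx(np.sqrt(lo * hi), rel=0.02)


class TestRender:
    def test_sample_count(self, rng, cfg):
        fig = sg.build_fixed_figure(rng, cfg)
        g = sg.build_ground(rng, 42, cfg)
        stim = sg.render_stimulus(fig, g, 0.0, cfg)
        assert stim.samples.size == 92_610  # 42 chords * 50 ms * 44.1 kHz

    def test_peak_normalized_no_clipping(self, rng, cfg):
        fig = sg.build_fixed_figure(rng, cfg)
        g = sg.build_ground(rng, 42, cfg)
        stim = sg.render_stimulus(fig, g, 12.0, cfg)
        assert np.max(np.abs(stim.samples)) == pytest.approx(0.95)

    def test_snr_zero_amplitudes_equal(self, cfg):
        """At 0 dB a figure tone and a ground tone have the same amplitude:
        a chord with one of each at the same frequency doubles one alone."""
        fig = sg.FigureTrack(chords=((1000.0,),) * 2, variant="fixed")
        g = sg.GroundTrack(chords=((1000.0,),) * 2, freq_range=(180.0, 7246.0))
        both = sg.render_raw(fig, g, 0.0, cfg)
        fig_silent = sg.FigureTrack(chords=((),) * 2, variant="fixed")
        alone = sg.render_raw(fig_silent, g, 0.0, cfg)
        ratio = np.max(np.abs(both)) / np.max(np.abs(alone))
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_figure_rms_monotone_in_snr(self, rng, cfg):
        fig = sg.build_fixed_figure(rng, cfg)
        silent_ground = sg.GroundTrack(chords=((1e-3,),) * 42, freq_range=(1e-4, 1.0))
        rms = []
        for snr in (-10.0, 0.0, 10.0):
            raw = sg.render_raw(fig, silent_ground, snr, cfg)
            rms.append(float(np.sqrt(np.mean(raw**2))))
        assert rms[0] < rms[1] < rms[2]

    def test_fft_peaks_match_commanded_components(self, cfg):
        rng = np.random.default_rng(6)
        fig = sg.build_fixed_figure(rng, cfg)
        g = sg.build_ground(rng, 42, cfg)
        stim = sg.render_stimulus(fig, g, 20.0, cfg)
        n = int(cfg.chord_ms * cfg.sample_rate / 1000)
        chord = stim.samples[10 * n : 11 * n]
        spec = np.abs(np.fft.rfft(chord * np.hanning(n)))
        freqs = np.fft.rfftfreq(n, 1 / cfg.sample_rate)
        bin_hz = freqs[1]
        for f_cmd in fig.chords[10]:
            # +/-2 bins: components can sit within ~60 Hz of each other
            window = (freqs >= f_cmd - 2 * bin_hz) & (freqs <= f_cmd + 2 * bin_hz)
            peak = freqs[window][np.argmax(spec[window])]
            assert abs(peak - f_cmd) <= bin_hz

    def test_raised_cosine_ramp_on_envelope(self, cfg):
        fig = sg.FigureTrack(chords=((1000.0,),), variant="fixed")
        g = sg.GroundTrack(chords=((1e-6,),), freq_range=(1e-7, 1.0))
        raw = sg.render_raw(fig, g, 60.0, cfg)  # figure dominates at +60 dB
        n_ramp = int(cfg.ramp_ms * cfg.sample_rate / 1000)
        t = np.arange(n_ramp) / cfg.sample_rate
        expected_env = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        carrier = np.sin(2 * np.pi * 1000.0 * t)
        measured = raw[:n_ramp] / 1000.0  # figure amplitude 10**(60/20)
        assert np.allclose(measured, expected_env * carrier, atol=2e-3)

    def test_mismatched_chord_counts_raise(self, rng, cfg):
        fig = sg.build_fixed_figure(rng, cfg)
        g = sg.build_ground(rng, 10, cfg)
        with pytest.raises(ValueError):
            sg.render_stimulus(fig, g, 0.0, cfg)

    def test_ground_continues_through_gap(self, rng, cfg):
        fig = sg.insert_gap(sg.build_fixed_figure(rng, cfg), 6, rng)
        g = sg.build_ground(rng, fig.n_chords, cfg)
        assert all(len(ch) >= 1 for ch in g.chords)
        stim = sg.render_stimulus(fig, g, 0.0, cfg)
        n = int(cfg.chord_ms * cfg.sample_rate / 1000)
        start, length = fig.gap
        for i in range(start, start + length):
            chord_rms = np.sqrt(np.mean(stim.samples[i * n : (i + 1) * n] ** 2))
            assert chord_rms > 0  # audible ground inside the figure gap


class TestPatternPair:
    def test_same_pair_shares_figure(self, cfg):
        rng = np.random.default_rng(8)
        a, b = sg.make_pattern_pair(rng, None, same=True, cfg=cfg, variant="dynamic_low")
        assert a.meta["chord_map"] == b.meta["chord_map"]
        assert a.meta["n_chords"] == b.meta["n_chords"]

    def test_different_pair_matched_length_different_pattern(self, cfg):
        rng = np.random.default_rng(9)
        a, b = sg.make_pattern_pair(rng, None, same=False, cfg=cfg, variant="dynamic_high")
        assert a.meta["n_chords"] == b.meta["n_chords"]
        assert a.meta["chord_map"] != b.meta["chord_map"]

    def test_chord_counts_within_sentence_range(self, cfg):
        rng = np.random.default_rng(10)
        for _ in range(100):
            a, b = sg.make_pattern_pair(rng, None, same=bool(rng.integers(2)),
                                        cfg=cfg, variant="dynamic_low")
            assert 15 <= a.meta["n_chords"] <= 29

    def test_explicit_contours_need_matched_pair(self, cfg, rng):
        series = [ChordF0Series(np.full(15, 120.0)), ChordF0Series(np.full(20, 130.0))]
        with pytest.raises(ValueError, match="matched-length"):
            sg.make_pattern_pair(rng, series, same=False, cfg=cfg, variant="dynamic_low")

    def test_grounds_drawn_independently(self, cfg):
        rng = np.random.default_rng(11)
        a, b = sg.make_pattern_pair(rng, None, same=True, cfg=cfg, variant="dynamic_low")
        assert not np.array_equal(a.samples, b.samples)


class TestWavRoundTrip:
    def test_round_trip_within_one_lsb(self, rng, cfg, tmp_path):
        fig = sg.build_fixed_figure(rng, cfg)
        g = sg.build_ground(rng, 42, cfg)
        stim = sg.render_stimulus(fig, g, 3.5, cfg)
        path = tmp_path / "stim.wav"
        sg.write_wav(stim, path)
        back = sg.read_wav(path)
        assert np.max(np.abs(back.samples - stim.samples)) <= 2**-15
        assert back.sample_rate == stim.sample_rate
        assert back.snr_db == 3.5  # sidecar preserves the commanded SNR exactly
        assert back.meta["gap"] == (list(stim.meta["gap"]) if stim.meta["gap"] else None)

    def test_rewrite_is_byte_identical(self, rng, cfg, tmp_path):
        fig = sg.build_fixed_figure(rng, cfg)
        g = sg.build_ground(rng, 42, cfg)
        stim = sg.render_stimulus(fig, g, 0.0, cfg)
        p1, p2 = tmp_path / "a.wav", tmp_path / "b.wav"
        sg.write_wav(stim, p1)
        sg.write_wav(stim, p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_render_deterministic_from_seed(cfg):
    def build(seed):
        rng = np.random.default_rng(seed)
        fig = sg.insert_gap(sg.build_fixed_figure(rng, cfg), 6, rng)
        g = sg.build_ground(rng, fig.n_chords, cfg)
        return sg.render_stimulus(fig, g, 2.0, cfg)

    a, b = build(99), build(99)
    assert np.array_equal(a.samples, b.samples)
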