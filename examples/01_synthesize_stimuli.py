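"""Build and render one stimulus of each figure-ground variant.

The fixed variant repeats three tones over 42 chords with a 6-chord gap; the
dynamic variants carry a harmonic complex on a synthetic speech pitch
contour (x{2,3,4} low, x{5,10,20,30} high) over 15-29 chords.
"""

import numpy as np

from afgkit import stimgen as sg
from afgkit._seeds import spawn_rng

cfg = sg.StimulusConfig()

# fixed-frequency figure with a gap, on the high-range tone cloud
rng = spawn_rng(0, "example", "fixed")
fig = sg.insert_gap(sg.build_fixed_figure(rng, cfg), cfg.gap_chords, rng)
ground = sg.build_ground(rng, fig.n_chords, cfg, cfg.ground_range_high)
stim = sg.render_stimulus(fig, ground, snr_db=0.0, cfg=cfg)
print(f"fixed   : {fig.n_chords} chords, gap at chord {fig.gap[0]} "
      f"({fig.gap[1]} chords), {stim.samples.size} samples "
      f"({stim.samples.size / cfg.sample_rate:.2f} s)")

# dynamic low and high variants from fresh synthetic pitch contours
for variant in ("dynamic_low", "dynamic_high"):
    rng = spawn_rng(0, "example", variant)
    series = sg.draw_dynamic_series(rng, cfg, variant)
    figure = sg.build_dynamic_figure(series, cfg.multipliers(variant),
                                     cfg.ground_range(variant)[1], variant)
    ground = sg.build_ground(rng, figure.n_chords, cfg, cfg.ground_range(variant))
    stim = sg.render_stimulus(figure, ground, snr_db=6.0, cfg=cfg)
    top = max(max(ch) for ch in figure.chords)
    print(f"{variant}: {figure.n_chords} chords, F0 mean "
          f"{np.mean(series.f0_per_chord):.1f} Hz, top harmonic {top:.0f} Hz "
          f"(mask limit {cfg.ground_range(variant)[1]:.0f} Hz)")

# The printed chord/gap geometry and the mask check are the stimulus-level
# guarantees every trial of the battery relies on.
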