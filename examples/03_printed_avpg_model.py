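"""Evaluate the published multiposition aortic-gradient model.

The model maps four predicted murmur grades (MG_A, MG_P, MG_T, MG_M) and
per-position noise indicators to the aortic valve mean pressure gradient:

    AVPGmean = 3.5 + 0.6 MG_A^2 + 1.1 MG_P^2 + 0.5 MG_T
               + 0.9 MG_A^2 noise_P + 8.9 MG_M noise_A noise_P noise_T

A noisy position's grade is forced to zero before evaluation.
"""

from pcgscreen import avpg

cases = [
    ([0, 0, 0, 0], [0, 0, 0, 0], "no murmur anywhere"),
    ([2, 1, 1, 0], [0, 0, 0, 0], "moderate aortic murmur, all clean"),
    ([3, 2.5, 2, 1], [0, 0, 0, 0], "loud radiating murmur"),
    ([2, 0, 0, 1.5], [1, 1, 1, 0], "only the mitral recording usable"),
]
for mg, noise, label in cases:
    value = avpg.evaluate(avpg.PRINTED_MODEL, mg, noise)
    print(f"{label:38s} -> AVPGmean {value:6.2f} mm Hg")

# 15 / 20 / 40 mm Hg are the mild / moderate / severe stenosis cutoffs, so
# the first case sits at the healthy baseline (the 3.5 mm Hg intercept) and
# the loud-murmur case crosses the moderate-stenosis threshold.
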