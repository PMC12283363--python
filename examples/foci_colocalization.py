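"""Colocalization of two focus channels with a 90-degree rotation control.

Builds a synthetic nucleus: 90 'green' foci uniform in a 20x20 um field,
and 80 'red' foci of which 75% sit on a green focus (within detection
jitter) and the rest are placed independently.  True colocalization shows
up as a high overlap percentage at the 0.33 um threshold; rotating the
green channel 90 degrees about the field centre destroys the pairing and
leaves only the chance-overlap level.
"""

import numpy as np

from xomap import PointSet, overlap_fraction, rotation_control

rng = np.random.default_rng(5)
bounds = ((0.0, 20.0), (0.0, 20.0))

green = rng.uniform(0, 20, size=(90, 2))
colocal = green[rng.choice(90, size=60, replace=False)] + rng.normal(0, 0.08, size=(60, 2))
background = rng.uniform(0, 20, size=(20, 2))
red = np.clip(np.vstack([colocal, background]), 0, 20)

red_ps = PointSet("red", red, bounds)
green_ps = PointSet("green", green, bounds)

pr, pg, pairs = overlap_fraction(red_ps, green_ps, max_dist=0.33)
cr, cg, _ = rotation_control(red_ps, green_ps, max_dist=0.33)

print(f"red foci overlapping green:   {pr:.1f}%  ({len(pairs)} one-to-one pairs)")
print(f"green foci overlapping red:   {pg:.1f}%")
print(f"rotation control (red): {cr:.1f}%  <- chance level after 90-degree rotation")
print("a large observed-vs-control gap indicates genuine spatial association")
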