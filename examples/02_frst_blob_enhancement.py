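"""Fast radial symmetry transform: spherical foci beat tubular structures.

Builds a toy volume containing one bright ball (a CMB-like focus) and one
bright tube (a vessel-like mimic), computes the mean FRST over radii
{2, 3, 4, 6} voxels, and compares the responses.
"""

import numpy as np

from cmbkit.frst import frst_mean

shape = (32, 32, 32)
grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
ball = (
    sum((g - c) ** 2 for g, c in zip(grids, (16, 22, 22))) <= 3.0**2
)
tube = ((grids[1] - 9) ** 2 + (grids[2] - 9) ** 2) <= 1.0
data = 0.8 * np.maximum(ball, tube)

fr = frst_mean(data, radii=(2, 3, 4, 6))
peak = np.unravel_index(np.argmax(fr.data), shape)
print(f"ball centre:            (16, 22, 22)")
print(f"FRST argmax:            {tuple(int(p) for p in peak)}")
print(f"max response on ball:   {fr.data[ball].max():.3f}")
print(f"max response on tube:   {fr.data[tube].max():.3f}")
# The argmax sits on the ball centre and the ball response dominates the
# tube response: exactly the property that makes the FRST map a useful
# second input channel for candidate detection.
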