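"""Extract CIP-like features: depth plus four derivative channels.

CIP neurons respond to depth gradients and curvature; the model input
is the depth map and its first and second spatial derivatives in the
horizontal and vertical directions - 16 x 16 x 5 = 1280 values.
"""

import numpy as np

from shapecode.features import (
    CurvedSurfaceStimulus,
    derivative_stack,
    legendre_expand,
    v3a_channels,
)
from shapecode.render import build_grid, render_depth
from shapecode.shapes import Superquadric

dm = render_depth(Superquadric(0.03, 0.05, 0.02, 0.1, 1.0, 0.4), build_grid())
fs = derivative_stack(dm)
print("channels:", fs.channel_names)
print("flattened input length:", fs.flat().shape[0])
for name, ch in zip(fs.channel_names, fs.channels):
    print(f"  {name:10s} range [{ch.min():+.4f}, {ch.max():+.4f}]")

# expanded quadratic tuning variables for the dendritic/CIP fits
ext = legendre_expand(fs)
print("with expanded variables:", ext.channels.shape[0], "channels")

# the V3A input variant: 7 pointwise disparity-tuning functions
v3a = v3a_channels(dm)
print("V3A stack:", v3a.shape, "- near+far sigmoids sum to",
      float((v3a[5] + v3a[6]).mean()))

# curved-surface stimulus: curvature decomposition
s = CurvedSurfaceStimulus(K1=2.0, K2=0.0)
print(f"curved surface K=(2,0): curvedness C={s.C:.4f}, shape index SI={s.SI:.2f}"
      " (0.5 = cylindrical ridge)")
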