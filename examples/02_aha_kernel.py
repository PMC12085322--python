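"""Truncated cost-distance kernels and the AHA metric.

A disperser with a 500-unit budget can cross 500 m of open land in any
direction.  A one-pixel building wall costs (10+500)/2 + (500+10)/2 =
510 to cross, so the same budget cannot pass it: the kernel, and with it
AHA = a_p / (pi R^2), collapses on the walled side.
"""

import math

import numpy as np

from ahascape import cost_distance_kernel
from ahascape.landscape_io import GridSpec
from ahascape.resistance import ResistanceSurface

n = 121
open_cost = np.full((n, n), 10.0)
grid = GridSpec(0, n * 10, 10, n, n)

walled = open_cost.copy()
walled[:, 70] = 500.0  # building wall 100 m east of the focal cell

for label, cost in [("open land", open_cost), ("wall at +100 m", walled)]:
    surf = ResistanceSurface(grid=grid, cost=cost)
    res = cost_distance_kernel(surf, (60, 60), 500.0)
    aha = res.a_p / (math.pi * res.budget.radius_m**2)
    print(f"{label:16s} reached {res.n_cells:5d} cells, a_p = {res.a_p/1e4:7.1f} ha, AHA = {aha:.3f}")
# Frictionless AHA sits near 2*sqrt(2)/pi = 0.90 (octagonal metric);
# the wall removes the area beyond it and AHA drops accordingly.
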