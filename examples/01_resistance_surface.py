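"""Build a resistance surface from a tiny coded land-cover layer.

Per-pixel crossing costs come from the rank-cost power law
C_i = (Rank_i / Rank_max)^x * C_max; the shipped replication config pins
roads at 250 and buildings at 500 cost units per pixel, with permeable
land at 10 (one unit per meter on 10 m cells).
"""

import numpy as np

from ahascape import GridSpec, build_resistance_surface, replication_config
from ahascape.landscape_io import DEFAULT_CLASS_CODES
from ahascape.resistance import rank_to_cost

cfg = replication_config()
print("per-pixel crossing costs:")
for name in ("open", "lake", "road", "building"):
    print(f"  {name:9s} {cfg.class_cost(name):8.2f}")
print("rank-cost formula at road rank 2.5:",
      f"{rank_to_cost(2.5, 3, 4, 500):.2f}  (config override pins 250)")

layer = np.zeros((8, 8), dtype=np.int64)
layer[3, :] = 1       # a road crossing the block
layer[5:7, 5:7] = 2   # a 2x2 building
grid = GridSpec(origin_x=0, origin_y=80, cell_size=10, n_rows=8, n_cols=8)
surf = build_resistance_surface(layer, cfg, grid, DEFAULT_CLASS_CODES)
print("\ncost surface (cost units per pixel):")
print(surf.cost.astype(int))
# Rows of 250 mark the road, the 500 patch the building; everything else
# costs 10 per 10 m pixel, i.e. 1 per meter of open land.
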