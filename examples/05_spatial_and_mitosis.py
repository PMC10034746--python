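"""Spatial colony organization and proliferative state.

Bins cells into 100-um edge-distance groups, detects mitotic nuclei by
2-means on morphology + Hoechst brightness, and compares neighbor-relative
lipid abundances between dividing and non-dividing cells.
"""

import numpy as np

import lipidcolony as lc
from lipidcolony import cells as C

config = lc.ColonyPhantomConfig(n_cells=1500, seed=9)
table, truth = lc.generate_cell_table(config, day=0)

bins = lc.bin_by_edge_distance(table, features=["mz_722.5", "mz_940.6"])
for f in ("mz_722.5", "mz_940.6"):
    sub = bins[(bins["feature"] == f) & (bins["n"] > 0)]
    print(f"{f.replace('mz_', 'm/z ')} mean by edge-distance group:",
          np.round(sub["mean"].to_numpy(), 1))

flags = lc.detect_mitotic(table, seed=0)
acc = (flags == table["mitotic"].to_numpy()).mean()
print(f"mitosis detector: {flags.sum()} flagged, "
      f"{100 * acc:.1f}% agreement with planted labels")

res = lc.compare_dividing(table.assign(mitotic=flags), "mz_835.5")
print(f"m/z 835.5 dividing vs non-dividing: median diff "
      f"{res['median_diff']:+.2f} log-units, p = {res['p_value']:.2e}")
# The PI species is enriched in dividing cells — consistent with the faster
# cell cycle of pluripotent-like cells.
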