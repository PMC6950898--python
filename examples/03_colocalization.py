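"""Detect interneuron somata and count directional marker overlaps.

Renders CA1 cell maps from the packaged marker configuration, detects
somata per channel, fuses detections across channels by Dice matching, and
reports the laminar distribution of APP-positive cells plus directional
colocalization percentages at the SR/SLM border.
"""

import numpy as np

from lamplaq import (assign_laminae, build_geometry, coloc_percentages,
                     detect_positive_cells, laminar_distribution,
                     merge_detections, render_channels)
from lamplaq.presets import fig1_cell_config, fig1_geometry
from lamplaq.simulate import MARKERS

label_map = build_geometry(fig1_geometry())
cfg = fig1_cell_config()

cells = []
for section in range(6):
    img, _ = render_channels(label_map, cfg, "control", 3.0,
                             np.random.SeedSequence([3, section]))
    dets = {m: detect_positive_cells(img.channel(m), img.pixel_size)
            for m in MARKERS}
    cells += assign_laminae(merge_detections(dets, img.pixel_size), label_map)

print(f"{len(cells)} cells pooled over 6 sections\n")
print("Laminar distribution of APP+ cells (percent):")
print(laminar_distribution(cells, "APP").to_string(index=False))

print("\nDirectional overlaps:")
for a, b, scope in (("APP", "GABABR1", "border"), ("GABABR1", "APP", "border"),
                    ("APP", "Reelin", "border"), ("CCK", "APP", "CA1")):
    r = coloc_percentages(cells, a, b, scope)
    print(f"  {r.percentage:5.1f} % of {a}+ cells are {b}+  "
          f"(scope {scope}, n={r.n_a})")
print("\nMost APP+ cells sit at the SR/SLM border; every APP+ cell there is "
      "GABA_BR1+ by construction and the pipeline recovers exactly that.")
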