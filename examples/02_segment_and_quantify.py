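"""Segment one synthetic animal and measure its laminar plaque burden.

Renders a single control animal, runs the automatic segmentation
(hippocampus -> SP/SG bands -> distance-band laminae -> WFS1 subfield split),
builds the Triangle-threshold plaque mask with the 10 um^2 particle filter,
and compares measured area fractions against the planted truth.
"""

import numpy as np

from lamplaq import (build_geometry, make_plaque_mask, measure_regions,
                     render_channels, segment_image)
from lamplaq.presets import fig3_effect_config, fig3_geometry

geometry = fig3_geometry()
label_map = build_geometry(geometry)
effect = fig3_effect_config(geometry)

img, truth = render_channels(label_map, effect, "control", 3.0,
                             np.random.SeedSequence(42))
regions = segment_image(img.channel("VGLUT1"), img.channel("WFS1"),
                        img.pixel_size)
mask = make_plaque_mask(img.channel("ABETA"), img.pixel_size,
                        min_area_um2=10.0, crop_mask=regions.mask("HIPPO"))
measured = measure_regions(regions, mask).set_index("region")
planted = truth.regions.set_index("region")

print(f"Triangle threshold at 8-bit bin {mask.threshold_bin}; "
      f"{len(mask.particles)} particles survive the >10 um^2 filter\n")
print(f"{'region':>10} {'measured %':>11} {'planted %':>10}")
for code in planted.index:
    print(f"{code:>10} {measured.area_fraction_pct[code]:>11.2f} "
          f"{planted.area_fraction_pct[code]:>10.2f}")
print(f"{'HIPPO':>10} {measured.area_fraction_pct['HIPPO']:>11.2f} "
      f"{100 * planted.plaque_area_um2.sum() / planted.area_um2.sum():>10.2f}")
print("\nMeasured fractions track the planted burden; small deficits come "
      "from the size filter dropping sub-10 um^2 plaques, exactly as in the "
      "real workflow.")
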