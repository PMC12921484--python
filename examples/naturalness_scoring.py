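"""Visual naturalness from labeled panorama masks.

Naturalness of a sampling point is the percentage of natural pixels among
natural + man-made pixels; sky and human pixels are excluded entirely. A
site's score is the unweighted mean over its sampling points.
"""

import numpy as np

from greendose import LabelMask, point_naturalness, site_naturalness

label_map = {0: "natural", 1: "man_made", 2: "sky", 3: "human"}


def make_mask(natural, man_made, sky, human, point_id):
    codes = [0] * natural + [1] * man_made + [2] * sky + [3] * human
    side = int(np.ceil(np.sqrt(len(codes))))
    codes += [2] * (side * side - len(codes))
    return LabelMask(np.array(codes).reshape(side, side), label_map,
                     point_id=point_id, site_id="UP")


mask = make_mask(60, 20, 15, 5, "pano1")
print(f"single panorama (60 natural / 20 man-made / 15 sky / 5 human): "
      f"{point_naturalness(mask):.1f}% natural")

site = site_naturalness([make_mask(80, 20, 10, 0, "p1"),
                         make_mask(90, 10, 40, 2, "p2")])
print(f"site mean over {len(site.point_pct)} sampling points: "
      f"{site.site_mean_pct:.1f}%")
print("Sky/human pixels never change a score, and every sampling point "
      "counts equally regardless of image size.")
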