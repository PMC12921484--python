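"""Visual naturalness scoring of pre-labeled scene segmentation masks.

A site's visual naturalness is the percentage of *natural* pixels among the
natural + man-made pixels of a panoramic scene — sky and human pixels are
excluded entirely — averaged without weighting over the 5-10 sampling points
photographed at the site. The semantic segmentation that produces the label
masks is upstream of this package; inputs are integer label images plus a
code -> category map.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CATEGORIES = ("natural", "man_made", "sky", "human")

#: Convenience mapping of common scene-parsing class names to the four
#: categories. Non-normative: real label maps come from the upstream
#: segmentation and should be supplied explicitly.
DEFAULT_CLASS_CATEGORIES = {
    "tree": "natural", "grass": "natural", "plant": "natural", "water": "natural",
    "earth": "natural", "mountain": "natural", "flower": "natural", "rock": "natural",
    "sand": "natural", "lake": "natural", "river": "natural",
    "building": "man_made", "road": "man_made", "sidewalk": "man_made",
    "wall": "man_made", "fence": "man_made", "bench": "man_made", "car": "man_made",
    "signboard": "man_made", "streetlight": "man_made", "bridge": "man_made",
    "sky": "sky",
    "person": "human",
}


@dataclasses.dataclass
class LabelMask:
    """Integer label image plus the code -> category map for one sampling point."""

    labels: np.ndarray
    label_map: Mapping[int, str]
    point_id: str = "point"
    site_id: str = "site"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 2-D integer image")
        self.label_map = {int(k): v for k, v in self.label_map.items()}
        for code, cat in self.label_map.items():
            if cat not in CATEGORIES:
                raise ValueError(f"label {code} maps to unknown category {cat!r}; "
                                 f"expected one of {CATEGORIES}")
        present = set(np.unique(self.labels).tolist())
        unmapped = present - set(self.label_map)
        if unmapped:
            raise ValueError(f"mask {self.point_id!r} contains unmapped labels {sorted(unmapped)}")

    def category_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(CATEGORIES, 0)
        codes, n = np.unique(self.labels, return_counts=True)
        for code, k in zip(codes, n):
            counts[self.label_map[int(code)]] += int(k)
        return counts


@dataclasses.dataclass
class NaturalnessResult:
    """Per-point percentages and the unweighted site mean."""

    site_id: str
    point_pct: dict[str, float]
    category_counts: dict[str, dict[str, int]]

    @property
    def site_mean_pct(self) -> float:
        return float(np.mean(list(self.point_pct.values())))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"site": self.site_id, "point": p, "naturalness_pct": v}
                for p, v in self.point_pct.items()]
        rows.append({"site": self.site_id, "point": "SITE_MEAN",
                     "naturalness_pct": self.site_mean_pct})
        return pd.DataFrame(rows)


def point_naturalness(mask: LabelMask) -> float:
    """100 * natural / (natural + man_made); sky and human pixels are ignored."""
    counts = mask.category_counts()
    denom = counts["natural"] + counts["man_made"]
    if denom == 0:
        raise ValueError(
            f"sampling point {mask.point_id!r}: only sky/human pixels; "
            "naturalness undefined"
        )
    return 100.0 * counts["natural"] / denom


def site_naturalness(masks: Iterable[LabelMask]) -> NaturalnessResult:
    """Unweighted mean of point percentages — every sampling point counts
    equally regardless of image resolution."""
    masks = list(masks)
    if not masks:
        raise ValueError("site has no sampling points")
    site_ids = {m.site_id for m in masks}
    if len(site_ids) > 1:
        raise ValueError(f"masks span several sites: {sorted(site_ids)}")
    return NaturalnessResult(
        site_id=masks[0].site_id,
        point_pct={m.point_id: point_naturalness(m) for m in masks},
        category_counts={m.point_id: m.category_counts() for m in masks},
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_label_map(path: str | Path) -> dict[int, str]:
    raw = json.loads(Path(path).read_text())
    return {int(k): v for k, v in raw.items()}


def read_mask(path: str | Path, label_map: Mapping[int, str],
              point_id: str | None = None, site_id: str = "site") -> LabelMask:
    """Read a mask from paletted PNG or a whitespace-delimited integer grid."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image
        with Image.open(path) as img:
            # paletted PNGs carry the label codes as palette indices
            labels = np.asarray(img if img.mode == "P" else img.convert("I"))
    else:
        labels = np.loadtxt(path, dtype=int, ndmin=2)
    return LabelMask(labels=labels, label_map=label_map,
                     point_id=point_id or path.stem, site_id=site_id)


def write_results(results: Iterable[NaturalnessResult], path: str | Path) -> Path:
    path = Path(path)
    pd.concat([r.to_frame() for r in results], ignore_index=True).to_csv(path, index=False)
    return path
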