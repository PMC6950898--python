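"""Region coding and the lamina label map.

The hippocampus is modelled as three subfields, each divided into laminae:

* CA1 and CA2/3: stratum oriens (SO), stratum pyramidale (SP),
  stratum radiatum (SR), stratum lacunosum-moleculare (SLM);
* dentate gyrus (DG): molecular layer (MO), stratum granulosum (SG),
  hilus (H).

Every measurement in the package is expressed in the coordinate system of a
:class:`LaminaLabelMap`: an integer raster in which 0 is background and every
positive label names exactly one (subfield, lamina) region.  Region codes are
strings of the form ``"CA1_SO"``; the aggregate codes ``"CA1"``, ``"CA23"``,
``"DG"`` and ``"HIPPO"`` address pixel-pooled unions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

SUBFIELDS = ("CA1", "CA23", "DG")
CA_LAMINAE = ("SO", "SP", "SR", "SLM")
DG_LAMINAE = ("MO", "SG", "H")

#: canonical label assignment used by the synthetic generator and all writers
CANONICAL_LABELS: dict[int, tuple[str, str]] = {
    1: ("CA1", "SO"), 2: ("CA1", "SP"), 3: ("CA1", "SR"), 4: ("CA1", "SLM"),
    5: ("CA23", "SO"), 6: ("CA23", "SP"), 7: ("CA23", "SR"), 8: ("CA23", "SLM"),
    9: ("DG", "MO"), 10: ("DG", "SG"), 11: ("DG", "H"),
}

ALL_REGION_CODES = tuple(f"{s}_{l}" for s, l in CANONICAL_LABELS.values())
AGGREGATE_CODES = ("CA1", "CA23", "DG", "HIPPO")


def region_code(subfield: str, lamina: str) -> str:
    return f"{subfield}_{lamina}"


@dataclass
class LaminaLabelMap:
    """Integer label raster plus its code table and physical pixel size.

    Parameters
    ----------
    labels
        2-D ``int32`` array; 0 is background.
    code_table
        Maps every non-zero label to its ``(subfield, lamina)`` pair.
    pixel_size
        Pixel edge length in micrometres.
    """

    labels: np.ndarray
    code_table: dict[int, tuple[str, str]] = field(
        default_factory=lambda: dict(CANONICAL_LABELS))
    pixel_size: float = 0.325

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("label raster must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.code_table)
        if missing:
            raise ValueError(f"labels without code-table entry: {sorted(missing)}")

    # -- lookups ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size ** 2

    def codes(self) -> list[str]:
        """Region codes present in the raster, canonical order."""
        present = set(np.unique(self.labels)) - {0}
        return [region_code(*self.code_table[l])
                for l in sorted(present, key=self._canonical_key)]

    def _canonical_key(self, label: int) -> int:
        sub, lam = self.code_table[label]
        order = [(s, l) for s, l in CANONICAL_LABELS.values()]
        try:
            return order.index((sub, lam))
        except ValueError:
            return 100 + label

    def label_for(self, code: str) -> int:
        for lab, (s, l) in self.code_table.items():
            if region_code(s, l) == code:
                return lab
        raise KeyError(f"unknown region code {code!r}")

    def mask(self, code: str) -> np.ndarray:
        """Boolean mask for a lamina region, a subfield aggregate or HIPPO."""
        if code == "HIPPO":
            return self.labels > 0
        if code in SUBFIELDS or code == "CA":
            labs = [lab for lab, (s, _) in self.code_table.items() if s == code]
            if not labs:
                raise KeyError(f"no labels for subfield {code!r}")
            return np.isin(self.labels, labs)
        return self.labels == self.label_for(code)

    def area_um2(self, code: str) -> float:
        return float(self.mask(code).sum()) * self.pixel_area_um2

    # -- derived geometry ------------------------------------------------
    def boundary_distance_um(self, code_a: str, code_b: str) -> np.ndarray:
        """Distance (um) of every pixel to the interface between two regions.

        The interface is the set of pixels of either region that 4-neighbour
        the other; distances are Euclidean from that set.  Used for the
        derived "SR/SLM border" scope.
        """
        a, b = self.mask(code_a), self.mask(code_b)
        st = ndimage.generate_binary_structure(2, 1)
        iface = (a & ndimage.binary_dilation(b, st)) | (b & ndimage.binary_dilation(a, st))
        if not iface.any():
            return np.full(self.shape, np.inf)
        return ndimage.distance_transform_edt(~iface) * self.pixel_size

    # -- IO --------------------------------------------------------------
    def to_tiff(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.labels.astype(np.int32),
                         metadata={"pixel_size_um": self.pixel_size})
        table = pd.DataFrame(
            [(lab, s, l, region_code(s, l)) for lab, (s, l) in sorted(self.code_table.items())],
            columns=["label", "subfield", "lamina", "region"])
        table.to_csv(path.with_suffix(".codes.csv"), index=False)

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float | None = None) -> "LaminaLabelMap":
        path = Path(path)
        labels = tifffile.imread(path)
        codes_csv = path.with_suffix(".codes.csv")
        if codes_csv.exists():
            df = pd.read_csv(codes_csv)
            table = {int(r.label): (str(r.subfield), str(r.lamina)) for r in df.itertuples()}
        else:
            table = dict(CANONICAL_LABELS)
        if pixel_size is None:
            with tifffile.TiffFile(path) as tf:
                meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
            pixel_size = float(meta.get("pixel_size_um", 0) or 0)
            if pixel_size <= 0:
                raise ValueError(
                    f"{path}: no pixel size in metadata; pass pixel_size explicitly")
        return cls(labels, table, pixel_size)

    @classmethod
    def from_polygons(cls, path_or_spec, shape: tuple[int, int],
                      pixel_size: float) -> "LaminaLabelMap":
        """Rasterise named polygons (JSON) into a label map.

        The file holds ``[{"subfield": .., "lamina": .., "polygon":
        [[x, y], ...]}, ...]`` with vertices in pixel units.  A pixel belongs
        to a polygon when its *centre* is inside under the even-odd rule.
        Later polygons overwrite earlier ones.
        """
        if isinstance(path_or_spec, (str, Path)):
            spec = json.loads(Path(path_or_spec).read_text())
        else:
            spec = path_or_spec
        labels = np.zeros(shape, dtype=np.int32)
        table: dict[int, tuple[str, str]] = {}
        inv = {v: k for k, v in CANONICAL_LABELS.items()}
        next_free = max(CANONICAL_LABELS) + 1
        for entry in spec:
            key = (entry["subfield"], entry["lamina"])
            lab = inv.get(key)
            if lab is None:
                lab, next_free = next_free, next_free + 1
            table[lab] = key
            poly = np.asarray(entry["polygon"], dtype=float)
            labels[_points_in_polygon_evenodd(shape, poly)] = lab
        return cls(labels, table, pixel_size)


def _points_in_polygon_evenodd(shape: tuple[int, int], poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test on pixel centres.

    Vertices are (x, y) in pixel units; pixel centres are at integer
    coordinates.  Vectorised ray casting along +x.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    px, py = xx.astype(float), yy.astype(float)
    inside = np.zeros(shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    return inside
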