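"""Schematic hippocampal geometry for the synthetic cohort.

The layout is deliberately schematic rather than anatomically warped: what
the downstream measurements consume is region *membership*, never shape.  The
field of view holds the CA subfields as two side-by-side columns of stacked
laminar bands (CA1 left, CA2/3 right; SO | SP | SR | SLM from the top, i.e.
outer side, inward) and the dentate gyrus below them spanning the full
interior width (MO | SG | H).  A sinusoidal vertical offset shared by all
band boundaries gives the bands a gentle, parallel curvature so that
segmentation cannot rely on exact straightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import CANONICAL_LABELS, LaminaLabelMap


class GeometryError(ValueError):
    """Raised when a band layout cannot fit the requested raster."""


@dataclass
class GeometrySpec:
    """Band layout of the synthetic hippocampus.

    Thicknesses are in micrometres.  ``ca1_fraction`` is the fraction of the
    interior width given to CA1 (the WFS1-high side); ``curvature_um`` is the
    amplitude of the shared sinusoidal offset of all band boundaries.
    """

    image_size: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.325
    margin_um: float = 15.0
    ca_bands: tuple[tuple[str, float], ...] = (
        ("SO", 40.0), ("SP", 20.0), ("SR", 60.0), ("SLM", 40.0))
    dg_bands: tuple[tuple[str, float], ...] = (
        ("MO", 50.0), ("SG", 20.0), ("H", 60.0))
    ca1_fraction: float = 0.5
    curvature_um: float = 10.0
    subfields: tuple[str, ...] = ("CA1", "CA23", "DG")

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        for name, th in (*self.ca_bands, *self.dg_bands):
            if th <= 0:
                raise GeometryError(f"band {name!r} has non-positive thickness {th}")
        if not 0.0 < self.ca1_fraction < 1.0 and {"CA1", "CA23"} <= set(self.subfields):
            raise GeometryError("ca1_fraction must lie strictly in (0, 1)")
        h, w = self.image_size
        total_px = self.total_thickness_um() / self.pixel_size
        budget = h - 2 * self.margin_um / self.pixel_size - 2 * abs(
            self.curvature_um) / self.pixel_size
        if total_px > budget:
            # name the first band that overflows, walking the stack
            cum = 0.0
            for name, th in (*(self.ca_bands if set(self.subfields) & {"CA1", "CA23"} else ()),
                             *(self.dg_bands if "DG" in self.subfields else ())):
                cum += th / self.pixel_size
                if cum > budget:
                    raise GeometryError(
                        f"band {name!r} ({th} um) exceeds the image extent: "
                        f"stack needs {total_px:.0f} px, only {budget:.0f} available")
            raise GeometryError("band stack exceeds the image extent")

    def total_thickness_um(self) -> float:
        tot = 0.0
        if set(self.subfields) & {"CA1", "CA23"}:
            tot += sum(th for _, th in self.ca_bands)
        if "DG" in self.subfields:
            tot += sum(th for _, th in self.dg_bands)
        return tot


def build_geometry(spec: GeometrySpec) -> LaminaLabelMap:
    """Render the band layout into a :class:`LaminaLabelMap`.

    Every interior pixel receives background or exactly one (subfield,
    lamina) label; laminae partition their subfield exactly by construction.
    """
    spec.validate()
    h, w = spec.image_size
    ps = spec.pixel_size
    m = int(round(spec.margin_um / ps))
    labels = np.zeros((h, w), dtype=np.int32)
    inv = {v: k for k, v in CANONICAL_LABELS.items()}

    x = np.arange(w)
    interior = (x >= m) & (x < w - m)
    wint = max(int(w - 2 * m), 1)
    amp = spec.curvature_um / ps
    # shared boundary offset: parallel curved bands
    offset = amp * (1.0 + np.sin(np.pi * (x - m) / wint)) / 1.0
    offset = np.where(interior, offset, 0.0)

    has_ca = bool(set(spec.subfields) & {"CA1", "CA23"})
    rows_top = np.full(w, float(m)) + offset

    yy = np.arange(h)[:, None].astype(float)

    def paint(band_rows_top: np.ndarray, thickness_um: float, label_left: int,
              label_right: int | None, split_col: int | None) -> np.ndarray:
        th = thickness_um / ps
        sel = (yy >= band_rows_top[None, :]) & (yy < band_rows_top[None, :] + th)
        sel &= interior[None, :]
        if label_right is None or split_col is None:
            labels[sel] = label_left
        else:
            colsel = x[None, :] < split_col
            labels[sel & colsel] = label_left
            labels[sel & ~colsel] = label_right
        return band_rows_top + th

    split_col = m + int(round(spec.ca1_fraction * wint))
    if has_ca:
        only = None
        if "CA1" not in spec.subfields:
            only = "CA23"
        elif "CA23" not in spec.subfields:
            only = "CA1"
        for lam, th in spec.ca_bands:
            if only is not None:
                rows_top = paint(rows_top, th, inv[(only, lam)], None, None)
            else:
                rows_top = paint(rows_top, th, inv[("CA1", lam)],
                                 inv[("CA23", lam)], split_col)
    if "DG" in spec.subfields:
        for lam, th in spec.dg_bands:
            rows_top = paint(rows_top, th, inv[("DG", lam)], None, None)

    present = {lab: CANONICAL_LABELS[lab] for lab in np.unique(labels) if lab > 0}
    for lab, (sub, lam) in CANONICAL_LABELS.items():
        if sub in spec.subfields and lab not in present:
            raise GeometryError(f"region {sub}_{lam} rendered empty; "
                                "check band thicknesses against image size")
    return LaminaLabelMap(labels, dict(CANONICAL_LABELS), ps)
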