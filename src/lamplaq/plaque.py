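"""Amyloid plaque masking and per-region area-fraction measurement.

The plaque mask follows the slide-analysis dialect exactly: the channel is
linearly rescaled to the 8-bit range, a 256-bin histogram is auto-thresholded
with the Triangle (Zack) rule, foreground components are labelled with
8-connectivity and only particles whose physical area strictly exceeds the
cutoff (10 um^2 by default) survive.  Measurements are pixel counts times
pixel area: per lamina, per subfield and for the whole hippocampus, with
aggregates pooled at the pixel level rather than averaged over fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label, regionprops

DEFAULT_MIN_AREA_UM2 = 10.0


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle (Zack) auto-threshold on a 256-bin histogram.

    Locates the histogram peak, picks the longer tail, draws the line from
    (peak, peak height) to (tail end, 0) and returns the bin maximising the
    perpendicular distance from the histogram to that line.  A symmetric
    histogram uses the right tail; distance ties break toward the peak.
    The returned bin is intended as an exclusive lower bound for
    foreground (foreground = bins strictly above it).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("histogram must be 1-D with at least 2 bins")
    nz = np.flatnonzero(hist)
    if nz.size < 2:
        raise ValueError("degenerate histogram: fewer than 2 non-zero bins")
    peak = int(np.argmax(hist))
    left_end, right_end = int(nz[0]), int(nz[-1])
    use_right = (right_end - peak) >= (peak - left_end)

    if use_right:
        p, e = peak, right_end
        idx = np.arange(p, e + 1)
        vals = hist[idx]
    else:
        # mirror the left tail so the scan below always walks right
        p, e = peak, 2 * peak - left_end
        idx = np.arange(p, e + 1)
        vals = hist[2 * peak - idx]

    h = hist[peak]
    # |cross((e-p, -h), (b-p, vals-h))| up to a constant factor
    d = np.abs((e - p) * (vals - h) + h * (idx - p))
    best = int(idx[np.argmax(d)])  # argmax returns the first max: tie toward peak
    if not use_right:
        best = 2 * peak - best
    return best


@dataclass
class PlaqueMask:
    """Binary plaque raster plus its surviving-particle table."""

    mask: np.ndarray
    particles: pd.DataFrame  # particle, area_um2, centroid_y, centroid_x, bbox_*
    threshold_bin: int
    threshold_intensity: float
    pixel_size: float

    @property
    def total_area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size ** 2


_EMPTY_PARTICLES = pd.DataFrame(columns=[
    "particle", "area_um2", "centroid_y", "centroid_x",
    "bbox_y0", "bbox_x0", "bbox_y1", "bbox_x1"])


def make_plaque_mask(abeta: np.ndarray, pixel_size: float,
                     min_area_um2: float = DEFAULT_MIN_AREA_UM2,
                     crop_mask: np.ndarray | None = None) -> PlaqueMask:
    """Binarise the amyloid channel and size-filter the particles.

    The Triangle threshold is computed on the 256-bin histogram of the
    8-bit-rescaled channel, by default over the bounding box of
    ``crop_mask`` when one is given (the analysed single-hippocampus crop)
    and over the whole frame otherwise.  Components are 8-connected;
    particles touching the border are retained; components whose area is
    ``<= min_area_um2`` are dropped (strict ``>`` survival rule).  An empty
    result is a valid empty mask, not an error.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    v = np.asarray(abeta, dtype=np.float64)
    if v.ndim != 2:
        raise ValueError("channel must be 2-D")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        return PlaqueMask(np.zeros(v.shape, bool), _EMPTY_PARTICLES.copy(),
                          0, vmin, pixel_size)
    scaled = np.clip(np.round((v - vmin) / (vmax - vmin) * 255.0), 0, 255).astype(np.int64)
    if crop_mask is not None:
        ys, xs = np.nonzero(crop_mask)
        crop = scaled[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    else:
        crop = scaled
    hist = np.bincount(crop.ravel(), minlength=256)[:256]
    tbin = triangle_threshold(hist)
    thr_intensity = vmin + tbin / 255.0 * (vmax - vmin)
    fg = scaled > tbin

    lab = cc_label(fg, connectivity=2)
    px_area = pixel_size ** 2
    rows = []
    keep = np.zeros(int(lab.max()) + 1, dtype=bool)
    for rp in regionprops(lab):
        area = rp.area * px_area
        if area > min_area_um2:
            keep[rp.label] = True
            cy, cx = rp.centroid
            y0, x0, y1, x1 = rp.bbox
            rows.append((len(rows) + 1, area, cy, cx, y0, x0, y1, x1))
    mask = keep[lab]
    particles = pd.DataFrame(rows, columns=_EMPTY_PARTICLES.columns) if rows \
        else _EMPTY_PARTICLES.copy()
    return PlaqueMask(mask, particles, int(tbin), thr_intensity, pixel_size)


def measure_regions(label_map, mask: PlaqueMask | np.ndarray,
                    include_aggregates: bool = True) -> pd.DataFrame:
    """Area and plaque area fraction per region, plus pooled aggregates.

    Returns one row per lamina region present in the map and, when
    requested, per subfield and for ``HIPPO``; aggregate fractions are
    pixel-pooled (total plaque pixels over total region pixels), never
    averages of per-lamina fractions.
    """
    bin_mask = mask.mask if isinstance(mask, PlaqueMask) else np.asarray(mask, bool)
    if bin_mask.shape != label_map.shape:
        raise ValueError(
            f"mask shape {bin_mask.shape} != label map shape {label_map.shape}")
    if isinstance(mask, PlaqueMask) and not np.isclose(mask.pixel_size,
                                                       label_map.pixel_size):
        raise ValueError("mask and label map disagree on pixel size")
    px_area = label_map.pixel_area_um2
    labels = label_map.labels
    nbins = int(labels.max()) + 1
    region_px = np.bincount(labels.ravel(), minlength=nbins)
    plaque_px = np.bincount(labels[bin_mask].ravel(), minlength=nbins)

    rows = []
    lamina_codes = label_map.codes()
    for code in lamina_codes:
        lab = label_map.label_for(code)
        a, p = region_px[lab] * px_area, plaque_px[lab] * px_area
        rows.append((code, a, p, 100.0 * p / a if a else np.nan))
    if include_aggregates:
        by_sub: dict[str, list[int]] = {}
        for lab, (sub, _) in label_map.code_table.items():
            if lab < nbins and region_px[lab]:
                by_sub.setdefault(sub, []).append(lab)
        for sub in ("CA1", "CA23", "DG", "CA"):
            labs = by_sub.get(sub)
            if not labs:
                continue
            a = sum(region_px[l] for l in labs) * px_area
            p = sum(plaque_px[l] for l in labs) * px_area
            rows.append((sub, a, p, 100.0 * p / a if a else np.nan))
        a = region_px[1:].sum() * px_area
        p = plaque_px[1:].sum() * px_area
        rows.append(("HIPPO", a, p, 100.0 * p / a if a else np.nan))
    return pd.DataFrame(rows, columns=["region", "area_um2", "plaque_area_um2",
                                       "area_fraction_pct"])
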