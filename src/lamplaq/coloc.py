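"""Soma detection, lamina assignment and directional colocalization.

Immunopositive somata are detected per marker channel (threshold + 8-connected
components within a soma size range).  Detections from different channels are
identified as the same cell when their masks overlap with a Dice coefficient
of at least 0.5 (greedy one-to-one matching, an objective surrogate for the
visual overlap judgement of the original counts).  Cells carry a per-marker
positivity map; directional overlap percentages — e.g. the fraction of
APP-positive cells that are Reelin-positive — are conditional frequencies
over a lamina scope, with the derived "SR/SLM border" scope defined as
centroids within a configurable distance (20 um by default) of the SR-SLM
interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .regions import LaminaLabelMap

DEFAULT_BORDER_UM = 20.0


@dataclass
class Detection:
    """One above-threshold component in a single marker channel."""
    pixels: np.ndarray       # sorted flat indices
    centroid: tuple[float, float]
    area_um2: float


@dataclass
class CellRecord:
    """One detected soma with per-marker positivity."""
    cell_id: int
    centroid: tuple[float, float]
    area_um2: float
    positivity: dict[str, bool] = field(default_factory=dict)
    pixels: np.ndarray | None = None
    lamina: str | None = None          # region code or "outside"
    border_distance_um: float = np.inf

    def positive(self, marker: str) -> bool:
        return bool(self.positivity.get(marker, False))


def detect_positive_cells(channel: np.ndarray, pixel_size: float,
                          threshold: str | float = "otsu",
                          min_area_um2: float = 40.0,
                          max_area_um2: float = 140.0) -> list[Detection]:
    """Detect immunopositive somata in one channel.

    Threshold (auto-Otsu by default, or a fixed value reproducing manual
    thresholding), 8-connected components, keep components whose area lies
    in the soma range, centroid is the intensity-weighted centre.  An empty
    result is valid; a constant channel yields no detections.
    """
    v = np.asarray(channel, dtype=np.float64)
    if v.ndim != 2:
        raise ValueError("channel must be 2-D")
    if not np.isfinite(v).all():
        raise ValueError("channel contains non-finite intensities")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold policy {threshold!r}")
        if np.ptp(v) == 0:
            return []
        thr = float(threshold_otsu(v))
    else:
        thr = float(threshold)
    fg = v > thr
    lab = cc_label(fg, connectivity=2)
    px_area = pixel_size ** 2
    out: list[Detection] = []
    if lab.max() == 0:
        return out
    flat = lab.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labs = flat[order]
    starts = np.searchsorted(sorted_labs, np.arange(1, lab.max() + 1))
    ends = np.searchsorted(sorted_labs, np.arange(1, lab.max() + 1), side="right")
    w = v.shape[1]
    for lo, hi in zip(starts, ends):
        idx = np.sort(order[lo:hi])
        area = idx.size * px_area
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        ys, xs = idx // w, idx % w
        wts = v.ravel()[idx]
        wsum = wts.sum()
        cy, cx = float((ys * wts).sum() / wsum), float((xs * wts).sum() / wsum)
        out.append(Detection(idx, (cy, cx), area))
    return out


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.intersect1d(a, b, assume_unique=True).size
    return 2.0 * inter / (a.size + b.size) if (a.size + b.size) else 0.0


def merge_detections(detections_by_marker: dict[str, list[Detection]],
                     pixel_size: float, soma_radius_um: float = 5.0,
                     dice_min: float = 0.5) -> list[CellRecord]:
    """Fuse per-channel detections into cells by greedy Dice matching.

    Channels are processed in the given order; within a channel every
    detection is matched to at most one existing cell (the highest-Dice
    pairing first, each cell used once per channel, Dice >= ``dice_min``),
    unmatched detections found new cells.  Matching is one-to-one and the
    resulting counts are independent of cell ordering within a channel.
    """
    cells: list[CellRecord] = []
    search_r = 4.0 * soma_radius_um / pixel_size
    for marker, dets in detections_by_marker.items():
        if cells and dets:
            tree = cKDTree([c.centroid for c in cells])
            pairs = []
            for di, det in enumerate(dets):
                for ci in tree.query_ball_point(det.centroid, search_r):
                    d = _dice(det.pixels, cells[ci].pixels)
                    if d >= dice_min:
                        pairs.append((d, di, ci))
            pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
            used_d: set[int] = set()
            used_c: set[int] = set()
            for d, di, ci in pairs:
                if di in used_d or ci in used_c:
                    continue
                used_d.add(di)
                used_c.add(ci)
                cells[ci].positivity[marker] = True
        else:
            used_d = set()
        for di, det in enumerate(dets):
            if di in used_d:
                continue
            cells.append(CellRecord(len(cells), det.centroid, det.area_um2,
                                    {marker: True}, det.pixels))
    for c in cells:
        for marker in detections_by_marker:
            c.positivity.setdefault(marker, False)
    return cells


def assign_laminae(cells: list[CellRecord], label_map: LaminaLabelMap,
                   border_um: float = DEFAULT_BORDER_UM,
                   subfield: str = "CA1") -> list[CellRecord]:
    """Attach the lamina at each centroid plus the SR/SLM border distance.

    A centroid outside the image or on background is "outside"; a centroid
    exactly on the interface (distance 0) is inside the border scope.
    """
    h, w = label_map.shape
    sr, slm = f"{subfield}_SR", f"{subfield}_SLM"
    try:
        border_d = label_map.boundary_distance_um(sr, slm)
    except KeyError:
        border_d = np.full(label_map.shape, np.inf)
    for c in cells:
        iy, ix = int(round(c.centroid[0])), int(round(c.centroid[1]))
        if not (0 <= iy < h and 0 <= ix < w) or label_map.labels[iy, ix] == 0:
            c.lamina = "outside"
            c.border_distance_um = np.inf
            continue
        sub, lam = label_map.code_table[int(label_map.labels[iy, ix])]
        c.lamina = f"{sub}_{lam}"
        c.border_distance_um = float(border_d[iy, ix])
    return cells


def in_scope(cell: CellRecord, scope: str, border_um: float = DEFAULT_BORDER_UM,
             subfield: str = "CA1") -> bool:
    """Scope membership: lamina codes, derived border/interior scopes, or pools.

    Scopes: ``"all"``; a subfield (``"CA1"``); a full region code
    (``"CA1_SO"``) or bare lamina (``"SO"``, resolved within ``subfield``);
    ``"border"`` (SR or SLM, within ``border_um`` of the interface);
    ``"SR_int"`` / ``"SLM_int"`` (the lamina minus the border strip).
    """
    if cell.lamina is None:
        raise ValueError("cells must pass through assign_laminae first")
    if scope == "all":
        return cell.lamina != "outside"
    if cell.lamina == "outside":
        return False
    sub, lam = cell.lamina.split("_", 1)
    if scope in ("CA1", "CA23", "DG"):
        return sub == scope
    if scope == "border":
        return sub == subfield and lam in ("SR", "SLM") \
            and cell.border_distance_um <= border_um
    if scope == "SR_int":
        return sub == subfield and lam == "SR" and cell.border_distance_um > border_um
    if scope == "SLM_int":
        return sub == subfield and lam == "SLM" and cell.border_distance_um > border_um
    if "_" in scope:
        return cell.lamina == scope
    return sub == subfield and lam == scope


@dataclass
class ColocResult:
    """Directional overlap: fraction of A-positive cells also B-positive."""
    marker_a: str
    marker_b: str
    scope: str
    n_a: int
    n_ab: int
    percentage: float | None

    @property
    def defined(self) -> bool:
        return self.percentage is not None


def coloc_percentages(cells: list[CellRecord], marker_a: str, marker_b: str,
                      scope: str = "all",
                      border_um: float = DEFAULT_BORDER_UM) -> ColocResult:
    """Directional conditional frequency P(B+ | A+) over a scope.

    Undefined (no A-positive cells in scope) is flagged with a ``None``
    percentage, never reported as 0.
    """
    in_sc = [c for c in cells if in_scope(c, scope, border_um)]
    n_a = sum(c.positive(marker_a) for c in in_sc)
    n_ab = sum(c.positive(marker_a) and c.positive(marker_b) for c in in_sc)
    if n_a == 0:
        warnings.warn(f"no {marker_a}-positive cells in scope {scope!r}; "
                      "percentage undefined", stacklevel=2)
        return ColocResult(marker_a, marker_b, scope, 0, 0, None)
    return ColocResult(marker_a, marker_b, scope, n_a, n_ab, 100.0 * n_ab / n_a)


def laminar_distribution(cells: list[CellRecord], marker: str,
                         scopes: tuple[str, ...] = ("SO", "SP", "border",
                                                    "SR_int", "SLM_int"),
                         border_um: float = DEFAULT_BORDER_UM) -> pd.DataFrame:
    """Percentage of marker-positive cells per region scope.

    Percentages are over the marker-positive cells falling in any of the
    requested scopes and sum to 100 up to rounding; zero positive cells is
    flagged as undefined (NaN percentages).
    """
    pos = [c for c in cells if c.positive(marker)]
    counts = {s: sum(in_scope(c, s, border_um) for c in pos) for s in scopes}
    total = sum(counts.values())
    if total == 0:
        warnings.warn(f"no {marker}-positive cells in the requested scopes; "
                      "distribution undefined", stacklevel=2)
        return pd.DataFrame({"scope": list(scopes),
                             "count": [0] * len(scopes),
                             "percentage": [np.nan] * len(scopes)})
    return pd.DataFrame({"scope": list(scopes),
                         "count": [counts[s] for s in scopes],
                         "percentage": [100.0 * counts[s] / total for s in scopes]})


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    """Flatten cell records for CSV export (one boolean column per marker)."""
    markers = sorted({m for c in cells for m in c.positivity})
    rows = []
    for c in cells:
        rows.append({"cell_id": c.cell_id, "y": c.centroid[0], "x": c.centroid[1],
                     "lamina": c.lamina, "area_um2": c.area_um2,
                     "border_distance_um": c.border_distance_um,
                     **{m: c.positive(m) for m in markers}})
    return pd.DataFrame(rows)
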