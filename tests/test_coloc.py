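"""Soma detection, cross-channel matching and directional overlap counting."""

import copy

import numpy as np
import pandas as pd
import pytest

from lamplaq import (assign_laminae, build_geometry, coloc_percentages,
                     detect_positive_cells, in_scope, laminar_distribution,
                     merge_detections, render_channels, sample_cells)
from lamplaq.simulate import MARKERS
from lamplaq.presets import fig1_cell_config, fig1_geometry


@pytest.fixture(scope="module")
def fig1_map():
    return build_geometry(fig1_geometry())


@pytest.fixture(scope="module")
def fig1_cfg():
    return fig1_cell_config()


@pytest.fixture(scope="module")
def noiseless_cellmap(fig1_map, fig1_cfg):
    cfg = copy.deepcopy(fig1_cfg)
    cfg.noise.read_sigma = 0.0
    cfg.noise.shot_coeff = 0.0
    img, gt = render_channels(fig1_map, cfg, "control", 3.0, 101)
    return img, gt


@pytest.fixture(scope="module")
def noisy_cellmap(fig1_map, fig1_cfg):
    img, gt = render_channels(fig1_map, fig1_cfg, "control", 3.0, 101)
    return img, gt


def _pipeline_cells(img, fig1_map, markers=MARKERS):
    dets = {m: detect_positive_cells(img.channel(m), img.pixel_size)
            for m in markers}
    return assign_laminae(merge_detections(dets, img.pixel_size), fig1_map)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_noiseless_detection_count_exact(noiseless_cellmap):
    img, gt = noiseless_cellmap
    k_planted = int(gt.cells.APP.sum())
    dets = detect_positive_cells(img.channel("APP"), img.pixel_size)
    assert len(dets) == k_planted


def test_blank_channel_zero_detections():
    assert detect_positive_cells(np.full((64, 64), 0.05), 1.0) == []


def test_default_noise_detection_f1(noisy_cellmap, fig1_cfg):
    """Detection F1 >= 0.95 against planted somata at soma-radius matching."""
    img, gt = noisy_cellmap
    dets = detect_positive_cells(img.channel("APP"), img.pixel_size)
    planted = gt.cells[gt.cells.APP][["y", "x"]].to_numpy()
    r_px = fig1_cfg.cells.soma_radius_um / img.pixel_size
    from scipy.spatial import cKDTree
    if len(dets) == 0:
        pytest.fail("no detections")
    got = np.array([d.centroid for d in dets])
    tree = cKDTree(planted)
    dist, idx = tree.query(got)
    matched = set()
    tp = 0
    for d, i in sorted(zip(dist, idx)):
        if d <= r_px and i not in matched:
            matched.add(i)
            tp += 1
    prec, rec = tp / len(got), tp / len(planted)
    f1 = 2 * prec * rec / (prec + rec)
    assert f1 >= 0.95


# ---------------------------------------------------------------------------
# lamina assignment and scopes
# ---------------------------------------------------------------------------

def test_lamina_assignment_matches_planted_scopes(noisy_cellmap, fig1_map):
    """Recovered scope equals the planted scope for every detected APP+ cell.

    The generator keeps interior placements clear of the border strip, so
    scope recovery should be exact despite centroid jitter.
    """
    img, gt = noisy_cellmap
    cells = _pipeline_cells(img, fig1_map)
    app = [c for c in cells if c.positive("APP")]
    planted = gt.cells[gt.cells.APP]
    from scipy.spatial import cKDTree
    tree = cKDTree(planted[["y", "x"]].to_numpy())
    agree = total = 0
    for c in app:
        d, i = tree.query(c.centroid)
        if d > 3:
            continue
        total += 1
        scope = planted.iloc[i].scope_true
        agree += in_scope(c, scope)
    assert total > 30
    assert agree == total


def test_centroid_on_boundary_included_in_border_scope(fig1_map):
    from lamplaq.coloc import CellRecord
    c = CellRecord(0, (0, 0), 78.0, {"APP": True})
    c.lamina = "CA1_SR"
    c.border_distance_um = 0.0
    assert in_scope(c, "border")
    c.border_distance_um = 20.0
    assert in_scope(c, "border")
    c.border_distance_um = 20.1
    assert not in_scope(c, "border")
    assert in_scope(c, "SR_int")


def test_centroid_outside_image_is_outside(fig1_map):
    from lamplaq.coloc import CellRecord
    c = CellRecord(0, (-5.0, 10.0), 78.0, {"APP": True})
    assign_laminae([c], fig1_map)
    assert c.lamina == "outside"
    assert not in_scope(c, "all")


# ---------------------------------------------------------------------------
# colocalization percentages
# ---------------------------------------------------------------------------

def test_forced_coexpression_recovers_exactly_100(noisy_cellmap, fig1_map):
    """Generator forces GABABR1 wherever APP: pipeline returns exactly 100."""
    img, _ = noisy_cellmap
    cells = _pipeline_cells(img, fig1_map, markers=("APP", "GABABR1"))
    res = coloc_percentages(cells, "APP", "GABABR1", scope="border")
    assert res.defined
    assert res.percentage == 100.0


def test_disjoint_populations_zero_percent():
    from lamplaq.coloc import CellRecord
    cells = []
    for i in range(10):
        c = CellRecord(i, (10.0 + i, 10.0), 78.0,
                       {"APP": i < 5, "Reelin": i >= 5})
        c.lamina = "CA1_SO"
        c.border_distance_um = np.inf
        cells.append(c)
    res = coloc_percentages(cells, "APP", "Reelin", scope="SO")
    assert res.percentage == 0.0
    assert res.n_a == 5


def test_no_positive_cells_flagged_undefined():
    from lamplaq.coloc import CellRecord
    c = CellRecord(0, (1.0, 1.0), 78.0, {"APP": False, "CCK": True})
    c.lamina = "CA1_SO"
    c.border_distance_um = np.inf
    with pytest.warns(UserWarning, match="undefined"):
        res = coloc_percentages([c], "APP", "CCK", scope="all")
    assert res.percentage is None
    assert not res.defined


def test_directionality_shares_matched_set(noisy_cellmap, fig1_map):
    """n(A+B+) is identical in both directions of the same matched set."""
    img, _ = noisy_cellmap
    cells = _pipeline_cells(img, fig1_map, markers=("APP", "Reelin"))
    ab = coloc_percentages(cells, "APP", "Reelin", scope="border")
    ba = coloc_percentages(cells, "Reelin", "APP", scope="border")
    assert ab.n_ab == ba.n_ab


def test_matching_invariant_to_cell_order(noisy_cellmap, fig1_map):
    img, _ = noisy_cellmap
    dets = {m: detect_positive_cells(img.channel(m), img.pixel_size)
            for m in ("APP", "GABABR1", "Reelin")}
    base = merge_detections(dets, img.pixel_size)
    shuffled = {m: list(reversed(d)) for m, d in dets.items()}
    perm = merge_detections(shuffled, img.pixel_size)
    def counts(cells):
        return sorted((sum(c.positive(m) for m in ("APP", "GABABR1", "Reelin")),
                       round(c.centroid[0], 1)) for c in cells)
    assert counts(base) == counts(perm)


# ---------------------------------------------------------------------------
# laminar distribution
# ---------------------------------------------------------------------------

def test_all_cells_one_scope_distribution():
    from lamplaq.coloc import CellRecord
    cells = []
    for i in range(7):
        c = CellRecord(i, (1.0, 1.0 + i), 78.0, {"APP": True})
        c.lamina = "CA1_SO"
        c.border_distance_um = np.inf
        cells.append(c)
    dist = laminar_distribution(cells, "APP").set_index("scope")
    assert dist.percentage["SO"] == 100.0
    assert dist.percentage.drop("SO").eq(0).all()


def test_distribution_sums_to_100(noisy_cellmap, fig1_map):
    img, _ = noisy_cellmap
    cells = _pipeline_cells(img, fig1_map)
    dist = laminar_distribution(cells, "APP")
    assert dist.percentage.sum() == pytest.approx(100.0)


def test_planted_laminar_split_recovered(fig1_map, fig1_cfg):
    """Planted 60/20 border/SO split recovered within the multinomial CI."""
    rng = np.random.default_rng(77)
    frames = []
    for sec in range(6):
        img, _ = render_channels(fig1_map, fig1_cfg, "control", 3.0,
                                 np.random.SeedSequence([77, sec]))
        frames.append(_pipeline_cells(img, fig1_map))
    cells = [c for f in frames for c in f]
    dist = laminar_distribution(cells, "APP").set_index("scope")
    n = dist["count"].sum()
    for scope, p in (("border", 0.60), ("SO", 0.20)):
        se = 100 * np.sqrt(p * (1 - p) / n)
        assert abs(dist.percentage[scope] - 100 * p) <= 1.96 * se + 100 / n


def test_zero_cells_distribution_flagged():
    with pytest.warns(UserWarning, match="undefined"):
        dist = laminar_distribution([], "APP")
    assert dist.percentage.isna().all()
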