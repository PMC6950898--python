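"""Plaque masking: Triangle-threshold oracle, particle filter semantics,
region measurement against a brute-force pixel count."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lamplaq import (LaminaLabelMap, make_plaque_mask, measure_regions,
                     triangle_threshold)


# ---------------------------------------------------------------------------
# triangle threshold
# ---------------------------------------------------------------------------

def triangle_bruteforce(hist: np.ndarray) -> int:
    """Independent oracle: exhaustive perpendicular-distance maximisation.

    Explicit point-to-line distances |Ax + By + C| / sqrt(A^2 + B^2) for the
    line through (peak, h) and (end, 0), scanned over every candidate bin on
    the longer-tail side, ties broken toward the peak.
    """
    hist = np.asarray(hist, float)
    nz = np.flatnonzero(hist)
    peak = int(np.argmax(hist))
    left, right = int(nz[0]), int(nz[-1])
    end = right if (right - peak) >= (peak - left) else left
    h = hist[peak]
    # line through (peak, h) and (end, 0); normal (h, end - peak)
    denom = np.hypot(h, end - peak)
    best, best_d = peak, -1.0
    # scan outward from the peak so ties resolve toward it
    order = range(peak, end + 1) if end >= peak else range(peak, end - 1, -1)
    for b in order:
        d = abs(h * (b - peak) + (end - peak) * (hist[b] - h)) / denom
        if d > best_d + 1e-12:
            best, best_d = b, d
    return best


@st.composite
def histograms(draw):
    n = draw(st.integers(min_value=2, max_value=256))
    positions = draw(st.lists(st.integers(0, 255), min_size=2, max_size=n,
                              unique=True))
    hist = np.zeros(256, dtype=float)
    for p in positions:
        hist[p] = draw(st.integers(1, 10000))
    return hist


@settings(max_examples=200, deadline=None, derandomize=True)
@given(histograms())
def test_triangle_matches_bruteforce_oracle(hist):
    assert triangle_threshold(hist) == triangle_bruteforce(hist)


def test_triangle_oracle_on_random_histograms_bulk():
    """1000 seeded random 256-bin histograms, implementation == oracle."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        hist = np.zeros(256)
        k = rng.integers(2, 60)
        pos = rng.choice(256, size=k, replace=False)
        hist[pos] = rng.integers(1, 5000, size=k)
        assert triangle_threshold(hist) == triangle_bruteforce(hist)


def test_triangle_symmetric_histogram_uses_right_tail():
    hist = np.zeros(256)
    hist[100:157] = np.concatenate([np.arange(1, 30), np.arange(28, 0, -1)])
    t = triangle_threshold(hist)
    assert t >= 128  # peak at 128; right tail chosen on the tie


def test_triangle_two_spike_threshold_between_spikes():
    hist = np.zeros(256)
    hist[10], hist[200] = 100000, 500
    t = triangle_threshold(hist)
    assert 10 < t < 200


def test_triangle_linear_decay_example():
    """Peak at 10, linear decay to a far spike at 200: matches the oracle."""
    hist = np.zeros(256)
    hist[10] = 5000
    hist[11:200] = np.linspace(400, 2, 189)
    hist[200] = 50
    assert triangle_threshold(hist) == triangle_bruteforce(hist)


def test_triangle_shift_equivariance():
    """Adding a constant to all intensities shifts the threshold bin equally."""
    rng = np.random.default_rng(0)
    hist = np.zeros(256)
    hist[5:80] = rng.integers(1, 1000, size=75)
    shift = 40
    shifted = np.zeros(256)
    shifted[5 + shift:80 + shift] = hist[5:80]
    assert triangle_threshold(shifted) == triangle_threshold(hist) + shift


def test_triangle_degenerate_histogram_raises():
    hist = np.zeros(256)
    hist[7] = 10
    with pytest.raises(ValueError, match="degenerate"):
        triangle_threshold(hist)


# ---------------------------------------------------------------------------
# particle filter
# ---------------------------------------------------------------------------

def _square_image(pixel_counts, pixel_size, gap=8, value=200.0, bg=10.0):
    side = int(np.ceil(np.sqrt(max(pixel_counts))))
    img = np.full((side + 2 * gap, (side + gap) * len(pixel_counts) + gap), bg)
    x = gap
    for n in pixel_counts:
        s = int(np.sqrt(n))
        cols = n // s
        img[gap:gap + s, x:x + cols] = value
        rem = n - s * cols
        if rem:
            img[gap + s, x:x + rem] = value
        x += side + gap
    return img


def test_size_filter_keeps_only_above_10um2():
    """Particles of {4, 9, 25, 100} um^2: exactly the 25 and 100 survive."""
    ps = 0.5  # 0.25 um^2 per pixel
    counts = [int(a / ps ** 2) for a in (4, 9, 25, 100)]
    img = _square_image(counts, ps)
    mask = make_plaque_mask(img, ps, min_area_um2=10.0)
    assert len(mask.particles) == 2
    assert sorted(mask.particles.area_um2) == pytest.approx([25.0, 100.0])


def test_exactly_10um2_particle_excluded():
    ps = 0.5
    img = _square_image([40], ps)  # 40 px * 0.25 = 10.0 um^2 exactly
    mask = make_plaque_mask(img, ps, min_area_um2=10.0)
    assert len(mask.particles) == 0
    assert not mask.mask.any()


def test_filter_monotonicity():
    """Raising min_area never increases total mask area."""
    rng = np.random.default_rng(1)
    img = (rng.random((128, 128)) > 0.7).astype(float) * 200 + 10
    prev = np.inf
    for min_area in (0.0, 2.0, 5.0, 10.0, 50.0):
        m = make_plaque_mask(img, 1.0, min_area_um2=min_area)
        assert m.total_area_um2 <= prev
        prev = m.total_area_um2


def test_constant_channel_yields_valid_empty_mask():
    m = make_plaque_mask(np.full((32, 32), 7.0), 1.0)
    assert not m.mask.any()
    assert len(m.particles) == 0


def test_noisy_cohort_area_recovery_within_10pct(rendered_control, map_small):
    """Default-noise synthetic animal: recovered plaque area within 10 %."""
    img, gt = rendered_control
    mask = make_plaque_mask(img.channel("ABETA"), img.pixel_size,
                            crop_mask=map_small.mask("HIPPO"))
    meas = measure_regions(map_small, mask).set_index("region")
    truth = gt.regions.set_index("region")
    for code in truth.index:
        planted = truth.plaque_area_um2[code]
        if planted < 200:  # skip regions with trivial planted area
            continue
        assert meas.plaque_area_um2[code] == pytest.approx(planted, rel=0.10), code


# ---------------------------------------------------------------------------
# region measurement
# ---------------------------------------------------------------------------

def _random_label_map(rng, n_labels=4, size=64):
    labels = rng.integers(0, n_labels + 1, size=(size, size)).astype(np.int32)
    table = {i: ("CA1", lam) for i, lam in
             zip(range(1, n_labels + 1), ("SO", "SP", "SR", "SLM"))}
    return LaminaLabelMap(labels, table, pixel_size=1.0)


def test_measurement_equals_bruteforce_double_loop():
    """Area fractions equal an O(N^2) per-pixel count on random instances."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        lm = _random_label_map(rng)
        mask = rng.random(lm.shape) > 0.5
        meas = measure_regions(lm, mask, include_aggregates=False)
        for row in meas.itertuples():
            lab = lm.label_for(row.region)
            reg_px = plq_px = 0
            for y in range(lm.shape[0]):
                for x in range(lm.shape[1]):
                    if lm.labels[y, x] == lab:
                        reg_px += 1
                        plq_px += bool(mask[y, x])
            assert row.area_um2 == reg_px * 1.0
            assert row.plaque_area_um2 == plq_px * 1.0
            expect = 100.0 * plq_px / reg_px if reg_px else np.nan
            assert row.area_fraction_pct == pytest.approx(expect)


def test_zero_and_full_masks(map_small):
    zero = measure_regions(map_small, np.zeros(map_small.shape, bool))
    assert (zero.area_fraction_pct == 0).all()
    full = np.zeros(map_small.shape, bool)
    full[map_small.mask("CA1_SP")] = True
    meas = measure_regions(map_small, full).set_index("region")
    assert meas.area_fraction_pct["CA1_SP"] == pytest.approx(100.0)
    assert meas.area_fraction_pct["DG_H"] == 0.0


def test_aggregation_consistency(rendered_control, map_small):
    """Hippocampus plaque area equals lamina and subfield sums exactly."""
    img, _ = rendered_control
    mask = make_plaque_mask(img.channel("ABETA"), img.pixel_size)
    meas = measure_regions(map_small, mask).set_index("region")
    lam = [r for r in meas.index if "_" in r]
    subs = ["CA1", "CA23", "DG"]
    assert meas.plaque_area_um2[lam].sum() == pytest.approx(
        meas.plaque_area_um2["HIPPO"], abs=1e-6)
    assert meas.plaque_area_um2[subs].sum() == pytest.approx(
        meas.plaque_area_um2["HIPPO"], abs=1e-6)


def test_shape_mismatch_rejected(map_small):
    with pytest.raises(ValueError, match="shape"):
        measure_regions(map_small, np.zeros((10, 10), bool))
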