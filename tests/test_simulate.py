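"""Generator contracts: Poisson thinning, marker sampling, ELISA, determinism."""

import copy

import numpy as np
import pandas as pd
import pytest

from lamplaq import (ConfigError, build_geometry, generate_cohort,
                     render_channels, sample_cells, sample_elisa,
                     sample_measurement_table)
from lamplaq.simulate import (CellModel, CohortSpec, EffectConfig, MarkerModel,
                              calibrate_conditional)
from lamplaq.presets import (FIG1_APP_RATE, FIG1_OVERLAPS, fig1_cell_config,
                             fig1_geometry, fig3_effect_config)


# ---------------------------------------------------------------------------
# plaques
# ---------------------------------------------------------------------------

def test_null_ratio_identical_to_control(map_small, effect_small):
    """All ratios 1 makes the cKO arm statistically identical to control."""
    cfg = copy.deepcopy(effect_small)
    cfg.cko_density_ratio = {r: 1.0 for r in cfg.cko_density_ratio}
    _, gt_c = render_channels(map_small, cfg, "control", 3.0, 7)
    _, gt_k = render_channels(map_small, cfg, "cko", 3.0, 7)
    pd.testing.assert_frame_equal(gt_c.regions, gt_k.regions)


def test_poisson_thinning_expectation(map_small, effect_small):
    """Planted cKO/control count ratio converges to the configured ratio.

    Monte-Carlo over replicate animals via the analytic twin; the CA1-SP
    ratio (0.25) must land within 3 SE of its planted value, and the planted
    mean count must match the Poisson rate within 3 SE.
    """
    cfg = copy.deepcopy(effect_small)
    cfg.animal_cv = 0.0
    reps = 200
    rng = np.random.default_rng(11)
    code = "CA1_SP"
    area_mm2 = map_small.area_um2(code) / 1e6
    lam_c = cfg.baseline_plaque_density[code] * area_mm2
    counts = {"control": [], "cko": []}
    for arm in counts:
        t = sample_measurement_table(map_small, cfg, arm, reps, 3.0, rng)
        frac = t.loc[t.region == code, "area_fraction_pct"].to_numpy()
        counts[arm] = frac * map_small.area_um2(code) / 100.0 / cfg.plaque.mean_area_um2
    mean_c = np.mean(counts["control"])
    se_c = np.std(counts["control"]) / np.sqrt(reps)
    assert abs(mean_c - lam_c) < 3 * se_c
    ratio_hat = np.mean(counts["cko"]) / mean_c
    se_ratio = ratio_hat * np.sqrt(
        np.var(counts["cko"]) / (reps * np.mean(counts["cko"]) ** 2)
        + np.var(counts["control"]) / (reps * mean_c ** 2))
    assert abs(ratio_hat - cfg.cko_density_ratio[code]) < 3 * se_ratio


def test_ground_truth_area_matches_rendered_mask(noiseless_control, map_small):
    """Planted per-region plaque area equals the pre-noise rendered area.

    With noise off, thresholding the amyloid channel at mid-intensity
    recovers the rendered foreground exactly; intersecting with each region
    must reproduce the ground-truth table to the pixel.
    """
    img, gt = noiseless_control
    fg = img.channel("ABETA") > 0.5
    px = map_small.pixel_area_um2
    for row in gt.regions.itertuples():
        rendered = (fg & map_small.mask(row.region)).sum() * px
        assert rendered == pytest.approx(row.plaque_area_um2, abs=1e-9)


def test_unknown_region_code_rejected(map_small, effect_small):
    cfg = copy.deepcopy(effect_small)
    cfg.baseline_plaque_density["CA9_XX"] = 100.0
    with pytest.raises(ConfigError, match="CA9_XX"):
        render_channels(map_small, cfg, "control", 3.0, 0)


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

def test_forced_coexpression_by_construction():
    """P(GABABR1 | APP+) = 1 in the table forces it in every sample."""
    lm = build_geometry(fig1_geometry())
    cfg = fig1_cell_config()
    _, cells = sample_cells(lm, cfg, 3)
    app = cells[cells.APP]
    assert len(app) > 0
    assert app.GABABR1.all()


def test_marker_frequencies_converge_as_sqrt_n():
    """Empirical conditionals approach the table at the multinomial rate."""
    lm = build_geometry(fig1_geometry())
    cfg = fig1_cell_config()
    rng = np.random.default_rng(9)
    devs = {}
    for n_sections in (2, 8):
        frames = [sample_cells(lm, cfg, rng)[1] for _ in range(n_sections)]
        cells = pd.concat(frames)
        border_app = cells[(cells.scope_true == "border") & cells.APP]
        emp = border_app[["Reelin", "CCK", "Calbindin"]].mean()
        planted = {m: FIG1_OVERLAPS["border"][m][0] for m in emp.index}
        devs[n_sections] = max(abs(emp[m] - planted[m]) for m in emp.index)
        n = len(border_app)
        # each conditional inside ~4 binomial SEs
        for m in emp.index:
            se = np.sqrt(planted[m] * (1 - planted[m]) / n)
            assert abs(emp[m] - planted[m]) < 4 * max(se, 1e-3)
    assert devs[8] < devs[2] * 2.5  # shrinking with n (allowing noise slack)


def test_calibrated_reverse_conditionals_match_targets():
    """The calibrated joint reproduces both directions of every overlap."""
    mm = fig1_cell_config().cells.markers
    for scope, table in FIG1_OVERLAPS.items():
        for marker, (p1, q) in table.items():
            if q is None:
                continue
            assert mm.p_app_given_marker(scope, marker) == pytest.approx(q, abs=1e-12)
            assert mm.conditionals[scope][marker][0] == p1


def test_infeasible_conditional_pair_flagged():
    with pytest.raises(ConfigError, match="infeasible"):
        calibrate_conditional(0.9, 0.05, 0.5)  # would need P(m|APP-) > 1


def test_hardcore_separation_and_density_error():
    lm = build_geometry(fig1_geometry())
    cfg = fig1_cell_config()
    _, cells = sample_cells(lm, cfg, 1)
    xy = cells[["y", "x"]].to_numpy()
    from scipy.spatial.distance import pdist
    min_sep_px = cfg.cells.min_separation_um / lm.pixel_size
    assert pdist(xy).min() >= min_sep_px - 1e-9
    crowded = copy.deepcopy(cfg)
    crowded.cells.cells_per_image = 5000
    with pytest.raises(ConfigError, match="lower the density"):
        sample_cells(lm, crowded, 1)


# ---------------------------------------------------------------------------
# ELISA
# ---------------------------------------------------------------------------

def test_elisa_null_and_degenerate_limits(effect_small):
    cfg = copy.deepcopy(effect_small)
    cfg.elisa.reduction = 0.0
    rng = np.random.default_rng(3)
    c = sample_elisa(cfg, "control", 4000, rng)
    k = sample_elisa(cfg, "cko", 4000, rng)
    assert np.mean(k) / np.mean(c) == pytest.approx(1.0, abs=0.01)
    cfg.elisa.cv = 1e-9
    vals = sample_elisa(cfg, "control", 10, rng)
    assert vals == pytest.approx(cfg.elisa.control_mean, rel=1e-4)


def test_elisa_reduction_recovery(effect_small):
    """Replicated 12-vs-12 sampling recovers the planted 17 % reduction."""
    from lamplaq.stats import percent_reduction

    rng = np.random.default_rng(17)
    reds = []
    for _ in range(300):
        c = sample_elisa(effect_small, "control", 12, rng)
        k = sample_elisa(effect_small, "cko", 12, rng)
        reds.append(percent_reduction(c, k).percent_reduction)
    se = np.std(reds) / np.sqrt(len(reds))
    assert abs(np.mean(reds) - 17.0) < 2 * se + 0.2  # small-sample ratio bias allowance


# ---------------------------------------------------------------------------
# cohort bundles
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_cohort_spec(tmp_path_factory, geo_small):
    cfg = fig3_effect_config(geo_small)
    return CohortSpec(geometry=geo_small, effect=cfg, n_per_arm=2,
                      master_seed=5, age_months=3.0,
                      out_dir=tmp_path_factory.mktemp("cohort") / "run")


def test_cohort_bundle_counts_and_determinism(tiny_cohort_spec):
    spec = tiny_cohort_spec
    manifest = generate_cohort(spec)
    images = sorted(p.name for p in manifest.parent.glob("*.ome.tif"))
    assert len(images) == 4  # 2 arms x 2 animals
    truth1 = (manifest.parent / "truth_regions.csv").read_bytes()
    with pytest.raises(FileExistsError):
        generate_cohort(spec)
    spec.overwrite = True
    generate_cohort(spec)
    assert (manifest.parent / "truth_regions.csv").read_bytes() == truth1


def test_cohort_seed_sensitivity(tmp_path, geo_small, effect_small):
    counts = {}
    for seed in (5, 6):
        spec = CohortSpec(geometry=geo_small, effect=effect_small, n_per_arm=1,
                          arms=("control",), master_seed=seed,
                          out_dir=tmp_path / f"s{seed}")
        generate_cohort(spec)
        t = pd.read_csv(tmp_path / f"s{seed}" / "truth_regions.csv")
        counts[seed] = t.plaque_count.to_numpy()
    assert (counts[5] != counts[6]).any()
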