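"""Synthetic two-arm hippocampal cohorts with known ground truth.

This module emulates the inputs of the plaque-quantification workflow — a
VGLUT1-like neuropil channel with dark cell-body bands, a WFS1-like
CA1-restricted channel, an amyloid channel with plaque blobs, soma-scale
interneuron-marker channels — together with per-animal ELISA-style Aβ42
concentrations.  Everything planted is recorded in a :class:`GroundTruth`
object so that every downstream stage (segmentation, plaque masking, region
measurement, colocalization, statistics) can be validated by parameter
recovery without any microscopy data.

Design of the amyloid model
---------------------------
Plaques are a per-region Poisson process: in region ``r`` of an animal the
expected count is ``density[r] * area[r] * ratio[r] * age_scaling[age] *
animal_mult`` where ``ratio`` is 1 in the control arm and the configured
knock-out thinning factor in the cKO arm, and ``animal_mult`` is a lognormal
per-animal multiplier (biological mouse-to-mouse variability, shared across
regions within an animal).  Plaque footprints are hard discs with lognormal
radius; the default distribution puts roughly 15 % of plaques below the
10 um^2 particle cutoff so the size filter is genuinely exercised.

Noise is additive Gaussian read noise plus an intensity-scaled Gaussian term
approximating shot noise; detector physics is deliberately out of scope.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image import MultiChannelImage, write_image
from .regions import LaminaLabelMap, SUBFIELDS
from .geometry import GeometrySpec, build_geometry

MARKERS = ("APP", "GABABR1", "PV", "SST", "CCK", "Reelin", "Calbindin", "Calretinin")

#: cell placement scopes understood by the generator and the coloc stage
CELL_SCOPES = ("SO", "SP", "border", "SR_int", "SLM_int")


class ConfigError(ValueError):
    """Invalid effect / cohort configuration."""


# ---------------------------------------------------------------------------
# configuration blocks
# ---------------------------------------------------------------------------

@dataclass
class PlaqueModel:
    """Lognormal disc-radius model; radius parameters are ln(um)."""
    radius_mu_log: float = float(np.log(2.5))
    radius_sigma_log: float = 0.35
    intensity: float = 0.9

    @property
    def mean_area_um2(self) -> float:
        """E[pi r^2] for lognormal r."""
        return float(np.pi * np.exp(2 * self.radius_mu_log + 2 * self.radius_sigma_log ** 2))

    def validate(self) -> None:
        if self.radius_sigma_log <= 0:
            raise ConfigError("radius_sigma_log must be > 0")


@dataclass
class NoiseModel:
    background: float = 0.05
    read_sigma: float = 0.015
    shot_coeff: float = 0.04  # sigma contribution = shot_coeff * sqrt(intensity)

    def validate(self) -> None:
        if self.read_sigma < 0 or self.shot_coeff < 0:
            raise ConfigError("noise sigmas must be >= 0")

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        sigma = np.sqrt(self.read_sigma ** 2 +
                        (self.shot_coeff ** 2) * np.clip(img, 0, None))
        return np.clip(img + rng.standard_normal(img.shape) * sigma, 0.0, 1.0)


@dataclass
class Appearance:
    """Pre-noise channel intensities (arbitrary units in [0, 1])."""
    neuropil: float = 0.55       # VGLUT1 in SO/SR/SLM/MO/H
    cell_body_band: float = 0.18  # VGLUT1 in SP/SG (contrast ~3:1)
    wfs1_high: float = 0.60      # WFS1 over CA1
    wfs1_low: float = 0.08       # WFS1 elsewhere in the hippocampus
    soma: float = 0.80           # positive-marker soma discs

    def validate(self) -> None:
        if self.neuropil / max(self.cell_body_band, 1e-9) < 1.0:
            raise ConfigError("neuropil must be brighter than cell-body bands")


@dataclass
class ElisaModel:
    """Lognormal per-animal soluble Ab42 concentrations (pg/mg)."""
    control_mean: float = 50.0
    reduction: float = 0.17   # cKO mean = control mean * (1 - reduction)
    cv: float = 0.09

    def validate(self) -> None:
        if self.cv <= 0:
            raise ConfigError("ELISA CV must be > 0")
        if not 0.0 <= self.reduction <= 1.0:
            raise ConfigError("ELISA reduction must be in [0, 1]")

    def mean(self, arm: str) -> float:
        return self.control_mean * (1.0 - self.reduction) if arm == "cko" \
            else self.control_mean


def calibrate_conditional(p_marker_given_app: float, p_app_given_marker: float,
                          app_rate: float) -> float:
    """Solve P(marker | APP-) from the two directional conditionals.

    The study reports conditional overlap percentages in both directions
    (fraction of APP+ cells positive for a marker, and fraction of
    marker-positive cells that are APP+).  Given an APP+ base rate ``a``
    these pin down the full 2x2 joint; this returns
    ``P(marker | APP-) = a p (1 - q) / (q (1 - a))`` and raises when the
    pair of conditionals is infeasible at that base rate.
    """
    a, p, q = app_rate, p_marker_given_app, p_app_given_marker
    if q == 0.0:
        if p != 0.0:
            raise ConfigError("P(APP|marker)=0 requires P(marker|APP+)=0")
        raise ConfigError("P(APP|marker)=0 leaves P(marker|APP-) free; set it directly")
    p0 = a * p * (1.0 - q) / (q * (1.0 - a))
    if not 0.0 <= p0 <= 1.0:
        raise ConfigError(
            f"infeasible conditional pair: P(m|APP+)={p}, P(APP|m)={q} "
            f"at APP+ rate {a} needs P(m|APP-)={p0:.3f}")
    return p0


@dataclass
class MarkerModel:
    """Per-scope joint marker model, factored through APP status.

    ``conditionals[scope][marker] = (P(marker | APP+), P(marker | APP-))``;
    markers are independent given APP status within a scope.  This is the
    minimal joint consistent with directional conditionals reported both
    ways; :func:`calibrate_conditional` builds the APP- column from a pair
    of directional percentages and flags infeasible pairs at load time.
    """
    app_rate: dict[str, float] = field(default_factory=lambda: dict.fromkeys(CELL_SCOPES, 0.5))
    conditionals: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def validate(self) -> None:
        for scope, a in self.app_rate.items():
            if not 0.0 <= a <= 1.0:
                raise ConfigError(f"APP rate for {scope} outside [0, 1]")
        for scope, table in self.conditionals.items():
            for m, (p1, p0) in table.items():
                if m == "APP":
                    raise ConfigError("APP is the conditioning variable, not a marker entry")
                if not (0.0 <= p1 <= 1.0 and 0.0 <= p0 <= 1.0):
                    raise ConfigError(f"conditional for {m} in {scope} outside [0, 1]")

    def p_app_given_marker(self, scope: str, marker: str) -> float:
        a = self.app_rate[scope]
        p1, p0 = self.conditionals[scope][marker]
        denom = a * p1 + (1 - a) * p0
        return float("nan") if denom == 0 else a * p1 / denom

    def draw(self, scope: str, rng: np.random.Generator) -> dict[str, bool]:
        app = bool(rng.random() < self.app_rate[scope])
        out = {"APP": app}
        for m in MARKERS[1:]:
            p1, p0 = self.conditionals.get(scope, {}).get(m, (0.0, 0.0))
            out[m] = bool(rng.random() < (p1 if app else p0))
        return out


@dataclass
class CellModel:
    """Soma placement and rendering parameters.

    Somata are placed by a hard-core point process (dart throwing with a
    minimum centre separation of at least one soma diameter) within
    placement scopes derived from the label map; the derived SR/SLM border
    scope is the strip within ``border_halfwidth_um`` of the SR-SLM
    interface, and the SR/SLM interior scopes exclude a guard band so that
    planted scope membership is unambiguous under centroid jitter.
    """
    soma_radius_um: float = 5.0
    min_separation_um: float = 12.0
    cells_per_image: int = 90
    placement: dict[str, float] = field(default_factory=lambda: {
        "border": 0.60, "SO": 0.20, "SP": 0.04, "SR_int": 0.08, "SLM_int": 0.08})
    border_halfwidth_um: float = 16.0
    interior_guard_um: float = 26.0
    markers: MarkerModel = field(default_factory=MarkerModel)

    def validate(self) -> None:
        if self.min_separation_um < 2 * self.soma_radius_um:
            raise ConfigError("min separation must be >= soma diameter")
        if abs(sum(self.placement.values()) - 1.0) > 1e-9:
            raise ConfigError("placement fractions must sum to 1")
        self.markers.validate()


@dataclass
class EffectConfig:
    """Declarative description of one synthetic arm pair.

    ``baseline_plaque_density`` maps region codes to expected plaques per
    mm^2 in the control arm; ``cko_density_ratio`` holds the multiplicative
    Poisson-thinning factor applied in the cKO arm (1 = no effect).
    """
    baseline_plaque_density: dict[str, float] = field(default_factory=dict)
    cko_density_ratio: dict[str, float] = field(default_factory=dict)
    plaque: PlaqueModel = field(default_factory=PlaqueModel)
    age_scaling: dict[float, float] = field(default_factory=lambda: {3.0: 1.0})
    animal_cv: float = 0.12
    elisa: ElisaModel = field(default_factory=ElisaModel)
    cells: CellModel | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    appearance: Appearance = field(default_factory=Appearance)

    def validate(self, label_map: LaminaLabelMap | None = None) -> None:
        for reg, d in self.baseline_plaque_density.items():
            if d < 0:
                raise ConfigError(f"negative density for {reg}")
        for reg, r in self.cko_density_ratio.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"cKO ratio for {reg} outside [0, 1]")
        if self.animal_cv < 0:
            raise ConfigError("animal_cv must be >= 0")
        self.plaque.validate()
        self.noise.validate()
        self.appearance.validate()
        self.elisa.validate()
        if self.cells is not None:
            self.cells.validate()
        if label_map is not None:
            known = set(label_map.codes())
            for reg in (*self.baseline_plaque_density, *self.cko_density_ratio):
                if reg not in known:
                    raise ConfigError(f"unknown region code in config: {reg!r}")

    def ratio(self, region: str, arm: str) -> float:
        return self.cko_density_ratio.get(region, 1.0) if arm == "cko" else 1.0

    def age_mult(self, age_months: float) -> float:
        try:
            return self.age_scaling[float(age_months)]
        except KeyError:
            raise ConfigError(f"age {age_months} not in age_scaling table") from None


@dataclass
class GroundTruth:
    """Everything the generator planted, in measurement coordinates."""
    label_map: LaminaLabelMap
    regions: pd.DataFrame          # region, area_um2, plaque_area_um2, plaque_count, area_fraction_pct
    cells: pd.DataFrame | None = None
    elisa_pg_mg: float | None = None


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _animal_mult(cv: float, rng: np.random.Generator) -> float:
    if cv <= 0:
        return 1.0
    s2 = np.log1p(cv ** 2)
    return float(rng.lognormal(-s2 / 2, np.sqrt(s2)))


def _draw_disc(canvas: np.ndarray, cy: float, cx: float, r_px: float) -> None:
    h, w = canvas.shape
    y0, y1 = max(int(cy - r_px) - 1, 0), min(int(cy + r_px) + 2, h)
    x0, x1 = max(int(cx - r_px) - 1, 0), min(int(cx + r_px) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= r_px ** 2


def render_channels(truth_map: LaminaLabelMap, cfg: EffectConfig, arm: str,
                    age_months: float, seed) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one animal's multi-channel image plus its ground truth.

    Channels: VGLUT1 (neuropil bright, SP/SG dark), WFS1 (elevated over CA1
    only), ABETA (plaque discs), and one soma channel per marker when a
    cell model is configured.
    """
    if arm not in ("control", "cko"):
        raise ConfigError(f"arm must be control|cko, got {arm!r}")
    cfg.validate(truth_map)
    rng = np.random.default_rng(seed)
    ps = truth_map.pixel_size
    labels = truth_map.labels
    hippo = labels > 0
    app_ch, noise = cfg.appearance, cfg.noise

    vglut1 = np.full(labels.shape, noise.background, dtype=np.float64)
    vglut1[hippo] = app_ch.neuropil
    for code in truth_map.codes():
        if code.endswith("_SP") or code.endswith("_SG"):
            vglut1[truth_map.mask(code)] = app_ch.cell_body_band

    wfs1 = np.full(labels.shape, noise.background, dtype=np.float64)
    wfs1[hippo] = app_ch.wfs1_low
    ca1_labels = [lab for lab, (s, _) in truth_map.code_table.items() if s == "CA1"]
    if ca1_labels:
        wfs1[np.isin(labels, ca1_labels)] = app_ch.wfs1_high

    # -- plaques ---------------------------------------------------------
    mult = _animal_mult(cfg.animal_cv, rng)
    age_mult = cfg.age_mult(age_months)
    plaque_mask = np.zeros(labels.shape, dtype=bool)
    count_by_region: dict[str, int] = {}
    for code in truth_map.codes():
        dens = cfg.baseline_plaque_density.get(code, 0.0)
        region_px = np.flatnonzero((labels == truth_map.label_for(code)).ravel())
        area_mm2 = region_px.size * truth_map.pixel_area_um2 / 1e6
        rate = dens * area_mm2 * cfg.ratio(code, arm) * age_mult * mult
        n = int(rng.poisson(rate))
        count_by_region[code] = n
        if n == 0 or region_px.size == 0:
            continue
        centers = region_px[rng.integers(0, region_px.size, n)]
        cys, cxs = np.unravel_index(centers, labels.shape)
        jit = rng.uniform(-0.5, 0.5, size=(n, 2))
        radii = rng.lognormal(cfg.plaque.radius_mu_log, cfg.plaque.radius_sigma_log, n) / ps
        for cy, cx, (jy, jx), r in zip(cys, cxs, jit, radii):
            _draw_disc(plaque_mask, cy + jy, cx + jx, r)

    abeta = np.full(labels.shape, noise.background, dtype=np.float64)
    abeta[plaque_mask] = cfg.plaque.intensity

    rows = []
    for code in truth_map.codes():
        reg_mask = labels == truth_map.label_for(code)
        area = reg_mask.sum() * truth_map.pixel_area_um2
        parea = (plaque_mask & reg_mask).sum() * truth_map.pixel_area_um2
        rows.append((code, area, parea, count_by_region[code],
                     100.0 * parea / area if area else np.nan))
    regions = pd.DataFrame(rows, columns=[
        "region", "area_um2", "plaque_area_um2", "plaque_count", "area_fraction_pct"])

    channels = {"VGLUT1": vglut1, "WFS1": wfs1, "ABETA": abeta}
    cells_df = None
    if cfg.cells is not None:
        marker_channels, cells_df = sample_cells(truth_map, cfg, rng)
        channels.update(marker_channels)

    channels = {k: noise.apply(v, rng) for k, v in channels.items()}
    img = MultiChannelImage(channels, ps)
    elisa = float(sample_elisa(cfg, arm, 1, rng)[0])
    return img, GroundTruth(truth_map, regions, cells_df, elisa)


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

def scope_masks(truth_map: LaminaLabelMap, border_halfwidth_um: float,
                interior_guard_um: float | None = None,
                subfield: str = "CA1") -> dict[str, np.ndarray]:
    """Pixel pools for the CA1 cell scopes, including the derived border.

    ``border`` is the strip within ``border_halfwidth_um`` of the SR-SLM
    interface; ``SR_int`` / ``SLM_int`` are the laminae minus a guard band
    (defaults to the border halfwidth) so interior placements cannot leak
    into the border scope.
    """
    guard = border_halfwidth_um if interior_guard_um is None else interior_guard_um
    sr, slm = f"{subfield}_SR", f"{subfield}_SLM"
    d = truth_map.boundary_distance_um(sr, slm)
    srslm = truth_map.mask(sr) | truth_map.mask(slm)
    return {
        "SO": truth_map.mask(f"{subfield}_SO"),
        "SP": truth_map.mask(f"{subfield}_SP"),
        "border": srslm & (d <= border_halfwidth_um),
        "SR_int": truth_map.mask(sr) & (d >= guard),
        "SLM_int": truth_map.mask(slm) & (d >= guard),
    }


def sample_cells(truth_map: LaminaLabelMap, cfg: EffectConfig,
                 rng_or_seed) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Place somata and render one soma channel per marker.

    Returns the marker channels (pre-noise) and the planted cell table with
    true scope, true lamina at the centre pixel, and marker booleans.
    """
    cm = cfg.cells
    if cm is None:
        raise ConfigError("no cell model configured")
    cm.validate()
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) \
        else np.random.default_rng(rng_or_seed)
    ps = truth_map.pixel_size
    pools = scope_masks(truth_map, cm.border_halfwidth_um, cm.interior_guard_um)

    # largest-remainder rounding of per-scope counts
    shares = {s: cm.placement.get(s, 0.0) * cm.cells_per_image for s in CELL_SCOPES}
    counts = {s: int(np.floor(v)) for s, v in shares.items()}
    rem = cm.cells_per_image - sum(counts.values())
    for s in sorted(shares, key=lambda s: shares[s] - counts[s], reverse=True)[:rem]:
        counts[s] += 1

    min_sep_px = cm.min_separation_um / ps
    placed: list[tuple[float, float]] = []
    records = []
    cell_id = 0
    for scope in CELL_SCOPES:
        n = counts[scope]
        if n == 0:
            continue
        pool = np.flatnonzero(pools[scope].ravel())
        if pool.size == 0:
            raise ConfigError(f"scope {scope!r} has no pixels in this geometry")
        attempts, placed_here = 0, 0
        max_attempts = 400 * n
        while placed_here < n:
            if attempts >= max_attempts:
                raise ConfigError(
                    f"could not place {n} cells in scope {scope!r} with "
                    f"min separation {cm.min_separation_um} um; lower the density")
            attempts += 1
            idx = pool[rng.integers(0, pool.size)]
            cy, cx = np.unravel_index(idx, truth_map.shape)
            cy, cx = cy + rng.uniform(-0.5, 0.5), cx + rng.uniform(-0.5, 0.5)
            if any((cy - py) ** 2 + (cx - px) ** 2 < min_sep_px ** 2
                   for py, px in placed):
                continue
            placed.append((cy, cx))
            placed_here += 1
            pos = cm.markers.draw(scope, rng)
            lab = truth_map.labels[int(round(cy)), int(round(cx))]
            sub, lam = truth_map.code_table.get(lab, ("outside", "outside"))
            records.append({"cell_id": cell_id, "y": cy, "x": cx,
                            "scope_true": scope,
                            "lamina_true": f"{sub}_{lam}" if lab else "outside",
                            **{m: pos[m] for m in MARKERS}})
            cell_id += 1

    cells = pd.DataFrame(records)
    r_px = cm.soma_radius_um / ps
    channels: dict[str, np.ndarray] = {}
    for m in MARKERS:
        canvas = np.zeros(truth_map.shape, dtype=bool)
        if len(cells):
            for _, row in cells[cells[m]].iterrows():
                _draw_disc(canvas, row.y, row.x, r_px)
        ch = np.full(truth_map.shape, cfg.noise.background, dtype=np.float64)
        ch[canvas] = cfg.appearance.soma
        channels[m] = ch
    return channels, cells


# ---------------------------------------------------------------------------
# ELISA and the fast statistical twin
# ---------------------------------------------------------------------------

def sample_elisa(cfg: EffectConfig, arm: str, n_animals: int, rng_or_seed) -> np.ndarray:
    """Per-animal soluble Ab42 concentrations, lognormal with arm mean and CV."""
    if n_animals < 1:
        raise ConfigError("n_animals must be >= 1")
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) \
        else np.random.default_rng(rng_or_seed)
    e = cfg.elisa
    e.validate()
    m = e.mean(arm)
    s2 = np.log1p(e.cv ** 2)
    return rng.lognormal(np.log(m) - s2 / 2, np.sqrt(s2), n_animals)


def sample_measurement_table(truth_map: LaminaLabelMap, cfg: EffectConfig, arm: str,
                             n_animals: int, age_months: float,
                             rng_or_seed) -> pd.DataFrame:
    """Planted per-animal region area fractions without rendering pixels.

    The statistical twin of :func:`render_channels`: identical compound-
    Poisson model (Poisson counts, lognormal disc areas, lognormal animal
    multiplier) evaluated analytically.  Used for replicate-heavy
    calibration studies where rendering and re-segmenting thousands of
    images would add nothing.
    """
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) \
        else np.random.default_rng(rng_or_seed)
    cfg.validate(truth_map)
    age_mult = cfg.age_mult(age_months)
    areas = {c: truth_map.area_um2(c) for c in truth_map.codes()}
    rows = []
    for i in range(n_animals):
        mult = _animal_mult(cfg.animal_cv, rng)
        for code, area in areas.items():
            dens = cfg.baseline_plaque_density.get(code, 0.0)
            rate = dens * (area / 1e6) * cfg.ratio(code, arm) * age_mult * mult
            n = int(rng.poisson(rate))
            radii = rng.lognormal(cfg.plaque.radius_mu_log,
                                  cfg.plaque.radius_sigma_log, n)
            parea = float(np.pi * (radii ** 2).sum())
            rows.append({"animal": f"{arm}_{i:02d}", "arm": arm,
                         "age_months": age_months, "region": code,
                         "area_fraction_pct": 100.0 * parea / area})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort bundles
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """One on-disk synthetic experiment: arms x animals at one age."""
    geometry: GeometrySpec
    effect: EffectConfig
    n_per_arm: int = 8
    arms: tuple[str, ...] = ("control", "cko")
    age_months: float = 3.0
    master_seed: int = 0
    out_dir: str | Path = "cohort"
    overwrite: bool = False


def animal_seed(master_seed: int, arm: str, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), ("control", "cko").index(arm), index])


def generate_cohort(cohort: CohortSpec) -> Path:
    """Write images + ground-truth tables + manifest; returns the manifest path.

    Deterministic given the master seed: per-animal seeds are spawned from
    ``SeedSequence([master, arm, index])`` so adding animals or arms never
    reshuffles existing ones.
    """
    out = Path(cohort.out_dir)
    manifest_path = out / "manifest.txt"
    if manifest_path.exists() and not cohort.overwrite:
        raise FileExistsError(
            f"{out} already holds a cohort bundle; pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)
    truth_map = build_geometry(cohort.geometry)
    truth_map.to_tiff(out / "label_map.tif")

    lines = [
        "format=lamplaq-cohort-v1",
        f"master_seed={cohort.master_seed}",
        f"age_months={cohort.age_months}",
        f"n_per_arm={cohort.n_per_arm}",
        f"pixel_size_um={cohort.geometry.pixel_size}",
    ]
    region_frames, cell_frames, elisa_rows = [], [], []
    for arm in cohort.arms:
        for i in range(cohort.n_per_arm):
            aid = f"{arm}_{i:02d}"
            seed = animal_seed(cohort.master_seed, arm, i)
            img, gt = render_channels(truth_map, cohort.effect, arm,
                                      cohort.age_months, seed)
            fname = f"{aid}.ome.tif"
            write_image(out / fname, img)
            reg = gt.regions.copy()
            reg.insert(0, "animal", aid)
            reg.insert(1, "arm", arm)
            region_frames.append(reg)
            if gt.cells is not None:
                c = gt.cells.copy()
                c.insert(0, "animal", aid)
                cell_frames.append(c)
            elisa_rows.append({"animal": aid, "arm": arm,
                               "ab42_soluble_pg_mg": gt.elisa_pg_mg})
            lines.append(f"image.{aid}={fname};seed={seed.entropy}")

    pd.concat(region_frames).to_csv(out / "truth_regions.csv", index=False)
    if cell_frames:
        pd.concat(cell_frames).to_csv(out / "truth_cells.csv", index=False)
    pd.DataFrame(elisa_rows).to_csv(out / "truth_elisa.csv", index=False)
    digest = hashlib.sha256((out / "truth_regions.csv").read_bytes()).hexdigest()[:16]
    lines.append(f"truth_regions_sha256={digest}")
    manifest_path.write_text("\n".join(lines) + "\n")
    return manifest_path
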