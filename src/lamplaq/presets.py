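"""Packaged study configurations.

Three named setups ship with the package:

``fig3``
    The two-arm (control vs GABAergic-BACE1-cKO) plaque experiment at three
    months of age: calibrated baseline densities and per-lamina knock-out
    thinning ratios such that the planted reductions are 75 % in the SP of
    CA1 and 50 % in every DG lamina directly, while the pixel-pooled
    aggregates come out at 31 % for the whole hippocampus, 24 % for CA1 and
    50 % for DG (the aggregates are emergent, solved in closed form by
    :func:`calibrate_cko_ratios`, not planted per-lamina).

``fig1``
    The interneuron-marker colocalization setup: a CA1-focused geometry, a
    laminar placement distribution putting ~60 % of cells at the SR/SLM
    border and ~20 % in SO, and a per-scope joint marker table calibrated
    from directional overlap percentages (47 % Reelin|APP at the border,
    95 % APP|CCK pooled, 100 % GABA_BR1|APP with 97 % APP|GABA_BR1 at the
    border, ...).

``fig2``
    The 2/3/4/6-month time-course variant of ``fig3`` with a monotone age
    scaling and no knock-out effect.

Absolute densities are the package's own choice (the source experiments
report relative loads and reductions, not absolute densities); they are
set so that per-region plaque counts are large enough for stable area
fractions at n = 8 animals per arm while the whole-hippocampus burden stays
in a plausible single-digit-percent range for an aggressive knock-in model
at three months.
"""

from __future__ import annotations

from .geometry import GeometrySpec, build_geometry
from .simulate import (CellModel, ConfigError, EffectConfig, ElisaModel,
                       MarkerModel, PlaqueModel, calibrate_conditional)

#: control-arm area-fraction targets (fraction, not %) per region at 3 months
FIG3_BASELINE_FRACTIONS: dict[str, float] = {
    "CA1_SO": 0.090, "CA1_SP": 0.075, "CA1_SR": 0.060, "CA1_SLM": 0.120,
    "CA23_SO": 0.045, "CA23_SP": 0.030, "CA23_SR": 0.045, "CA23_SLM": 0.090,
    "DG_MO": 0.030, "DG_SG": 0.0225, "DG_H": 0.0375,
}

#: planted reduction targets: direct per-lamina and emergent aggregates
FIG3_TARGETS = {
    "sp_ca1": 0.75, "dg": 0.50, "ca1": 0.24, "hippo": 0.31,
}


def fig3_geometry() -> GeometrySpec:
    """1024 px field at 0.65 um/px holding all 11 regions at workable sizes."""
    return GeometrySpec(
        image_size=(1024, 1024), pixel_size=0.65, margin_um=20.0,
        ca_bands=(("SO", 80.0), ("SP", 40.0), ("SR", 120.0), ("SLM", 80.0)),
        dg_bands=(("MO", 100.0), ("SG", 40.0), ("H", 120.0)),
        ca1_fraction=0.5, curvature_um=10.0)


def calibrate_cko_ratios(fractions: dict[str, float], areas: dict[str, float],
                         targets: dict[str, float]) -> dict[str, float]:
    """Solve per-lamina cKO ratios so pooled aggregates hit their targets.

    Direct constraints: the SP of CA1 is thinned by ``targets['sp_ca1']``
    and every DG lamina by ``targets['dg']`` (which fixes the DG aggregate
    at the same value).  Free parameters: one common ratio for the non-SP
    CA1 laminae, solved so the plaque-area-weighted CA1 aggregate equals
    ``targets['ca1']``; and one common CA2/3 ratio, solved so the
    hippocampus aggregate equals ``targets['hippo']``.  Raises when a
    target combination would need a ratio outside [0, 1].
    """
    pa = {r: fractions[r] * areas[r] for r in fractions}  # expected plaque area
    ca1 = [r for r in pa if r.startswith("CA1_")]
    ca23 = [r for r in pa if r.startswith("CA23_")]
    dg = [r for r in pa if r.startswith("DG_")]
    ratios = {"CA1_SP": 1.0 - targets["sp_ca1"]}
    ratios.update({r: 1.0 - targets["dg"] for r in dg})

    ca1_total = sum(pa[r] for r in ca1)
    ca1_rest = sum(pa[r] for r in ca1 if r != "CA1_SP")
    red_rest = (targets["ca1"] * ca1_total - targets["sp_ca1"] * pa["CA1_SP"]) / ca1_rest
    hippo_total = sum(pa.values())
    ca23_total = sum(pa[r] for r in ca23)
    red_ca23 = (targets["hippo"] * hippo_total
                - targets["ca1"] * ca1_total
                - targets["dg"] * sum(pa[r] for r in dg)) / ca23_total
    for name, red in (("CA1 non-SP", red_rest), ("CA2/3", red_ca23)):
        if not 0.0 <= red <= 1.0:
            raise ConfigError(
                f"aggregate targets infeasible: required {name} reduction {red:.3f}")
    ratios.update({r: 1.0 - red_rest for r in ca1 if r != "CA1_SP"})
    ratios.update({r: 1.0 - red_ca23 for r in ca23})
    return ratios


def fig3_effect_config(geometry: GeometrySpec | None = None) -> EffectConfig:
    """Calibrated two-arm effect configuration (plaques + ELISA)."""
    geometry = geometry or fig3_geometry()
    label_map = build_geometry(geometry)
    areas = {c: label_map.area_um2(c) for c in label_map.codes()}
    plaque = PlaqueModel()
    dens = {r: f / plaque.mean_area_um2 * 1e6
            for r, f in FIG3_BASELINE_FRACTIONS.items() if r in areas}
    ratios = calibrate_cko_ratios(
        {r: f for r, f in FIG3_BASELINE_FRACTIONS.items() if r in areas},
        areas, FIG3_TARGETS)
    return EffectConfig(
        baseline_plaque_density=dens, cko_density_ratio=ratios, plaque=plaque,
        age_scaling={3.0: 1.0}, animal_cv=0.12,
        elisa=ElisaModel(control_mean=50.0, reduction=0.17, cv=0.09))


def fig2_effect_config(geometry: GeometrySpec | None = None) -> EffectConfig:
    """Time-course variant: monotone age scaling, no knock-out effect."""
    cfg = fig3_effect_config(geometry)
    cfg.cko_density_ratio = {}
    cfg.age_scaling = {2.0: 0.25, 3.0: 1.0, 4.0: 1.75, 6.0: 3.0}
    return cfg


# ---------------------------------------------------------------------------
# fig1: colocalization
# ---------------------------------------------------------------------------

def fig1_geometry() -> GeometrySpec:
    """CA1-focused field with thick laminae to hold many somata per section."""
    return GeometrySpec(
        image_size=(1024, 1024), pixel_size=0.65, margin_um=20.0,
        ca_bands=(("SO", 120.0), ("SP", 50.0), ("SR", 200.0), ("SLM", 180.0)),
        dg_bands=(), ca1_fraction=1.0, curvature_um=10.0, subfields=("CA1",))


#: directional overlap percentages driving the marker-table calibration:
#: per scope, marker -> (P(marker | APP+), P(APP | marker)); None in the
#: second slot means the reverse direction is unconstrained.
FIG1_OVERLAPS: dict[str, dict[str, tuple[float, float | None]]] = {
    "border": {
        "Reelin": (0.47, 0.35),
        "CCK": (0.32, 0.95),
        "Calbindin": (0.27, 0.61),
        "Calretinin": (0.00, None),   # no Calretinin cell is APP+
        "GABABR1": (1.00, 0.97),
    },
    "SO": {
        "PV": (0.41, 0.53),
        "SST": (0.05, 0.08),
        "CCK": (0.32, 0.95),
        "GABABR1": (1.00, 0.70),
    },
}

#: APP+ base rate among sampled interneuron-like somata, per scope.  The
#: directional conditionals pin the joint down only once a base rate is
#: chosen; 0.5 keeps every reported pair feasible.
FIG1_APP_RATE = 0.5

#: free P(marker | APP-) values where only one direction is reported
FIG1_FREE_NEGATIVE = {"Calretinin": 0.20}


def fig1_marker_model() -> MarkerModel:
    """Joint marker table calibrated from the directional overlaps.

    Markers are conditionally independent given APP status within a scope;
    :func:`lamplaq.simulate.calibrate_conditional` converts each reported
    (P(m|APP+), P(APP|m)) pair into the implied P(m|APP-), raising at load
    time when a pair is infeasible at the configured APP+ base rate.
    Scopes without their own table (SP and the SR/SLM interiors) reuse the
    border profile so the CCK overlap pooled over CA1 stays at its
    calibrated value.
    """
    conditionals: dict[str, dict[str, tuple[float, float]]] = {}
    for scope, table in FIG1_OVERLAPS.items():
        out = {}
        for marker, (p1, q) in table.items():
            if q is None:
                out[marker] = (p1, FIG1_FREE_NEGATIVE.get(marker, 0.0))
            else:
                out[marker] = (p1, calibrate_conditional(p1, q, FIG1_APP_RATE))
        conditionals[scope] = out
    for scope in ("SP", "SR_int", "SLM_int"):
        conditionals[scope] = dict(conditionals["border"])
    return MarkerModel(
        app_rate=dict.fromkeys(("SO", "SP", "border", "SR_int", "SLM_int"),
                               FIG1_APP_RATE),
        conditionals=conditionals)


#: laminar placement of sampled cells over the CA1 scopes (fractions)
FIG1_PLACEMENT = {"border": 0.60, "SO": 0.20, "SP": 0.04,
                  "SR_int": 0.08, "SLM_int": 0.08}


def fig1_cell_config() -> EffectConfig:
    """Cell-map generator: marker somata only, no plaques."""
    return EffectConfig(
        baseline_plaque_density={}, cko_density_ratio={},
        age_scaling={3.0: 1.0}, animal_cv=0.0,
        cells=CellModel(markers=fig1_marker_model(),
                        placement=dict(FIG1_PLACEMENT),
                        cells_per_image=90))


PRESET_GEOMETRIES = {"fig1": fig1_geometry, "fig3": fig3_geometry, "fig2": fig3_geometry}
PRESET_EFFECTS = {"fig1": fig1_cell_config, "fig3": fig3_effect_config,
                  "fig2": fig2_effect_config}
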