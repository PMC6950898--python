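# Methods

This note records the models, algorithms and design choices behind
`lamplaq`, in the order the pipeline runs them. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Synthetic hippocampus and plaque model

**Geometry.** The field of view is a schematic hippocampus: CA1 and CA2/3 as
two side-by-side columns of stacked laminar bands (SO | SP | SR | SLM from
the outer side inward) with the dentate gyrus (MO | SG | H) below, spanning
the interior width. A sinusoidal vertical offset shared by all band
boundaries (default amplitude 10 µm) gives the bands a gentle, parallel
curvature. The geometry is deliberately schematic rather than anatomically
warped: every downstream measurement consumes region *membership* only, so
anatomical realism would add cost without adding information. Laminae
partition their subfield exactly by construction (pixel-count identities are
asserted in tests).

Defaults: 1024×1024 px at 0.325 µm/px (a plausible 20× slide-scanner
sampling, making the 10 µm² particle cutoff ≈ 95 px); the packaged two-arm
study uses 0.65 µm/px so that all 11 regions fit one field at plaque counts
large enough for stable per-animal area fractions (band thicknesses
80/40/120/80 µm in CA, 100/40/120 µm in DG).

**Plaques.** Within each region, plaques are a Poisson process with expected
count `density · area · ratio · age_scaling · animal_mult`, where `ratio` is
1 in the control arm and the configured knock-out thinning factor in the cKO
arm, and `animal_mult` is a lognormal per-animal multiplier with unit mean
(CV 0.12 by default), shared across regions within an animal — the
biological mouse-to-mouse component. Footprints are hard discs with
lognormal radius, ln r ~ N(ln 2.5 µm, 0.35²); this puts roughly 15 % of
plaques below the 10 µm² cutoff so the size filter is genuinely exercised,
with a mean plaque area of ≈ 25 µm². Ground truth records, per region, the
pre-noise rendered foreground area intersected with the region (the same
pixel-attribution semantics the measurement uses) and the per-region count
by plaque centre.

**Channels and noise.** VGLUT1: neuropil 0.55, cell-body bands 0.18
(≈ 3:1 contrast), background 0.05. WFS1: 0.60 over CA1, 0.08 elsewhere in
the hippocampus. ABETA: plaque discs at 0.9 over 0.05. Noise is additive
Gaussian read noise (σ 0.015) plus an intensity-scaled Gaussian term
(0.04·√I) approximating shot noise, clipped to [0, 1]. Detector physics,
PSF blur and staining artefacts are deliberately not modelled: the noise
model is sufficient to stress thresholding, which is what the pipeline's
correctness depends on. Consequently, passing recovery tests demonstrates
algorithmic correctness under calibrated noise — not robustness to uneven
illumination, autofluorescence, or antibody variability in real slides.

**Calibrated two-arm effects.** The packaged study plants a 75 % density
reduction in the SP of CA1 and 50 % in every DG lamina directly. The
aggregate reductions (whole hippocampus, CA1) are *emergent* pixel-pooled
mixtures, so the remaining per-lamina ratios are solved in closed form
(`presets.calibrate_cko_ratios`): one common ratio for the non-SP CA1
laminae such that the plaque-area-weighted CA1 aggregate is 24 %, and one
common CA2/3 ratio such that the hippocampus aggregate is 31 %. Infeasible
target combinations raise at load time. Baseline area-fraction targets
(CA1 9/7.5/6/12 %, CA2/3 4.5/3/4.5/9 %, DG 3/2.25/3.75 % at three months)
encode the qualitative burden pattern — CA1 above DG, SLM the heaviest CA
lamina — at counts that give reduction SEMs of ~4–6 points at n = 8 per
arm, comparable to the reported uncertainties. Absolute densities are the
package's own choice; the source experiments report only relative loads.

**ELISA.** Per-animal soluble Aβ42 concentrations are lognormal with arm
mean and CV (control 50 pg/mg, cKO mean reduced by 17 %, CV 0.09 — chosen
so a 12-vs-12 comparison yields a reduction SEM near the reported ±3).
Plate chemistry, standard curves and extraction are out of scope; this is a
statistical stand-in for the arm comparison only.

**Cells and markers.** Somata are placed by a hard-core point process
(dart throwing, centre separation ≥ 12 µm ≥ one soma diameter; an
unsatisfiable density raises with a suggestion to lower it) within five CA1
scopes: SO, SP, the SR/SLM border strip (within 16 µm of the interface),
and the SR/SLM interiors (≥ 26 µm from it, a guard band that keeps planted
scope membership unambiguous under centroid jitter). The packaged placement
puts 60 % of cells at the border and 20 % in SO.

The marker model is the minimal joint consistent with directional overlap
percentages reported in both directions: an APP⁺ base rate per scope (0.5)
and per-marker conditionals given APP status, markers conditionally
independent given APP within a scope. A full 2⁸-combination joint per
lamina cannot be identified from pairwise conditionals; this factorisation
can, and `calibrate_conditional` solves P(marker | APP⁻) from each
(P(m|APP⁺), P(APP|m)) pair, raising at load time when a pair is infeasible
at the chosen base rate. Scopes without their own table reuse the border
profile, which keeps the pooled APP|CCK overlap at its calibrated 95 %.

**Determinism.** All randomness flows from `numpy` `SeedSequence`s spawned
as `[master_seed, arm, animal]`, so adding animals or arms never reshuffles
existing ones; identical config + seed reproduces tables byte-for-byte.

**The statistical twin.** `sample_measurement_table` evaluates the same
compound-Poisson model (Poisson counts, lognormal disc areas, lognormal
animal multiplier) analytically, without rendering pixels. Replicate-heavy
calibration studies (null uniformity, power, time-course properties) use
it; the rendered-pixel path is exercised by the end-to-end recovery and
colocalization suites.

## 2. Segmentation

* **Hippocampus**: foreground above a low threshold placed a configurable
  fraction (default ⅓) of the way from the background mode to the Otsu
  level — low enough to keep the dim cell-body bands inside the mask — then
  small-object removal, Euclidean closing (10 µm), hole filling, largest
  component. Closing uses two distance transforms rather than structuring
  elements (exact Euclidean disc, fast at large radii).
* **SP/SG bands**: Otsu (or fixed, reproducing manual thresholding) on the
  intensities inside the hippocampus; dark components closed at 4 µm and
  filtered at 5000 µm² minimum band area; the two largest survive. SP is
  the band overlapping the WFS1-positive territory (or, without WFS1, the
  configured geometric side); scores too close to call raise instead of
  guessing.
* **Lamina partition**: for each remaining pixel, with `d_sp`, `d_sg` the
  distances to the bands and `u = d_sp/(d_sp+d_sg)`: the outer side of SP is
  SO; the CA-side gap splits into SR and SLM at `u = ca_fraction ·
  sr_fraction`; `u ≥ ca_fraction` is DG territory, split into MO (SP side of
  SG) and H. Side-of-band tests compare each pixel's distance to the other
  band against that of its nearest band pixel. The two fractions are free
  parameters (the interactive protocol drew these boundaries by hand);
  defaults 0.6 and 200/300 are the values implied by the packaged band
  thicknesses (SR 120 / SLM 80 / MO 100 µm) and are exposed in config.
  Imported regions bypass all of this verbatim.
* **Subfield split**: CA pixels are indexed by an along-band coordinate
  (the principal axis of the SP band snapped to the nearest image axis — a
  gently curved band would otherwise tilt the projection and skew the cut);
  the Gaussian-smoothed WFS1 profile along it is thresholded and a single
  cut minimising misclassified profile bins defines the boundary, WFS1-high
  side = CA1. Under the auto policy the Otsu level is refined to the
  midpoint of the two class means: on near-two-level data Otsu parks next
  to the lower mode, which would bias the crossing of the smoothed profile
  by several pixels. Uniformly high/low WFS1 assigns the whole CA to one
  subfield with a warning.

## 3. Plaque mask and measurement

The channel is linearly rescaled to [0, 255] (the 8-bit export convention
of the original workflow) and histogrammed into 256 bins — by default over
the bounding box of the hippocampus mask, matching the single-hippocampus
crops the protocol exports; a full-frame option exists. The Triangle (Zack)
rule picks the threshold: peak bin, longer tail (ties → right), line from
(peak, height) to (tail end, 0), bin of maximal perpendicular distance,
distance ties toward the peak. The implementation is checked bin-for-bin
against an exhaustive distance-maximisation oracle on randomized
histograms. Foreground components are 8-connected (particle-analysis
convention); border-touching particles are retained; survival requires
`area > 10 µm²` *strictly* — a particle of exactly 10.0 µm² is excluded.
Region measurement is pure pixel counting times pixel area; a particle
overlapping two regions contributes its pixels to each separately, and
subfield/hippocampus aggregates are pixel-pooled, never averages of
fractions (the identities are asserted exactly in tests).

## 4. Colocalization

Per-channel detection: threshold (auto-Otsu per channel by default — the
original positivity threshold was manual and is reproducible via a fixed
value), 8-connected components, soma area window 40–140 µm² (the rendered
soma is ≈ 78 µm²; the ceiling rejects merged pairs, the floor rejects noise
specks), intensity-weighted centroids. Cross-channel identity: greedy
one-to-one matching by Dice ≥ 0.5 within a channel, highest Dice first — an
objective surrogate for the visual same-cell judgement, insensitive to cell
ordering. Lamina assignment is the label at the centroid pixel; the SR/SLM
border scope is a centroid within 20 µm of the SR–SLM interface (the
interface is treated as a location in the source analyses; the 20 µm width
is this package's definition, exposed as a parameter; distance 0 counts as
inside). Counts are pooled across sections before percentages are formed,
and a scope with zero A⁺ cells yields a flagged undefined percentage, never
0.

## 5. Group statistics

Percent reduction is defined on arm means (ratio of means), not the mean of
per-animal ratios — the arms are independent animals, no pairing exists.
Its SEM comes from first-order (delta-method) propagation of the two arm
SEMs through the ratio; the test suite cross-checks it against a
bootstrap within 10 % (after the standard n/(n−1) plug-in correction at
very small n). How the source reports computed their ±-values is not
stated; the delta method is this package's documented choice. ANOVA is the
classical two-way decomposition (Type II, valid unbalanced) on
untransformed area fractions, with a log-transform switch off by default;
a single-level factor degrades to a one-way ANOVA with a warning (raising
only when both factors are degenerate, so that the single-region
`F = t²` identity remains available). No multiple-testing correction is
applied across regions, matching the per-region reporting convention.

One caveat the package surfaces deliberately: the generator's per-animal
multiplier correlates the region rows of one animal, which the classical
two-way ANOVA (used for fidelity to the original analysis) does not model —
pseudo-replication that makes the arm test anticonservative under animal
variability. The null-calibration study therefore switches the animal
multiplier off (ratios = 1, animal CV = 0), testing the statistic under its
own iid assumptions; with it on, arm p-values are not uniform under the
null, and a mixed model across sections/animals is an explicit non-goal.

## 6. Numerical conventions and degenerate inputs

Histograms are 256-bin after min-max rescale; a constant channel yields a
valid empty plaque mask (and zero detections in colocalization), while a
constant VGLUT1 channel is a segmentation error ("no candidate band").
Polygon region import uses the even-odd rule on pixel centres with 0-based
row-major indexing. Zero-variance equal arms give t = 0, p = 1. Empty
laminae after partitioning are retained with a warning rather than
renumbered, so region tables keep a stable schema. Single-animal ages carry
flagged NaN SEMs.

## 7. Problem sizes

The packaged end-to-end study runs 8 + 8 animals at 1024×1024 px;
replicate-heavy calibrations use 500 replicates of the statistical twin;
colocalization recovery pools sections until ≥ 1000 APP⁺ detected cells
(~22 sections at 90 cells each). Unit tests run the same physical field at
half resolution. These sizes are chosen so the planted-vs-recovered
comparisons have the statistical resolution claimed in the tests while the
whole suite stays comfortably interactive.

## 8. Known limitations

* The geometry is topologically faithful but metrically schematic; the
  distance-band lamina rule assumes roughly parallel bands and would need
  reparametrisation for strongly folded anatomy.
* The subfield cut is a single boundary along the band; interdigitated or
  patchy WFS1 expression would be forced into one crossing.
* No PSF/blur model: plaque and soma edges are pixel-sharp, so threshold
  placement barely affects recovered areas. Real slides will show a
  threshold-dependent area bias that cancels only partially in
  between-arm ratios.
* Marker conditional independence given APP status is an identification
  choice, not biology; only the pairwise overlaps it was calibrated to are
  claimed to be reproduced.
* ELISA values are a distributional stand-in; nothing about plates,
  standards or extraction chemistry is modelled.
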