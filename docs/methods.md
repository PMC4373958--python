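# Methods

This note documents the models behind `virtualqa`, the choices made where
the design was genuinely open, and what the synthetic study can and cannot
say about physical measurements.

## Coordinate frame and phantom

All geometry lives in a right-handed mm frame with the isocenter at the
origin: x lateral, y anterior–posterior (the 0° beam travels along −y),
z cranio-caudal. The phantom is a homogeneous 26.5 × 26.5 × 27.0 cm box;
the dose grid covers it with `ceil(extent/spacing)` voxels centred on the
isocenter (voxel (i,j,k) centre at `origin + (i+½)·spacing`). The default
spacing is 1 mm; the analyses, tests and acceptance script run at 2 mm,
which keeps a full five-size replicated experiment under a minute while
every identity and ordering property tested is spacing-independent (the
clean-chain identity is asserted bit-for-bit at 2 mm and holds at any
spacing by construction).

ROIs use strict voxel-centre inclusion with inclusive boundaries
(`r ≤ R`, `|z| ≤ L/2`; annuli take `r_in < r ≤ r_in + t`). There is no
partial-volume weighting, so mask volumes converge to the analytic
cylinder/annulus values as the grid refines (within 1–3% at 1 mm). The
peripheral rim is a circular annulus at the detector cylinder (inner
radius 95 mm, thickness 10 mm, length 50 mm, ≈314 cc) — deliberately
identical for every target size so that any size trend seen in it cannot
be a volume effect.

## Beam model and planning

The dose engine is a closed-form stand-in for a commercial pencil-beam
engine; the analysis needs a smooth, realistic dose topology, not
commissioning-grade accuracy. Per beam,

```
dose(v) = fluence(u, v) · PDD(depth) · (SAD / (SAD + depth − d_max))²
```

* **fluence** — the binary BEV aperture (target silhouette under parallel
  projection, dilated isotropically by the 3 mm MLC margin, clipped with a
  warning at the 10 cm field limit) convolved with a 2D Gaussian,
  σ = 3 mm (penumbra width typical of a fine-leaf MLC at depth);
* **PDD** — 0.5 at the surface rising linearly to 1.0 at d_max = 15 mm
  (6 MV build-up), then exp(−μ·(depth − d_max)) with μ = 0.005 /mm
  (≈ 5%/cm, the right scale for 6 MV in water);
* **inverse square** with SAD = 1000 mm.

Beams are weighted equally (the study design gives no weights) and the
summed dose is scaled so that target D95 equals the prescription, using
the exact 5th percentile of the in-target voxel doses (so "95% of the
target receives ≥ prescription" holds to machine precision, and the
normalization is idempotent). The resulting plans run hot at the centre —
isocenter ≈ 112–121% of prescription across sizes — which is the expected
behaviour of conformal multi-beam overlap, more pronounced in this toy
model than in a clinical TPS.

## Detector and measurement simulation

The helical array is a single staggered helix: 66 angular columns × 21
axial rows = 1,386 diodes on a 210 mm diameter × 210 mm cylinder; column
c sits at angle c·(360/66)° ≈ c·5.45° and is staggered axially by
10·c/66 mm, giving 10 mm pitch both along the helix arc and axially.
(The physical device interleaves two helical grids; a single helix
satisfies every stated constraint — count, pitch, angle, cylinder size —
and unwraps to a cleaner lattice.) Planned readings are trilinear samples
of the per-beam planned doses at the diode positions; the composite is
always the exact per-beam sum.

Simulated measurements apply, per beam:

* **global scale** (1 + s): calibration/output error, default off;
* **field-size response**: multiplicative factor from a piecewise-linear
  curve through (5 cm, −1.1%) and (25 cm, +1.3%), evaluated at the beam
  aperture's equivalent square (2ab/(a+b) of its bounding box), linearly
  extrapolated outside; one factor per beam, entry and exit treated alike;
* **rigid shift**: readings re-sampled at `p − shift` (detector shifted by
  `+shift` relative to the plan);
* **reading noise**: multiplicative zero-mean Gaussian, i.i.d. per diode,
  beam and replicate; replicate r uses seed + r.

With everything off the simulated reading equals the planned reference
bit-for-bit, anchoring the pipeline's clean-chain identity. The
ion-chamber analog at the isocenter samples the *true delivered* dose
(planned beams under global scale and shift) with reading noise; the
field-size response is a diode artifact and does not apply to it. That
asymmetry alone reproduces the study's signature observation: with the
response curve active, the diode-predicted isocenter deviation falls from
≈1.4% (1 cm target, equivalent square 2.4 cm) to ≈0.9% (9 cm target,
equivalent square 7.0 cm), because small fields sit lowest on the
response line relative to the 10 × 10 cm² calibration field.

Default experiment conditions: field-size response on at the calibration
points above, 1% reading noise (typical diode reproducibility; replicate
scatter in the emulated study's tables is 0.1–0.9%), no shift, no global
offset, three replicates, five sizes.

## Gamma engine

γ²(p) = min over candidate reference positions r of
|r − p|²/δ² + (D_r(r) − D_e(p))²/(Δ·D_norm)², global normalization,
threshold applied to the reference dose at the evaluation point (points
below 5% of D_norm are excluded from passing rates), γ ≤ 1 passes
(boundary inclusive). Candidates live on a lattice of step δ/3 within a
ball of radius 3δ, visited shell-by-shell outward with early termination
(a point stops once the distance term alone exceeds its current best γ);
a step larger than δ is refused rather than silently degraded. Each
point's best offset is then polished by three successive-halving local
searches (3^d neighbourhood, step halved each round), which removes most
of the lattice bias; the polish can only lower γ.

The brute-force oracle is an independent flat dense scan over the whole
ball. Engine and oracle agree exactly on the shared candidate lattice;
comparing against a finer-stepped oracle bounds the engine from below
(the engine never exceeds the oracle), with residual differences up to
~0.03 attributable to the oracle's own lattice resolution near shallow
minima.

2D diode gamma evaluates on the unwrapped (arc-length, z) cylinder
surface, periodic in the angular direction. Its reference is the planned
3D dose sampled continuously on the surface (the TPS dose is known
everywhere; at diode positions it coincides with the planned reading),
and its default normalization dose is the **maximum planned composite
diode reading**. The 3D maximum (≈2.3× larger here, since the diodes sit
at radius 105 mm while the five beams overlap at the centre) is available
via `norm_dose=`; with it, a 4% reading error can never exceed 3% of the
normalization dose anywhere on the lattice and the diode analysis loses
all sensitivity — the diode-level maximum is the natural global dose of
the diode-level comparison. 3D ROI gamma evaluates at ROI voxel centres
against the planned grid, normalized to the planned 3D maximum.

"Smooth-gradient regions" (used when asserting that a 2 mm shift is
absorbed by a 3 mm DTA) are defined objectively as diodes whose
reference-surface second difference at the DTA scale is ≤ 1% of the
normalization dose; penumbra shoulders exceed this, entrance plateaus do
not. An axial shift needs no such restriction: the shifted point stays on
the detector surface, so the DTA recovers it exactly (γ = shift/δ = 2/3).

## Dose reconstruction

Per beam, relative diode errors (measured/planned − 1; diodes below 1% of
the beam's maximum reading are excluded from the ratio, logged) are split
into entry and exit hemispheres by the sign of the diode position's dot
product with the source direction, then interpolated over the unwrapped
surface (linear barycentric with periodic angular wrap, nearest-value
extrapolation outside the hull — exact at diodes, overshoot-free). Each
voxel's ray along the beam direction pierces the detector cylinder at an
entry and an exit point; the voxel's error is the linear depth blend
(1−w)·entry + w·exit of the surface errors there, and the per-beam dose
is scaled by (1 + error). Voxels whose ray misses the cylinder use the
nearest surface point's hemisphere. Voxels with negligible beam dose
(<1e−6 of the beam maximum) are untouched, making the zero-error
reconstruction exactly the planned dose.

The construction is fixed by its exactness properties — zero errors
reproduce the plan bit-for-bit, a uniform relative error s is recovered
as (1+s)·plan everywhere, a single-beam error stays inside that beam's
shadow — not by equivalence to any proprietary algorithm, which is
neither claimed nor checkable. The linear depth blend is a declared
assumption; it is exposed through the per-hemisphere error fields.

Back-projection linearly averages the diode-level scatter, so i.i.d. 1%
reading noise leaves per-ROI 3D passing rates at 100% (and the
deviation-vs-rate correlation table undefined); the noise-sensitivity
analysis shows 3D rates leaving 100% once reading noise exceeds ~2%.
Spatially correlated measurement errors — the regime where the physical
study's 3D rates drop to 75–95% — are outside the default error model.

## DVH and statistics

DVHs are exact voxel-counting cumulative histograms on uniform bins
(default 1 cGy). D_x follows "largest dose with coverage ≥ x%" with
linear inter-bin interpolation, clipped to the observed dose range so
degenerate (uniform) distributions invert exactly; D95 ≤ D50 ≤ Dmax by
construction. Dose deviation is 100·|a − planned|/planned. Statistics are
scipy-backed with explicit degenerate conventions: pooled-variance
independent t-test (Welch switchable), one-way ANOVA, Pearson r with the
t-transform p; identical constant samples give statistic 0 and p = 1
(logged), constant input to Pearson is an error surfaced as NaN cells in
the report tables.

## What the synthetic study shows — and what it does not

Passing tests demonstrate the *analysis machinery*: the gamma engine
against an exhaustive oracle, exact identities through the full
measurement→reconstruction chain, correct recovery of injected global
errors, DTA behaviour under rigid shifts, and the field-size-dependence
ordering mechanism. They do not validate a physical detector or a
clinical TPS: the beam model is a toy, diode angular/dose-rate
dependence, absolute calibration, leaf sequencing and divergent
projection are all out of scope, and the numeric passing rates of the
emulated study arise from physical error sources richer than the four
controllable ones modelled here.
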