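# Methods

## Leaf model

Net photosynthesis of a leaf irradiated on both surfaces is a
non-rectangular hyperbola in the two-sided PPFD `E = E_ad + E_ab`:

    θP·Pg² − (φP·E + Pmax)·Pg + φP·E·Pmax = 0,   Pn = Pg + Rd,

always taking the smaller root (the larger root exceeds `Pmax`). `φP` is the
apparent quantum yield (dimensionless), `Pmax` the asymptotic gross rate
(µmol m⁻² s⁻¹), `θP ∈ [0, 1]` the convexity, `Rd ≤ 0` dark respiration
(µmol m⁻² s⁻¹). `θP = 0` reduces to the rectangular hyperbola
`φP·E·Pmax/(φP·E + Pmax)`, which the implementation special-cases; `θP` is
clamped to `1 − 1e-9` so the discriminant stays positive.

`φP` and `θP` depend on the adaxial share `p_ad = 100·E_ad/E` (%): abaxial
light is absorbed more readily by spongy mesophyll and reaches chloroplasts
with lower photosynthetic capacity, so purely abaxial irradiation yields
lower `φP` and `θP` than purely adaxial. The dependence is encoded by two
standardized shape functions,

    φ'P(p_ad) = a1 + a2·p_ad + a3·p_ad²,
    θ'P(p_ad) = b1 + b2 / (1 + b3·e^{−b4(p_ad−b5)}) − b6·e^{b4(p_ad−b7)},

with defaults a = (−0.87, −0.026, 0.00028) and
b = (−226, 267, 2.4, 0.0054, −98, 0.0017, −5.7), affinely rescaled so that
the curve passes exactly through the two measured single-surface anchors
(`p_ad = 0` abaxial, `p_ad = 100` adaxial):

    c2 = (x_ad − x_ab) / (s(100) − s(0)),  c1 = x_ab − c2·s(0),
    x(p_ad) = c1 + c2·s(p_ad).

Only the *shape* of `s` matters — any affine transform of a shape function
leaves every prediction unchanged (tested exactly). A dark leaf (`E = 0`)
has `p_ad` defined as 100 by convention; `Pn = Rd` regardless. The model is
anchored at exactly 0 and 100% even though near-abaxial measurements are
taken at `p_ad = 1%`; such records simply enter the fit as interior points.

**Known limitation — mid-range dip.** With the default coefficients the
quadratic `φ'P` has an interior minimum near `p_ad ≈ 46` that lies well
below both anchor values, so the rescaled `φP` collapses toward zero for
even 50/50 bilateral splits and `Pn` at intermediate `p_ad` can fall below
both single-surface values. This is a faithful consequence of the published
coefficients; it is physiologically questionable (absorptance arguments
predict `φP` monotone in `p_ad`, and measured leaves often photosynthesize
*more* under split irradiation), and the standardized magnitudes of `θ'P`
(≈ −115…−80) are likewise inconsistent with a z-score axis. Affine
invariance makes the `θ'P` scale harmless, but the non-monotone `φ'P` shape
does propagate to predictions. We deliberately do not "correct" the
coefficients; users with their own data can refit shapes via
`fit_shape_params`.

Convexity interpolations that overshoot 1 are clamped to `1 − 1e-9`
(possible for bump-shaped custom fits); interpolated `φP` is floored at a
tiny positive value.

## Parameter estimation

* `Rd`: mean of measured `Pn` at `E = 0` per leaf class.
* Per-`p_ad` curves (`fit_lrc_group`): `φP`, `θP` per `p_ad` level plus one
  shared `Pmax` per leaf class (day-after-sowing × leaf rank), by iteratively
  reweighted least squares. Gas-exchange error spread scales with the gross
  rate, so weights are `1/max(Pg_model, 0.5)²`, refreshed from each fit and
  iterated to a fixed point (relative parameter change < 1e-6, at most 50
  passes); the weighted-objective path is recorded in the diagnostics.
  `E = 0` records never enter the weighted objective — they determine `Rd`
  separately — and the 0.5 µmol m⁻² s⁻¹ floor keeps the weights finite near
  the origin.
* Bilateral fit (`fit_bilateral`): the five parameters
  (`φP;ad`, `φP;ab`, `Pmax`, `θP;ad`, `θP;ab`) jointly, with intermediate
  `p_ad` records tied to the anchors through the shape rescale; same
  weighting. At least two distinct `p_ad` levels are required, otherwise the
  anchors are unidentifiable.
* Shape fits (`fit_shape_params`): ordinary least squares for the quadratic
  (linear in its coefficients); seeded multi-start (20 restarts)
  Levenberg–Marquardt for the seven-parameter convexity shape, which is
  multimodal and not identifiable from seven design points — the contract is
  fit quality at the design points, not coefficient recovery.
* ETR calibration (`fit_etr_calibration`): `Pg = k1·J + k2·J²` through the
  origin per irradiated surface. The quadratic nests the linear case and
  guarantees `Pg(0) = 0`; inversion uses the monotone branch
  `J = 2·Pg/(k1 + √(k1² + 4·k2·Pg))` and raises past the vertex. Leaf ranks
  measured only by fluorescence get pseudo gas-exchange records
  (adaxially-lit records at `p_ad = 100`, abaxially-lit at 0) and go through
  the same bilateral fit; their `Rd` is the mean of the measured second- and
  third-leaf values at the same day-after-sowing.

**Estimator accuracy.** At the full measurement design (10 `E` levels ×
7 `p_ad` levels × 2–5 replicates) with 5% proportional noise, the median
absolute error of `Pmax` is ≈ 3% over 50 replicates when `Rd` is known, and
recovery is exact (< 1e-4 relative) on noise-free data. `Pmax` is highly
sensitive to the `Rd` plugged in: because the `1/Pg²` weights concentrate
leverage at low `E`, an `Rd` offset of 0.06 µmol m⁻² s⁻¹ roughly triples
the median `Pmax` error. Precise dark-respiration measurement matters more
than replicate count at high light.

## Scene and light transport

Geometry (metres): 1.25 × 1.25 cultivation bed; floor at z = 0; opaque
reflective panel (top of the cultivation system) at z = 0.10 with container
side walls below; four *perfect-mirror* planes 0.0135 outside the floor
edges spanning floor to ceiling, emulating an infinite array of identical
systems; linear lamps 1.22 × 0.03 between plant rows — upward lamps resting
on the panel, downward lamps directly above at panel + 0.30; ceiling
(reflection sheet) at panel + 0.35, i.e. just above the downward lamps (its
height is not otherwise constrained; a closed box requires one, and
sensitivity is limited because the ceiling only receives already-scattered
light). Mirror walls are handled analytically, so the box cannot leak; a
photon that nonetheless escapes aborts the run as a geometry error.

Materials are three-band (400–500/500–600/600–700 nm) Lambertian
reflectance/transmittance pairs; leaves additionally transmit. Band photon
fractions default to (0.20, 0.40, 0.40), a 5000 K phosphor-converted white
LED (blue pump plus broad phosphor hump). Leaf optics are identical for the
two faces (a single measured set); adaxial/abaxial asymmetry enters only
through the photosynthesis model. Petiole interceptions are tallied in a
separate budget and do not count as leaf PPFD.

Photometry: the downward lamp follows `I(α) = I(0)/cos α` on a cone of
half-angle π/3 about the downward axis (a uniform-irradiance design), the
upward lamp is uniform over its hemisphere; α is the polar angle from the
emission axis with azimuthal uniformity, giving closed-form normalizations
`I(0) = Φ/(2π·ln 2)` and `I(π) = Φ/(2π)` (verified against quadrature to
1e-6). Emission positions are uniform over the lamp rectangle; downward
directions sample `pdf(α) ∝ tan α` by inverse CDF (`cos α = 2^{−u}`),
upward directions sample the hemisphere uniformly in solid angle.

Transport: per band, photon packets carry `Φ_band/n` µmol s⁻¹. Surfaces
sample {reflect, transmit, absorb} with the band's (R, T, 1−R−T); both
scattered directions are cosine-weighted about the leaving-side normal.
Every crossing of a blade triangle tallies *incident* weight on the struck
side — the triangle's geometric normal marks the adaxial face, which the
canopy generator orients upward at generation pose — and per-triangle PPFD
is tallied weight over one-sided area (the Monte Carlo analogue of the
centroid-point estimate; identical in expectation for flat triangles). A
uniform voxel grid with 3D-DDA traversal accelerates intersection; Russian
roulette (survival 0.8, weight-compensated) terminates paths after 20
interactions. Identical (scene, photons, seed) inputs are bit-identical;
per-triangle standard errors use the summed squared deposited weights.

`direct_illumination_oracle` integrates `I(α)·cosθ_recv/d²` over each lamp
rectangle deterministically and exists for validation only; the tracer
matches it within 2% on occluder-free configurations. Note the integrand is
discontinuous at the downward cone edge, where the patch rule converges
only linearly.

## Synthetic canopy and data

Real plant reconstructions are not available, so the canopy generator builds
parametric rosettes: 7 leaves (rank 0 = cotyledon) with golden-angle
phyllotaxis and seeded jitter, rank-dependent blade area
(weights 0.25–1.25, mid ranks largest), elevation increasing with rank
(20° + 5°/rank ± 3°), blade droop 25–40°, tapered elliptical blades
triangulated into ~14 facets each (~100 blade triangles per plant, matching
the reconstruction budget), thin two-quad petioles. The summed one-sided
blade area is rescaled exactly to the 110.2 cm² target (within the 90–110%
window used for the original meshes). Plants are placed on a near-square
grid: `n = round(LAI·floor_area/110.2 cm²)` plants, planting distance
= floor side / row count, one upward-lamp aisle between adjacent rows plus
the two flanking aisles (rows + 1 lamps), downward lamps directly above.

What the generator does *not* emulate: measured komatsuna blade outlines and
curvature, leaf clumping/overlap statistics of real stands, petiole
thickness variation, and any leaf-angle acclimation to upward light.
Canopy-level numbers are therefore geometry-sensitive summaries of a
*synthetic* stand; leaf-level and transport-level tests, which are
geometry-free or use exact oracles, are unaffected.

Gas-exchange records follow the measurement design (E ∈ {0, 30, 70, 150,
240, 330, 470, 700, 1100, 1900} µmol m⁻² s⁻¹ × p_ad ∈ {1, 17, 33, 50, 67,
83, 100}% with 2–5 replicates): `Pn_obs = Pn_true + ε`,
`sd(ε) = cv·max(Pg, 0.5)` at light (default cv = 5%, matching the
`1/Pg²`-weighting rationale) and 0.1 µmol m⁻² s⁻¹ at darkness. ETR records
are produced by pushing single-surface gross rates through the inverse
calibration and adding proportional noise. All generators are pure
functions of their seeds.

## Canopy analysis

Per condition: `CPn = Σ Pn_i·A_i`, `CPg = Σ (Pn_i − Rd_rank)·A_i` (so
`CPg − CPn = −Σ Rd·A` exactly), `Φ_leaves = Σ E_i·A_i` counting *all*
incident flux on blade triangles (first-pass and re-scattered — "incident on
the canopy" is read inclusively; consequently `Φ_leaves` may exceed the
emitted flux), area-weighted mean PPFD, and `SD_E` as the area-weighted
population standard deviation of per-triangle two-sided PPFD (unweighted SD
would depend on meshing density). Vertical profiles bin triangle centroids
into equal-height layers between canopy bottom and top. Fig-10-style
normalization divides each metric by its within-(LAI, Φ_lamps)-group
maximum, flagging all-zero groups. The Table-2-style summary reports, per
(LAI, Φ_lamps), the `p_dw` maximizing CPn (ties resolved to the larger
`p_dw`, i.e. less upward hardware) and the CPg ratio to the `p_dw = 100`
baseline, flagging a zero baseline instead of dividing. Built-in default
leaf parameters use the measured second/third-leaf maxima (50.2, 53.7
µmol m⁻² s⁻¹) inside a hump-shaped rank profile, adaxial anchors above
abaxial (φ 0.055/0.042, θ 0.75/0.55), and `Rd = −3%` of `Pmax`.

Per-condition seeds derive deterministically from the master seed via
`SeedSequence([seed, condition_index])`; failed conditions are recorded and
the grid run continues.

## Problem sizes and numerical choices

The acceptance pipeline traces 10⁶ photons per band for the reference
condition (LAI 1.0, downward-only, 122 µmol s⁻¹); the ordering checks in
the test suite use 10⁵ photons per band over a reduced condition subset
(LAI 1.5/2.5/4.5 at 122 µmol s⁻¹) with three seeds and majority voting, and
mid-LAI trends are evaluated at the representative LAI 2.5. Estimator
checks use 50 synthetic replicates. Voxel grids scale with triangle count
(up to 64 × 64 × 16); intersection epsilons are 1e-9 (ray t) and 1e-7 m
(surface offset).

## Physical consistency of the closed scene

Because the mirror box plus reflective panel/ceiling is closed and
mirrors are lossless, every photon's expected number of leaf crossings is
bounded by 1/absorptance per band, giving a hard upper bound of ≈ 87
µmol m⁻² s⁻¹ on the area-weighted mean leaf PPFD at LAI 1.0 under 122
µmol s⁻¹ of lamp flux with the default leaf optics — independent of lamp
placement or canopy geometry. The simulated value (~77) sits near that
bound once petiole/container/panel losses are accounted. For the same
reason, in the closed scene `Φ_leaves` mildly *increases* with the downward
share (upward light must traverse the petiole/container layer first), and
downward-dominant lighting maximizes CPn at every LAI; external models that
allow sideways leakage above the canopy behave differently. These
conservation consequences are deliberate properties of the closed-box
semantics adopted here.
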