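# Methods

This note documents the models behind `canolux`, the defaults and why
they were chosen, the numerical choices, what the synthetic-data
generator does and does not emulate, and known limitations.

## Solar geometry and incident PAR

Sun position uses the NOAA solar-calculator series for declination and
the equation of time, evaluated for the leap study year 2012 (the
package's day-of-year tables use 366 days). Clock hours are converted to
apparent solar time with a 4 min/degree correction for the site
longitude's offset from its time-zone meridian — at the default site
(2.391° N, 76.657° W, UTC−5) the meridian offset alone is ≈ −6.6 min —
plus the equation of time. Agreement with an independent
Astronomical-Almanac implementation is ≈ 0.01° in elevation, far inside
the 0.5° accuracy the light budget needs.

Clear-sky incident PAR on a horizontal plane is

    direct  = I0 · tau^m · sin(elevation)
    diffuse = ratio · direct

with transmittance `tau = 0.63`, `ratio = 0.44` (site constants
estimated from satellite climatology in the motivating field study) and
extraterrestrial PAR `I0 = 2400 µmol m⁻² s⁻¹` (configurable; the true
top-of-atmosphere PAR photon flux is ≈ 2770, and 2400 puts modeled
midday totals at this site in the 1700–2300 range across the year,
bracketing typical observed midday peaks of 1000–2000 under clear to
lightly hazy skies). Air mass is Kasten–Young with a barometric altitude
correction exp(−z/8434 m). The instantaneous diffuse:direct coupling is
the default; a `diffuse_mode="daily"` switch instead constrains the
daily diffuse integral to the ratio times the daily direct integral with
a sin(elevation) diurnal shape.

The diffuse sky's angular distribution is the standard overcast sky,
L(θ) ∝ (1 + 2 cos θ)/3. Per-segment weights are the closed-form integral
of L(θ) cos θ sin θ over each grid segment, normalised over the whole
hemisphere (including rings discarded from structural analyses — the
sky still shines from them).

## Hemispherical-image analysis

The fisheye projection is equidistant (zenith ∝ radial distance), the
standard for the class of lens emulated; the geometry (centre, radius,
north offset) comes from a JSON sidecar or is inferred from the raster.
Binarization is a fixed grey-level threshold, default 131 (an average of
manual passes in the motivating study), exposed as a parameter and CLI
flag.

Gap runs are measured along concentric one-pixel arcs (azimuthal
transects), split at segment boundaries, with angular step ≈ 57.3°/r per
pixel at arc radius r. The clumping index is the gap-removal estimator:
the measured accumulated gap-size distribution is compared with the
random-canopy curve

    F(λ) = (1 + Lp·λ/Wp) · exp(−Lp · (1 + λ/Wp)),

where Lp = −ln(Fmr) is re-estimated from the reduced gap fraction each
pass, and the largest gap is removed while the measured accumulated gap
fraction at its size exceeds F. Two numerical guards matter:

- only gaps wider than the element width Wp are removal candidates — a
  run narrower than one foliage element cannot be a between-crown gap,
  and the measured and theoretical accumulated curves of *any* canopy
  converge as λ → 0, so without this guard quantization ties cascade
  into spurious removals;
- the effective element width is widened to the segment's mean arc
  quantum when that quantum exceeds Wp (inner rings of small rasters
  cannot resolve a 2° element; this is a resolution limit, not a canopy
  property).

Wp defaults to 2° of arc (the field software's value is unreported;
results are insensitive within 1–4°). Fully open or fully closed
segments have no defined Ω and are excluded from CI_CV, which is
computed over the used (0–81°) segments only. Ring summaries default to
the nine 9°-bands of the used range; an `eight_bands` option merges the
two lowest bands for an 8-region display convention.

## Crown light interception

Direct transmission uses the gap fraction of the single segment
containing the sun (no sub-segment interpolation; this matches the
216-segment discretization). When the sun occupies the discarded
81–90° ring in early/late hours, that ring's computed gap fraction is
still used — excluding it would zero real morning light. PARi is
100·(PARs − PARt)/PARs; the annual figure is the PARs-weighted mean of
hourly PARi over an every-4-days grid starting January 1 (92 days in
2012), hours 0600–1800. "December average day" quantities average the
hourly values over the December days of that grid.

## Leaf position and STAR

Tilt is arccos(cos pitch · cos roll), stored on the 0–90° field
convention; the 0–180° display convention (0 = tip to zenith) is a
transform using the sign of pitch as the tip-direction bit. Course is
the azimuth of the lamina normal. STAR clamps negative incidence
cosines to zero (one-sided adaxial exposure); `one_sided=False` takes
the absolute value for the bifacial alternative. STAR ignores leaf
overlap and mutual shading: it is an upper bound on exposure to the
direct beam.

## Circular statistics

Concentration κ is the maximum-likelihood von Mises estimate, obtained
by Brent inversion of A(κ) = I₁/I₀ (exponentially scaled Bessel
functions; |A(A⁻¹(r)) − r| < 1e−6 over r ∈ [0.01, 0.99]). Because the
field literature sometimes labels a dispersion measure κ, outputs carry
both `kappa_vm` (concentration, higher = tighter) and `dispersion`
(Fisher's circular dispersion, (1 − ρ₂)/(2R̄²), higher = more spread).

The specified-mean test is bootstrap CI-inclusion: percentile intervals
of the re-centred bootstrap mean directions (arc-aware signed
differences; linear interpolation of percentiles; default B = 9999,
seeded), with an add-one-corrected p from the bootstrap distribution of
angular distances. Monte-Carlo coverage at nominal 95% is ≈ 94%
(n = 50, κ = 2).

Homogeneity across sectors follows the Rao polar-vector approach: Wald
statistics on per-sample tangents of the mean direction (after rotating
all samples by the pooled mean — the test is equivariant under common
rotation and the tangent is stable near zero) and on log circular
variance log(1 − R̄), both with delta-method variances. The p-values
use Welch's heteroscedastic-ANOVA F reference rather than the raw
chi-square: with estimated weights at field sample sizes the chi-square
reference is anticonservative (Monte-Carlo type-I ≈ 0.08 at k = 5,
n = 90, α = 0.05); the Welch reference with the log-variance transform
brings both components to ≈ 0.055, with power ≥ 0.95 against a
four-fold concentration shift in one sector.

The von Mises sampler is Best–Fisher rejection sampling (exact;
cross-checked distributionally against an independent generator);
κ = 0 degenerates to the circular uniform.

## Synthetic-data generator

The generator emulates the field design: 9 trees; per tree one crown
photograph and 5 leaf sectors × 10 leaves (450 leaves); leaf tilt von
Mises around 45° truncated to [0, 90] (κ = 3 by default, with a 5%
tip-down probability realized through the pitch sign); lamina course
von Mises around south (180°) with high dispersion (κ = 0.6). Pitch and
roll are drawn jointly so that they exactly reproduce the drawn tilt.

Canopy images are binary-valued rasters with per-ring regimes. The
random regime is per-pixel Bernoulli vegetation (clumping ≈ 1). The
clustered regime is a sequential Boolean blob process in (zenith,
azimuth·sin θ) space: randomly centred discs are added until the ring
reaches its target coverage, with an overshoot-rejection rule so the
realized gap fraction is pinned near target; the blob angular radius is
the clumping knob. A plain Poisson blob count was rejected during
design: its coverage variance routinely inverted the intended ring
profile.

Doughnut crowns use a monotone openness/clumping profile over zenith
rings, [1, 0.85, 0.65, 0.35, 0.1, 0, …] from zenith to horizon, so the
doughnut hole covers the zenith band the noon sun crosses year-round at
this near-equatorial site (December noon zenith ≈ 26°). Defaults tie
the profile amplitude to the field contrasts — tops 46.1% more open,
and clumped at a blob radius mapped from the 51.4% contrast (≈ 2°).
Between-tree variation is confined to the hole (rings 0–3): each tree
draws an openness contrast in [0.15, 1.1], a blob radius in [1°, 8°]
and a hole-deepening exponent, while the transition ring and lateral
rings are identical across trees (matching the finding that trees
differ in their tops, not their flanks).

What the generator does *not* emulate: grey-level texture and exposure
(images are binary sky/vegetation, so threshold sensitivity is not
exercised), lens distortion and vignetting, penumbra, 3-D crown depth,
leaf overlap, and any ecological coupling between a tree's crown
structure and its leaf angles (the two are drawn independently).
Passing tests therefore validate the estimators and the radiative
bookkeeping, not field photogrammetry.

Realized CI_CV across a default 9-tree study spans ≈ 0.03–0.45. The
gap-size estimator bounds Ω in roughly [0.1, 1.05], which caps the CV
of a 216-segment mixture well below 1 unless most of the sky is
clumped; a spread reaching ≈ 0.8 would require clumping the lateral
rings, contradicting the design's common flanks, so the generator does
not attempt it. Annual interception across the default study spreads by
≈ 13–17 percentage points (closed-top vs open-top trees), driving a
clearly negative CI_CV regression at n = 9.

## Statistical stage

Mixed models follow a two-phase protocol: random-effects structure
(random tree intercept vs none) assessed under REML with the saturated
fixed part; fixed-effect candidates — all subsets of {incident PAR,
hour, height} plus the null — compared under maximum-likelihood AIC
(computed as −2·llf + 2k, k counting fixed effects plus the two
variance parameters). Two models are distinguishable only when ΔAIC
exceeds the threshold (default 10); among indistinguishable candidates
the most parsimonious is selected, which is also the tie-break.
Singular or non-convergent fits are flagged, given infinite AIC when
the likelihood degenerates, and fall back to OLS when the mixed fit
fails outright; several optimizers are tried in sequence.

The annual regression (annual % on CI_CV, height as covariate when it
varies) automates the influential-point re-fit: when the largest gap in
the sorted predictor exceeds 30% of its range and sits at the top, the
maximum-CI_CV tree is refit-excluded; both fits are always reported.

## Problem sizes

Defaults were chosen so a full validation pass is interactive: 481-px
synthetic rasters (≈ 181 000 sky pixels, ≈ 200–2600 pixels per
segment), 20-seed diurnal-contrast replication, 500-replicate bootstrap
coverage at B = 999, 200-replicate homogeneity calibration, and
20–40-replicate mixed-model recovery. All are parameters; larger
rasters mainly sharpen the inner rings, where the arc quantum, not the
estimator, is the binding constraint.

## Known limitations

- The clumping estimator's behaviour on the innermost ring of small
  rasters is resolution-limited (see above); absolute Ω there is less
  comparable across image sizes than in outer rings.
- PARi at hours when the sun sits below the horizon is undefined (NaN),
  so 0600/1800 points can be missing in December at the default site.
- The ΔAIC-rule selection assumes the candidate set nests the truth;
  with strongly collinear predictors (PAR and hour share the diurnal
  cycle) the selected label can alternate between `par` and `par+hour`
  on equivalent data.
- The optimum leaf angle for midday interception at the December
  solstice is 90° minus the noon elevation (≈ 25.9° at the site) for
  noon geometry; a daily-integrated optimum differs and no attempt is
  made to reconcile the two.
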