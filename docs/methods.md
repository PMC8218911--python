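# Methods

## Segmentation and measurement

A pixel is classified as plant material by the excess-green vegetation
index: 2G − R − B > τ with G strictly greater than both R and B, on the
0–255 scale. τ defaults to 20 — low enough to keep dark and yellowish-green
leaf tissue, high enough to reject neutral agar/plastic backgrounds whose
excess green rarely exceeds ~15. An HSV hue/saturation/value window is
available as an alternative for imaging setups with strong colour casts.
No morphological cleanup is applied: the projected shoot area is defined as
a raw pixel count, and opening/closing would bias small seedlings near the
100-px survival threshold.

Well regions are axis-aligned rectangles generated from a layout config
(rows × columns, pitch, margins), 0-based and half-open so every pixel
belongs to at most one well; pixels outside all wells are discarded. The
partition makes per-well counting exactly conservative: the well sums equal
the number of green pixels inside the union of boxes, for any mask. Plates
are a fixed 6 × 8 = 48-well format, so the grid comes from configuration
rather than automatic plate detection.

## Growth traits

Per-plant area series are indexed in days, with the twice-daily cadence
encoded as d (a.m.) and d + 0.25 (p.m.).

* RGR is computed per imaging interval as the difference of log areas over
  elapsed days and aggregated as the arithmetic mean of interval values —
  the most direct reading of an "over the whole period" rate. On exponential
  growth every interval equals the generative rate, so the mean recovers it
  exactly; intervals touching a non-positive area are dropped and logged.
* The growth-curve slope is the OLS slope of area against time over all
  timepoints. Zero areas are valid linear observations and are retained.
* CV uses the sample SD (n − 1) over the final-day areas, in percent.
* Survival is the percentage of plants with ≥ 100 green pixels on the final
  day (inclusive threshold).
* Dead plants (final area below the threshold) count in survival but are
  excluded from the other four traits by default: their residual green
  pixels measure decay, not growth, and their zero areas would break the
  log transform. The policy is configurable (`include_dead`).

## The PBC index

Each trait contributes s · log2(primed/unprimed), s = −1 for CV (lower CV
is better), +1 otherwise; the index is the sum. Survival is a stress-only
trait: under the unstressed condition the index sums the remaining four
contributions. A survival of exactly 0 % is floored at 100/(n + 1) % before
the ratio — a penalty that grows with the evidence (n) while keeping the
index finite; every flooring is logged.

Some published tabulations report the CV cell as the *raw* log2 of the CV
ratio rather than the sign-flipped value. The `cv_raw_log2` switch
reproduces that tabulation; the default applies the declared negative-trait
semantics. The two differ only in the sign of the CV term.

Classification reads the sign pattern of the index across conditions.
`epsilon` widens the zero band: the default 0 is the strict sign used in
published index tables, appropriate when each cell aggregates a large
screen. For single synthetic replicates we use ε = 3 × the null-index
standard deviation. The null sd, measured by running the generator with no
priming effect (40 independent two-group draws at n = 96), is ≈ 0.27 log2
units — see the sampling-noise analysis below — giving ε = 0.75, i.e. the
index must exceed three quarters of a doubling-equivalent before a label is
assigned.

### Sampling noise of the index — an irreducible floor

The CV contribution is a log ratio of two independent sample standard
deviations. For n plants per group, Var(ln s) ≈ 1/(2(n − 1)) regardless of
the noise scale, so at n = 96 the CV term alone has sd
√2 · 0.0725 / ln 2 ≈ 0.15 — *independent of how homogeneous the plants
are*. The group mean additionally enters the area, slope and (sign-flipped)
CV contributions coherently, raising the total null sd to ≈ 0.25–0.27 under
realistic between-plant variation. Consequently a single 96-vs-96
comparison cannot distinguish |index| below ~0.15 from zero, whatever the
generator settings; detecting small effects requires either replication
across rounds or dropping the CV trait. This floor is why the noise
tolerance above is expressed in multiples of the measured null sd.

## Chlorophyll fluorescence

Standard PAM definitions are used (Fv/Fm, ΦPSII, NPQ, Fv′/Fm′ as in the
README). When Fo′ is not measured it is estimated by the Oxborough–Baker
relation Fo′ = Fo / (Fv/Fm + Fo/Fm′) and the row is flagged. Fp is read
through but enters no derived parameter. Inputs are numeric transient
tables; fluorescence image processing is out of scope (plant masks for
fluorescence imaging are typically drawn manually at this seedling size).

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

* **Design.** Two 48-well plates per variant → 96 biological replicates;
  imaging twice daily (d, d + 0.25) over 7 days → 15 timepoints; conditions
  0, 75 and 150 mM NaCl; doses 0.001/0.01/0.1 µl ml⁻¹.
* **Growth.** A(t) = A0 · exp(r_eff · t) with A0 lognormal (median 100 px,
  ln-sd 0.35) and r_eff = r_base × condition multiplier × priming effect +
  N(0, 0.03). r_base = 0.25 day⁻¹ gives a ~5.8-fold area increase over 7
  unstressed days; the salt multipliers (0.70 at 75 mM, 0.45 at 150 mM)
  reproduce the qualitative stress-response ordering, and the noise levels
  yield final-day CVs of ~40–50 %, the range real plate screens show.
  Exponential growth is the generative model precisely because RGR is the
  log-slope: recovery is exact in the noiseless limit.
* **Death.** A daily Bernoulli process under stress only (probability
  0 at 0 and 75 mM, 0.007 day⁻¹ at 150 mM for unprimed variants →
  ≈ 95 % survival over 7 days). Dead rosettes shrink by 50 %/day and switch
  to a brown palette that fails the green criterion, so their measured area
  is 0 — survival measured from images equals the generative truth.
* **Rendering.** Each rosette is a quasi-circular lobed blob: well pixels
  are ranked by a radial score perturbed with a sinusoidal lobe term and
  exactly the ground-truth pixel count is coloured from the live palette
  (G ∈ [130, 210], R, B ∈ [20, 90], always green-positive). Counts are
  exact unless a rosette outgrows its well box (clipped and logged).
* **Determinism.** One seeded `numpy.random.Generator` drives simulation
  and rendering; fixtures (PNGs, manifest, ground truth) are byte-identical
  across runs with the same seed.

What the generator does **not** emulate: leaf-level morphology, overlap
between neighbouring rosettes, colour calibration drift, specular
highlights, condensation on plate lids, or measurement noise correlated in
time. Passing tests therefore validate the computational chain — counting,
trait algebra, index, classification — not the robustness of the colour
criterion to real imaging artefacts.

## Statistics layer

ANOVA (scipy F test) with Tukey HSD (statsmodels) at α = 0.05 and Pearson
correlation matrices with 0.05/0.01/0.001 stars are a thin reporting layer;
they gate nothing in the index. Tukey groupings are summarized by a small
insert–absorb compact-letter-display routine (groups that are not
significantly different share a letter).

The round-reproducibility headline is 100 × |A₁ − A₂| / max(A₁, A₂) on the
control-group final-area means, reported exactly and rounded to the nearest
integer percent (the denominator convention is immaterial at the percent
level for close means).

## Problem sizes

Tests and the default scenarios use 96 plants per variant, 15 timepoints,
and 560 × 420 px plate renderings (70 px well pitch). The well pitch only
sets the headroom for rosette radii; all trait computations are
resolution-independent, and layouts for full-size camera frames (e.g.
2500 × 2000 px) are configured the same way.

## Known limitations

* The grid is configured, not detected: plate misalignment is out of scope.
* The RGR aggregation (mean of interval RGRs) and the slope estimator (OLS
  over all timepoints) are choices among defensible alternatives; an
  endpoint-difference slope is available via the per-plant functions.
* Classification at single-replicate scale depends on the ε noise
  tolerance; the default strict sign is meant for large aggregated screens.
* The index sampling floor above means small |index| values from one
  96-vs-96 comparison are not interpretable as effects.
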