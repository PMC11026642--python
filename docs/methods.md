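# Methods

## Force-curve model and fitting

**Forward model.** A synthetic indentation assumes a rigid sphere of radius
*R* pressed into an elastic half-space: F = (4/3)·E/(1−ν²)·√R·δ^(3/2). On a
soft cantilever the piezo travel splits between indentation and lever
bending, δ = (z − z₀) − F/k, so the generated force at each piezo position
solves an implicit equation; it is found by Brent root-finding on δ ∈
[0, z − z₀] (tolerance ~1e-16 m, i.e. ≪ 1e-15 N in force). This matters at
the conditions emulated here: a ≲1 kPa sample probed with a 0.03 N/m lever
bends the cantilever by tens of nanometres at micron indentation, ~4 % of δ.

**Defaults (generator).** k = 0.03 N/m and R = 2.5 µm (the probe used for
the lung scaffolds), ν = 0.5 (incompressible, the convention for soft
hydrated ECM), a 3.1 µm ramp with the contact point at 2 µm so maximum
indentation is ≈1 µm (the trigger depth is not a reported quantity; ~1 µm is
typical for 20 µm sections with a 5 µm bead), 400 samples per segment, 5 pN
additive Gaussian deflection-force noise, a Gaussian pull-off well on the
withdrawal segment (depth = the target adhesion force; width 150 nm,
centred two widths outside contact so the sampled minimum equals the depth
exactly when noiseless), and a multiplicative withdrawal force reduction
(hysteresis factor, default 0.1) producing a tunable approach–retract loop.
Batches jitter z₀ per curve (σ = 50 nm) and draw per-curve seeds from
(seed, region, point, replicate), so they are bit-reproducible.

**Contact point.** Candidates are approach sample positions; for each, a
straight baseline is fitted to the pre-contact prefix (leaving a 5-sample
gap), the Hertz slope is refitted, and the whole-curve squared residual is
scored; the best grid candidate is refined by bounded golden-section search
between its neighbours. A curve is flagged "no contact" unless its best
candidate beats a contact-free linear fit of the entire segment by at least
5 % of SSE — a Hertz branch fitted to pure noise only ever gains a fraction
of a percent by overfitting, while genuine contact improves the residual by
orders of magnitude, so the margin separates the two regimes cleanly.

**Modulus.** E comes from the closed-form regression of F on δ^(3/2)
through the origin, restricted to δ between 10 % and 90 % of the maximum
indentation: the lower cut avoids contact-point noise, the upper cut avoids
deep-indentation substrate effects on thin sections. r² is reported over
the same window; curves with r² < 0.8 (configurable) are flagged, and the
curve — not the indentation — is the unit of QC exclusion.

**Viscosity index.** The dimensionless hysteresis ratio
(∫F_app dδ − ∫F_ret dδ)/∫F_app dδ over the common contact interval, with
negative forces clipped to zero; trapezoidal integration. It is a proxy for
viscous dissipation, not a viscosity in physical units. A known numerical
bias: reducing the withdrawal force also reduces lever bending, so the
withdrawal trace reaches slightly larger δ than the approach; truncating it
to the common interval inflates the recovered ratio by ≈ +0.02 absolute at
generator factor 0.3 under the default conditions. Tests therefore accept
the ratio to ±0.02.

**Adhesion.** |min| of the baseline-corrected withdrawal force, reported in
nN; zero when the withdrawal is purely repulsive. Noise induces a small
positive bias (the minimum of noise around the well bottom), ≈0.3 % at the
study's 5 pN noise.

**Aggregation.** Replicates → point → region → sample by successive
unweighted means; group mean ± SE with the sample (animal) as the unit of
replication and SE undefined for single-sample groups. Flagged curves are
excluded and counted in a QC report.

## ECM intensity quantification

All pixel intensities of a channel feed a Gaussian KDE (Silverman
bandwidth, samples capped at 10⁵ pixels with a seeded subsample) evaluated
on a 256-point grid spanning the bit-depth range and renormalized to
integrate to one over that grid (raw KDE mass can leak past the intensity
bounds for near-edge values; renormalization restores a proper density on
the intensity domain). Within user-supplied (lower, upper) thresholds the
density's area below vs above its peak gives the weak/intense split, each
normalized by the total thresholded area. The per-image scalar compared
between groups is the activated-pixel fraction — pixels inside
[lower, upper] over all pixels — defined by direct counting, never by the
KDE; the weak/intense areas are also emitted and the comparison metric is a
config switch. Because Silverman's bandwidth depends on sample size, the
profile is exactly invariant under image tiling only in its counting
metrics; the KDE areas vary at the second decimal.

Group comparisons report 100·(mean_aged − mean_young)/mean_young with a
two-sided Student t-test (Welch behind a flag).

**Synthetic images.** The generator ranks a random texture field (smoothed
random line segments for "fiber", smoothed noise for "blob") and sets
exactly round(f·N) top pixels to the signal level, so the pre-noise
activated fraction is exact; default levels 30/200 on 8 bits with σ = 3
noise, default thresholds the level midpoint and the bit maximum. Image
*sets* apply a per-image multiplicative fraction factor 1 + N(0, 0.02):
a ~2 % within-group coefficient of variation matches the tight within-group
scatter implied by p < 0.001 group differences at n = 3 images and keeps
group t-tests non-degenerate. What the generator does not emulate: uneven
illumination, stain bleed-through, out-of-focus background, and spatial
autocorrelation of staining intensity — so passing tests demonstrate the
correctness of the quantification arithmetic, not robustness to real
acquisition artifacts.

## Cell quantification

Nuclei: binarize at a user threshold (inclusive), 8-connected component
labeling, drop regions with equivalent circular diameter below the minimum
(default 6 px). Touching nuclei merge (no watershed); synthetic fields
enforce a minimum centre separation so counts are exact by construction.
Ki67: the thresholded Ki67 mask is dilated by a disk (default radius 2 px,
compensating small registration offsets between stains) and a nucleus is
positive iff ≥1 dilated Ki67 pixel overlaps its footprint — equivalent, by
symmetry of the disk, to dilating each nucleus footprint, and a single Ki67
pixel may mark several nuclei. Per-nucleus overlap pixel counts are
exported for stricter downstream rules. Viability: objects counted per
live/dead channel; viability = 100·live/(live+dead), undefined at zero
cells. All thresholds are in native intensity units; images are never
rescaled on read.

## Statistics

Student two-sample t (pooled variance; Welch by flag), α = 0.05;
zero-variance degeneracies resolve to t = 0, p = 1 for equal means and a
flagged p = 0 otherwise. The factorial model is response ~ age * volume
with Type II sums of squares — the conventional choice for the unbalanced
4-vs-8 animal design when main effects are the question; for balanced data
it reduces to the classical orthogonal partition and conserves total SS.
Empty design cells and rank deficiency are hard errors. Group summaries are
mean ± SE (SD with n−1 denominator over √n). No multiple-testing
correction by default; Holm adjustment available.

## Problem sizes

The bundled synthetic study runs at reduced scale chosen as the package's
default demonstration size: 3 samples per group × 8 curves (2 regions × 2
points × 2 replicates), 3 images per protein and group, 2 cell fields per
group. The recovery benchmarks in `scripts/acceptance.py` use the full
stated conditions: 200 curves per group (5 regions × 5 points × 8
replicates) at 5 pN noise, 10 images per group, and 20 live/dead fields of
100 cells.

## Known limitations

No bottom-effect (finite-thickness) correction and no adhesive-contact
(JKR/DMT) models; the hysteresis ratio is a stand-in for a full
viscoelastic analysis; no watershed separation of touching nuclei; no
vendor AFM file formats (conversion is upstream); pixel sizes are optional
metadata and all image filters are specified in pixels.
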