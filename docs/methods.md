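# Methods

## Statistical model of the synthetic populations

Each cell *i* carries, per reporter gene *g*, a true log₁₀ expression

    x_ig = μ_{c(i,g)}(t) + σ_{c(i,g)}(t)·ε_ig + β_g·m_i

where *c(i,g)* ∈ {off, on} is the mixture component (on with probability
`on_fraction(t)`), ε is standard normal, and m_i ~ N(0, σ_m) is a shared
per-cell metabolic-state factor with gene-specific loading β_g. The shared
factor is what produces positive cross-gene correlation; for two unimodal
genes it is exactly

    r = β₁β₂σ_m² / √((β₁²σ_m² + σ₁²)(β₂²σ_m² + σ₂²)),

which the tests use as a closed-form oracle. Wildtype (reporter-free) cells
draw the reporter channels from the autofluorescence distribution
N(autofluo_mu, autofluo_sd) instead; the natural-pyoverdine channel, when
enabled, is drawn for every strain, since wildtype cells make pyoverdine
too.

Mixture parameters follow a piecewise-linear schedule over the sampling
times (anchors at chosen hours, linear interpolation between them). This
generalizes a two-anchor early/late interpolation and lets the default
pyochelin (*pchEF*) schedule express the full three-phase narrative: bimodal
with a 16 % on-fraction up to 6 h (phase I), all-on by 9 h (phase II), then
a moderate decline of the on-state mean through 24 h (phase III). The
default pyoverdine (*pvdA*) schedule is a gradual unimodal induction with
shrinking SD. Neither the real component means nor SDs are published for
this system; the defaults are scenario parameters expressing the
qualitative pattern, in log₁₀ IntDen-equivalent units.

Per-condition additive shifts of the gene means emulate media differing in
iron limitation (iron-replete represses both genes); a per-(repeat, channel)
N(0, 0.15) offset emulates the between-repeat batch effect that the fusion
step removes.

## Optics and rendering

Cells are spherocylinders (rods) with uniform interior intensity placed by
rejection sampling with a minimum gap (exceeding the density cap raises an
error, keeping segmentation well-posed). In channel *ch* a cell's total
flux is `photon_scale · 10^x` grey·px, spread uniformly over its mask; the
canvas is blurred with an isotropic Gaussian PSF, and an additive radial
vignette field, a constant pad background and Gaussian camera noise are
added. Vignetting is additive, not a multiplicative gain, because the
correction chain removes it by subtraction of the outside-ROI mean;
flat-field calibration is out of scope. Phase contrast renders dark rods on
a bright background.

Defaults: 512 × 512 px fields, pad background 100 ± 2 grey, read noise
SD 2, vignette amplitude 8 grey with profile 1 − 0.8ρ², photon_scale 100,
PSF σ 0.6 px, rods 14–22 × 5–7 px. Two calibration considerations fix
these numbers. First, the scalar outside-ROI correction removes only the
*mean* of the vignette, so its spatial residual is a noise floor of a few
grey per pixel; the default expression scenarios keep the dimmest reporter
cells (≈ 3σ below the off-component mean) above that floor, because below
it per-cell log values are dominated by background residuals — on real
data, that regime is equally unquantifiable and is what the wildtype
zeroing marks as "background level". Second, the segmented mask captures
only the flux the PSF leaves inside the cell outline, so the capture
fraction (and its variation across cell geometries) sets the accuracy
ceiling of IntDen recovery; σ = 0.6 px keeps that variation ≲ 0.01 in
log₁₀ while still exercising the blur path.

Reporter-strain cells emit reporter flux only (no additive cellular
autofluorescence on top); wildtype cells emit the autofluorescence draw.
This makes the correction chain exactly invertible at zero noise:
`log_final = x − median(wildtype autofluorescence)`, the property the
recovery tests assert. Real reporter cells add autofluorescence on top of
reporter signal, so on real data the wildtype-median subtraction is exact
only where reporter flux dominates — passing recovery tests demonstrate the
chain's correctness, not that real off-state cells are measured without
bias.

Plate-reader curves are lagged-logistic OD600 (inoculum OD 10⁻⁴ as in the
sampling design being emulated) with RFU = OD × E[10^x] × scale, where
E[10^x] is the closed-form lognormal-mixture mean — bulk fluorescence is
mean per-cell expression times density.

## Measurement chain

Segmentation replaces a trained pixel classifier with deterministic global
Otsu thresholding on the phase image, a 1-px morphological opening,
8-connected labelling, removal of border-touching objects, and an area
cut-off (default 30 px²; the original workflow's cut-off value is
unreported, so it is a config parameter). Externally produced label maps
can be substituted at the measurement stage. Coordinates are pixel-centred
(row, col), 0-based. IntDen is mean grey × area, the ImageJ convention.

The correction order is fixed: pad blank → vignette offset → log →
wildtype median. Subtracting the scalar pad blank commutes with the
outside-ROI offset only because the blank is spatially uniform (tested both
ways). Nonpositive corrected IntDen values are floored at ε = 1 grey·px
before the log and flagged; the log base is 10. Wildtype medians pool
repeats within each (condition, time point) by default (the pooling rule is
configurable, as the original description leaves it open); a stratum
without wildtype cells is a hard error naming the stratum, and fewer than
20 wildtype cells warns.

## Fusion

Δx = x̄ − x_r per (condition, time, strain) and value column, with x̄ the
unweighted mean of repeat means (cell-weighted optional). The shift is
*added*, so post-fusion each repeat's stratum mean equals the global mean
exactly; read literally, "subtract Δx" would move repeat means away from
the global mean, defeating the fusion purpose, so that reading is exposed
only behind a `strict_literal` audit flag. Strata present in a single
repeat pass through unshifted with a warning.

## Statistics

- Heterogeneity: sample SD (n−1) of log values. On-fraction: share with
  log(fluo) ≥ 1 (threshold configurable).
- Bimodality: 1- vs 2-component Gaussian mixture; bimodal iff
  ΔBIC(2 vs 1) > 10 AND |μ₂−μ₁| > 2·√(mean within-component variance) AND
  minor weight > 0.05, on ≥ 100 cells. The thresholds are defaults chosen
  to hold the false-positive rate on unimodal nulls at ≤ 5 % while
  retaining ≥ 95 % power at 3-SD separation (both properties are tested by
  simulation); the underlying decision was originally made by eye from
  density plots, so the formal test is this package's own formalization.
- Trend regressions start at the 9th hour (the time from which all cells
  express siderophore genes in the emulated design) and can run on single
  cells or on per-stratum summaries — the caller chooses.
- Linear models use Type-II sums of squares (robust to mild imbalance);
  rank-deficient designs raise an error naming the aliased terms. No
  multiple-testing correction is applied by default, matching the
  single-test reporting style of the analyses being reproduced.
- Growth parameters: μmax is the maximum slope of ln(OD) over a 5-point
  sliding OLS window; lag is where the tangent at μmax meets the inoculum
  baseline. The windowing is a documented default, not a claim about how
  any particular plate-reader analysis was windowed. Per-capita expression
  masks time points with OD ≤ 0.01 to avoid near-zero-division inflation.

## Problem sizes and determinism

The default validation experiment is 3 media × 8 time points × 2 strains
(double reporter + wildtype) × 2 repeats with one 200-cell field and four
blank fields per pad (≈ 19 000 quantified cells); simulation-based checks
use 100–200 seeded replicates and n = 5 000–10 000 cells where binomial or
Monte-Carlo error bounds are asserted. All randomness derives from a single
seed through a named `SeedSequence` tree keyed by (condition, time, strain,
repeat, field), so identical configs are bit-identical and any field can be
re-derived in isolation.

## Known limitations

- The generator is phenomenological: it produces the statistical
  signatures (funnel, bimodality, shared-factor correlation), not the
  Fur/PvdS/PchR regulatory dynamics that cause them. No time-lapse
  lineage structure, no cell-to-cell spatial covariance, no photobleaching,
  no multiplicative shading.
- Segmentation is thresholding-based; on real phase-contrast data with
  touching cells a trained classifier will outperform it — the pipeline
  accepts such label maps directly.
- Correlations between a reporter and the pyoverdine autofluorescence
  channel are computed on values that are background- but not
  autofluorescence-corrected, mirroring the channel's special treatment.
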