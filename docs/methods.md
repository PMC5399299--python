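# Methods

This note records the models, defaults and numerical choices behind each
analysis stage, what the synthetic data emulate (and what they do not),
and the design decisions taken where the underlying procedure was
genuinely open.

## Synthetic data model

The generator exists so that every downstream measurement has a
parameter-recovery test against known truth. It deliberately emulates
the *statistical structure* the analyses assume, not the optics of a
microscope: there is no PSF convolution, shot-noise statistics or camera
gain model, so passing tests demonstrate correctness of the
measurement chain, not robustness to every imaging artifact.

**Oscillatory traces.** One cycle is a raised cosine,
`osc(φ) = ½(1−cos 2πφ)`, φ ∈ [0,1) — smooth, well-defined peaks at cycle
midpoints even under cycle-length jitter, which a plain sine would not
give once cycles are concatenated. Cycle lengths are gamma-distributed
with mean `true_period` and coefficient of variation `period_jitter_cv`
(the jitter knob needed to emulate the "stochastic period" phenotype;
CV 0 gives perfect periodicity). The trace is
`(baseline + amplitude·osc + ε)·e^{−t/τ}` clipped at 0, with
ε ~ N(0, noise_sd²). The noise sits **inside** the bleaching envelope:
it models signal-borne fluctuations, which decay with the fluorophore
pool as photon noise does. This choice keeps bleach correction
well-posed — dividing out the decay restores homoscedastic noise; had
noise been added after the decay, any multiplicative correction would
amplify the tail noise by e^{t/τ} and no threshold-based period detector
could meet its operating targets. Every realization records its cycle
boundaries, peak times, and the noise-free and bleach-free signals.

Reference conditions used throughout tests: 25–30 min traces at
Δt = 30 s (60 samples), period 180 s (≈10 cycles), noise 30% of the
oscillation amplitude, bleaching τ = 600–900 s, 12-bit intensity range
(0–4,095 AU).

**FRET pairs.** Cells are polygons rasterized to a label image; channel
I carries a per-cell base intensity (uniform 18–28% of the 12-bit
ceiling); channel II equals channel I times a per-region true ratio
(junction band / medial interior, optionally split into DV/AP-oriented
band sub-regions), is translated by a known sub-10 px shift (bilinear),
and both channels then receive a background level plus clipped Gaussian
noise. In noiseless, unshifted pairs the channel totals obey exact
conservation, which is asserted in tests.

**Clusters, nuclei, ellipses.** Puncta are hard-edged disks/ellipses
painted with an inclusive boundary (`d ≤ r`), so pixel areas track the
analytic area to a few percent at the radii used; specs may not overlap
or touch. Nuclei are isotropic Gaussian blobs (σ default 3 px) drifting
rigidly at a known speed; tissue masks are filled ellipses with AP along
the image x axis.

## Trace analysis

**Photobleach correction** fits `a·e^{−t/τ}` to the trace by least
squares, divides the decay out, refits the residual decay of the
corrected trace and composes the two (up to 5 iterations): a single fit
is slightly biased by the oscillation riding on the decay, while the
composition converges on the true τ (noiseless recovery error ≈1% RMS
at τ = 600 s over a 30 min trace; exact idempotency; a first-pass τ
above 10× the trace duration means "no detectable decay" and the trace
is returned unchanged). Traces that are non-positive over more than half
their samples are rejected as too weak to correct. The division leaves
the initial intensity unchanged, which is the rescaling convention used
everywhere.

**Peak intervals.** Peaks are local maxima with prominence at least
`min_prominence_fraction` (default 0.1) of the trace range; endpoints
are never peaks. The period distribution is the set of adjacent-peak
intervals; fewer than two peaks yields `NOT_PROMINENT`.

**Autocorrelation period.** ρ(k) is the Pearson correlation of the
trace with its k-sample offset copy, so ρ(0)=1 exactly and a noiseless
periodic trace scores 1.0 at its period (an n-normalized estimator would
cap the score at 1−k/n ≈ 0.9 and misrepresent clean signals). Peak
*finding* runs on a lightly smoothed correlogram (Gaussian, σ = 0.75
lag) — smoothing stabilizes the bump position on noisy, jittered traces
without touching the reported score, which is always the raw ρ at the
chosen lag. The period is the lag of the first local maximum after the
first zero crossing, ties toward smaller lags (never a harmonic). The
estimate is `NOT_PROMINENT` when the score falls below
`max(min_detectability, z/√(n−k))` with `min_detectability = 0.2` and
z = 2.5. The second term is a Bartlett-style white-noise bound: the sd
of ρ(k) under pure noise is ≈1/√(n−k), and because the detector scans
several lags before settling, z is set above the pointwise 1.96 so that
the false-detection rate on pure noise stays near 1% at n = 60 (Monte
Carlo: 99% rejection; plain 0.2 alone rejects only ~92%). Constant
traces are `NOT_PROMINENT` with score 0. `NOT_PROMINENT` is an explicit
sentinel, never NaN.

Cycle means partition the trace into one-period windows starting at the
first detected peak (or t = 0 if no peak exists, e.g. constant traces
with an externally supplied period); only complete windows count.
Population summaries report mean ± sd over detectable cells, with the
`NOT_PROMINENT` count kept separate rather than polluting the mean.

Measured operating characteristics at the reference conditions (100–400
trace Monte Carlo): mean recovered period 180 ± a few s with <1% of
cells losing detectability; on 5×-reduced amplitude with jitter CV 0.3
the per-cell autocorrelation periods disperse ≈25 s while raw peak
intervals disperse ≈55 s — the quantitative form of "autocorrelation is
more robust on irregular, small-amplitude signals". Note the comparison
is per-cell periods vs the interval distribution: per-trace *mean*
intervals can look deceptively tight while being systematically wrong
(noise peaks pull them to ≈145 s in that regime).

## FRET analysis

Processing order: subtract a sample-free background ROI (clip at 0) →
register channel II onto channel I by translation (upsampled phase
correlation, sub-pixel; structureless images are rejected) → Gaussian
smoothing (tests use σ = 0.75 px; larger σ mixes ratios across the
junction/medial boundary — at σ = 1 px the boundary mixing alone biases
region ratios by ≈5% for 7.5 px bands) → acceptor threshold (Otsu by
default) → per-pixel ratio on valid pixels only. Validity additionally
requires the donor to exceed ε = 1% of its 99th percentile; invalid
pixels carry NaN, never a number. The ratio convention is channel II
over channel I (higher ratio = higher Rho1 activity); swapping the
convention inverts every reported ratio and is config-switchable, since
the original numerator convention is not recoverable.

**Cell partition.** The junctional band is every cell pixel within
`band_width` of the boundary (Euclidean distance transform); the default
1.5 μm is a declared proxy for the MyoII-distribution-derived split used
originally, which cannot be reconstructed; it is config-exposed. Band
orientation: boundary pixels get a local tangent by PCA over boundary
neighbours within 3.5 px; a tangent within 45° of the DV axis
(perpendicular to the required `ap_axis_deg` input) is DV-oriented. Band
pixels take the label of the nearest *confidently* oriented boundary
pixel; pixels equidistant from a DV and an AP edge (corners) fall back
to a centroid-direction rule with exact diagonals alternating by row
parity — this makes the DV/AP split exactly balanced on symmetric cells,
which matters because the polarity ratio is a *total*-intensity ratio
and therefore sensitive to class pixel counts. The DV/AP junctional
ratio defaults to totals (the planar-polarity definition); a mean-based
variant is provided.

## Cluster quantification

Pixels inside the intensity window are binarized and grouped
8-connected (config-switchable to 4; connectivity was not specified
originally and 8 is the common puncta convention). A component is kept
iff its area strictly exceeds `min_area` (0.2 μm², following the
printed ">"), its circularity 4πA/P² lies within the preset window, and
its mean intensity lies within the same window (the intensity criterion
is applied both pixelwise and per-component, since the original wording
is ambiguous; the pixelwise window is primary). The perimeter is the
4-direction Crofton estimator (less biased than naive boundary counts
near circularity thresholds); a naive estimator is available for
sensitivity analysis. Single-pixel regions are defined to have
circularity 1; discretization can push tiny regions slightly above 1, so
values are clamped at the window's upper bound *for filtering only* and
reported raw. The presets are `hela` (2,500–4,095 AU, >0.2 μm²,
0.5–1.0) and `follicle` (1,200–4,095 AU, >0.2 μm², 0.35–1.0), on 12-bit
data; other bit depths are rescaled with a warning.

Correctness is pinned by an independent brute-force oracle (exhaustive
flood fill plus a Crofton perimeter computed by direct line-intercept
counting) that must agree **exactly** — component for component, area
for area, verdict for verdict — on randomized images.

Cluster time courses first rescale every frame to the initial image
intensity over a configurable foreground mask (the whole-image
bleaching compensation applied to optogenetic series), then report
per-frame clustered area and mean cluster intensity relative to frame 0
(or to the first frame with clusters, flagged via the
`reference_frame` column). This compensation assumes the frame mean is
dominated by a stable (diffuse) pool; scenes whose clusters dominate
total intensity violate that assumption by construction.

## Morphometry

Elongation uses caliper extents: pixel coordinates are projected on the
AP direction and its perpendicular, and each extent includes the 1 px
pixel footprint so axis-aligned rectangles measure exactly; a
moment-based fitted-ellipse variant is provided. Nuclear detection is
smoothing (σ = half the expected radius) → Otsu → components with a
minimum area of a quarter of the expected nuclear disk → intensity-
weighted centroids. Linking is greedy mutual-nearest-neighbour per frame
transition with a hard `max_displacement` gate, no gap closing or
merging — follicle rotation is slow and coherent, so heavier linkers add
nothing. Chamber speed is the mean over tracks of the per-track mean
frame-to-frame *path* displacement per minute (path length, not net
displacement). Linescans resample the polyline at 1 px arclength steps
and average `width_px` bilinear samples along the local normal; width 1
along a grid row reproduces the row exactly. Region statistics report
the junctional percentage of total cell signal (junction + medial = 100%
exactly, by construction) and the junction/medial mean-intensity ratio.

## Reproducibility plumbing

All generator randomness flows through `numpy.random.default_rng(seed)`
with seeds recorded in the ground-truth containers; identical seeds give
bit-identical outputs. `RunConfig` hashes its canonical JSON form and
every written result table embeds that hash and the package version in
its header. The run timestamp exists only on the in-memory result table:
written bytes depend on nothing but config and seed, so reruns are
byte-identical (and tested to be).

## Problem sizes

Tests and the acceptance script run desk-scale versions of each study:
populations of 100–200 traces of 60 samples, 9-cell epithelia of 8 μm
cells at 0.2 μm/px (≈145² px scenes), 50 randomized 48² px cluster
images, 20-frame 200² px rotation movies with 12 nuclei, and ellipse
masks up to ≈700×300 px. These sizes give stable Monte-Carlo estimates
for every recovery check while keeping the full suite in the
tens-of-seconds range.

## Known limitations

- The synthetic scenes are geometrically idealized (square cell grids,
  rigid drift, hard-edged puncta); recovery there does not demonstrate
  robustness to segmentation error, cell deformation or drift, all of
  which are out of scope (masks are assumed stationary over the 25–30
  min window).
- The junction/medial split is a fixed-width geometric proxy, not the
  reporter-distribution-derived split of the original procedure.
- Period estimation is time-domain only (by design; no Fourier/wavelet
  path) and quantized to the frame interval.
- The photobleach model is mono-exponential; fluorophores with
  multi-component decay will be corrected only approximately.
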