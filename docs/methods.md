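# Methods

This note documents the models, estimators and numerical conventions
behind `iknm`, the design choices made where several reasonable options
existed, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate and time conventions

All positions are distances from the apical surface in micrometres
(apical = 0, basal positive); all times are minutes, anchored so that
the final metaphase frame of each track is t = 0 and earlier frames are
negative. Apically directed motion therefore *decreases* position, and
velocities are reported with the apical-positive sign convention
(v(tᵢ) = −(p(tᵢ₊₁) − p(tᵢ))/δt), so "upward" movement is positive.
Units are fixed; nothing infers or converts them.

Motion is analyzed in one dimension. The tracked quantity is the scalar
apico-basal coordinate, so the "2D" in the power-law intercept ln 2D is
the conventional prefactor of the 1-D MSD of free diffusion
(MSD = 2DΔt), not a statement about dimensionality.

Tracks must be uniformly sampled: the overlapping-pair MSD assumes a
constant frame interval δt. Gapped tracks are truncated to their final
contiguous, metaphase-anchored run (lenient mode) or rejected (strict
mode); they are never interpolated, which would manufacture correlated
displacements.

## MSD estimation and power-law fitting

For a segment of N points, the estimator at lag Δt = nδt averages all
N − n overlapping pairs:

MSD(Δt) = (1/(N−n)) Σᵢ (p((n+i)δt) − p(iδt))².

The maximum lag is bounded by the segment length (N − 1 frames); for
fitting, lags up to N/2 are recommended, since the pair count — and
hence the estimator's stability — collapses at longer lags.

The anomalous exponent a and diffusion constant D come from ordinary
least squares on ln MSD vs ln Δt (slope a, D = exp(intercept)/2).
Zero-MSD lags cannot be log-transformed; they are excluded and counted,
and a fully immobile segment is reported as a named error rather than a
fit. Exponents are banded into motion classes: constrained
(a < 1 − b), diffusive (|a − 1| ≤ b), ballistic (a ≥ 2 − b₂), directed
otherwise, with default half-widths b = 0.1 and b₂ = 0.15. The bands
are conventions for labeling, not inferential tests, and are exposed as
parameters.

Two fitting routes are provided. Per-track fits preserve
track-to-track variability but are biased slightly low: regressing the
*logarithm* of a noisy per-track MSD incurs a Jensen bias that grows
with lag (measured: mean per-track exponent 0.93 for 200 Brownian
tracks of 100 frames fitted over lags 1–25, vs 0.99 for the pooled
fit). The pooled fit — per-lag MSD values averaged across tracks with
pair-count weights before fitting — concentrates the MSD first and is
effectively unbiased; it is the default for cohort-level exponents.
Both are reported because cohort figures in the field are sometimes one
and sometimes the other.

## Phase segmentation

The transition from non-directed to directed apical motion is, in
experimental practice, a manual call (persistent apical movement plus
cortical myosin enrichment). The package preserves that route
(`mode="supplied"`) and adds an automatic one.

The automatic changepoint assumes the two-phase generative model: zero
net drift before onset, constant apical drift after. The scan
minimizes the two-segment residual sum of squares *on the
frame-to-frame displacements* (early mean fixed at 0, late mean
fitted), over all admissible split indices, breaking ties toward the
latest index. This is the exact least-squares changepoint for the
model above. Fitting the equivalent piecewise curve to raw positions
instead is misspecified when the early phase is a random walk — the
late-phase line absorbs early wander and drags the onset earlier; on
the synthetic regime below this biased onsets by ~3 frames and
velocities by ~14%, versus no measurable bias for the displacement-space
scan.

A split is only accepted when (i) the fitted late drift points
apically and (ii) the best split reduces the zero-drift null's residual
by at least a relative margin (default 0.1). For i.i.d. zero-mean
displacements the best of ~N spurious splits reduces the residual by
roughly log N / N — under 10% for usable track lengths — while a real
directed phase of even a few frames reduces it several-fold more.
Tracks failing the margin return a "no directed phase" outcome rather
than a guess; on 200 simulated pure-Brownian tracks of 61 frames the
false-positive rate was 7%. When a myosin series is present, candidate
onsets can be restricted to frames after the reporter first crosses a
threshold, mirroring the experimental dual criterion.

Mitotic nuclear velocity is the net displacement from the onset frame
to the metaphase frame divided by the elapsed time — a secant velocity,
deliberately insensitive to within-phase fluctuations. Fold-change
normalization divides by the control cohort's mean (so the control's
own normalized mean is 1).

## Tissue morphology

Zone partitioning reads the nuclear layer's start and end off a
DAPI-style line profile as the first and last sample whose lightly
smoothed intensity (moving average, default window 3 samples) exceeds a
fraction (default 0.2) of the smoothed maximum. The apical
proliferative zone is everything apical of the layer, the nucleus-free
zone everything basal, and the three heights sum to the profile extent
by construction. The rule is a reproducible surrogate for what is, in
practice, a manual boundary call; the threshold and window are exposed.
Boundary accuracy is limited by sample spacing (the detected boundary is
the first supra-threshold *sample*) and by the smoothing window; both
effects stay within two sample spacings on the synthetic fixtures.

Peak counting uses prominence-based local-maximum detection (default
prominence 0.25 of the dynamic range, minimum separation 2 µm —
sub-nuclear, since nuclei are ≳3 µm). Counting runs on the raw profile
by default with an optional smoothed mode, since either could plausibly
match an upstream manual count. Nuclear density is
n / (apical area × NL height), in nuclei/µm³, reported per sampled
segment and collated rather than averaged away.

## Position statistics

The deep-nucleus ("translocating") fraction uses a strict inequality at
the cutoff (default 5 µm): boundary nuclei count as apical.
Normalized positions divide each distance by its own disc's
nuclear-region height; values above 1 are flagged but kept, since a
nucleus below the nominal nuclear region is data, not an error.
Distribution comparisons pool all age-matched discs of a condition
first, then apply the two-sample Kolmogorov–Smirnov test
(`scipy.stats.ks_2samp`); the asymptotic p-value is the default with
the exact small-sample option exposed, as either convention is common.

Clone neighborhoods classify a tracked cell by genotype and the
fraction of its apical perimeter adjoining RNAi-expressing cells:
wt:wt at fraction 0, wt:rnai at 0.5–1, rnai:wt when wild-type
neighbors occupy 0.5–1 (RNAi fraction 0–0.5), rnai:rnai at fraction 1.
A boundary of exactly 50% is assigned to the adjoining band — a
convention, flagged as such — and anything outside the bands is
counted as unclassified rather than forced into a cohort.

## Synthetic generators

`simulate_tracks` draws the two-phase model directly: before the
changepoint, Euler–Maruyama diffusion (pure Brownian at
confinement_k = 0; Ornstein–Uhlenbeck with a restoring force toward the
starting position otherwise — the simplest process whose MSD slope
falls below 1 over intermediate lags, with plateau 2·d_early/k and
stability requiring k·δt < 1); after it, drift −v_late plus diffusion
d_late. The apical surface reflects (nuclei abut but do not cross it),
measurement noise is added last and clipped at zero. The changepoint
is snapped to the frame grid and recorded per track as ground truth.
Each track uses an independent RNG sub-stream keyed by (seed, track
index), so track i is identical regardless of cohort size.
`alpha_early` is recorded as the intended early-phase exponent label;
the realized exponent is emergent from the dynamics, not imposed.

The frame interval defaults to 1.5 min — a realistic choice for
minute-scale confocal time lapses of nuclear migration — but is a
required, explicit parameter everywhere rather than a baked-in
constant. Cohort-scale defaults (tens of tracks, tens of frames,
drift ~0.6 µm/min over ~15 min, diffusion ~0.05–0.1 µm²/min, starting
depth ~20 µm) are sized to the tissue: nuclei a few microns wide moving
tens of microns over tens of minutes.

`simulate_profile` sums unit-height Gaussian nuclear peaks placed
evenly through the configured nuclear layer (regular stacking mimics
columnar packing; randomness enters through intensity noise only). The
outermost centers are inset by σ√(2 ln 5) ≈ 1.794σ so the summed
intensity decays to ~20% of a peak height exactly at the configured
layer boundary — i.e., the generator *defines* the layer edge as the
20%-envelope crossing, consistent with the partition threshold default.
Zone heights sum to the epithelial height exactly by construction.

`simulate_positions` draws per-disc distances from exponential,
half-normal, or a two-component mixture family (apical half-normal
spike plus a shifted-exponential deep tail), covering apically
concentrated, dispersed, and bimodal regimes of mitotic positioning.

## What the synthetic tests do and do not show

The generators share the analyses' own model family (piecewise
diffusion/drift, Gaussian peaks, named distance distributions). Passing
tests therefore demonstrate estimator correctness and calibration —
recovery of known exponents, changepoints, velocities, zone heights,
counts and tail probabilities under realistic noise — not robustness to
everything real tissue produces: tracking errors and identity swaps,
non-stationary early phases, z-drift, uneven illumination across the
profile, partially overlapping nuclei, or disc-to-disc height variation
within a condition. The synthetic regime used for parameter-recovery
checks (d_early = 0.1 µm²/min, v_late = 0.6 µm/min, onset −15 min,
d_late = 0.05 µm²/min, no measurement noise, 61 frames at δt = 1 min,
100 tracks) fixes the quantities the generators' defaults imply; test
ensembles of 100–200 tracks keep the full suite in seconds on one core.

## Known limitations

* The automatic changepoint assumes a single transition to a constant
  drift; pauses, multi-step onsets, or drift ramps will be summarized
  by one effective onset.
* Per-track exponent summaries are biased slightly low at long lag
  windows (Jensen bias, quantified above); prefer the pooled fit, or a
  short lag window, for cohort exponents.
* Zone boundaries are threshold crossings of a 1-D profile; strongly
  non-uniform staining along the axis will shift them.
* KS p-values assume independent pooled observations; nuclei within a
  disc are treated as exchangeable after pooling, as is standard for
  this readout.
* Position distances are assumed pre-measured; no image processing of
  any kind is performed here.
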