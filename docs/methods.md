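# Methods

`fawave` quantifies the mechanochemical behaviour of single focal adhesions
(FAs) in migrating cells imaged on micropillar arrays with a ratiometric FAK
biosensor. This note documents the models, the estimators, the synthetic-data
generators used to validate every stage, and the numerical choices that were
genuinely open.

## Traction forces from pillar deflections

Each elastomer post is treated as an independent cantilever. A tip deflection
`δ` (µm) maps to a force

    F = 3 E I δ / L³,      I = π r⁴ / 4,

with `E` the Young's modulus (Pa), `r` the post radius and `L` the post
height (µm). Units are handled strictly: the exported force is in nN
(`r = 1 µm, L = 8 µm, E = 2 MPa` gives a tip stiffness of 9.20 nN/µm).
Pillar geometry is user-supplied configuration; the named presets
(`soft_5kPa`, `stiff_14kPa`) carry nominal placeholder dimensions because
only effective substrate stiffnesses are experimentally established, and no
stiffness→geometry conversion is attempted.

Pillar tops are detected per frame by Gaussian smoothing at half the pillar
radius, Otsu thresholding, and intensity-weighted centroids per connected
component (duplicates closer than half the pitch are merged). The undeformed
reference lattice is fitted to *anchor* pillars — pillars far from any
segmented FA, presumed unloaded — rather than to a separate unloaded
acquisition: an initial basis comes from clustering nearest-neighbour
difference vectors on the doubled angle (lattice directions are defined
modulo π), followed by alternating integer-index assignment and linear least
squares for origin and basis. The fit requires at least 6 anchors and a mean
anchor residual below pitch/4, and is translation/rotation-equivariant by
construction. Deflections are observed centroids minus assigned reference
nodes; FA→pillar assignment takes the nearest node within pitch/2, with
exact ties broken toward the lower node index.

Coordinates are 0-based pixel indices, pixel centres at integer multiples of
the pixel size, x rightward and y downward.

## FRET biosensor quantification

The biosensor reports FAK activity as the donor/corrected-FRET ratio
(high ratio = low FRET = open, active conformation). The per-frame chain:

1. **Costes background** on the (donor, FRET) pair: orthogonal (total
   least squares) regression of FRET on donor, thresholds walked down the
   regression line from the maximum until the Pearson correlation of pixels
   below both thresholds is ≤ 0 (an undefined correlation — a constant
   sub-threshold population — counts as decorrelated). The walk step is one
   quantization unit for integer images and 1/512 of the range for float
   images. Degenerate noise-free images can stay perfectly correlated all
   the way down; the walk then falls back to the smallest non-empty
   below-threshold set so that a background estimate always exists.
2. **Background subtraction**: the per-channel mean over the background
   mask is subtracted (clamped at zero) before any ratioing.
3. **Bleed-through correction**: `cFRET = I_FRET − α·I_ECFP − β·I_YPet`
   with donor and acceptor constants α = 0.175 and β = 0.056 (calibrated
   from single-labelled controls), clamped below at 0 because negative
   corrected intensities are unphysical and would break the ratio.
4. **Ratio map**: donor/cFRET where cFRET exceeds a scale-free floor
   (1% of the frame's 99th-percentile cFRET) and the pixel is foreground.
5. **Per-FA statistic**: the median ratio over the FA mask's valid pixels
   (the mean is exposed as an option); an FA with no valid pixel yields a
   missing value, not an error.

Photobleaching is corrected by the simple-ratio method — each frame scaled
so the mean of a reference region is constant over time — with the Costes
(cell-free) background as the default reference, so biology-driven intensity
trends cannot contaminate the correction.

## FA segmentation and tracking

Segmentation on the YPet channel: negated Laplacian-of-Gaussian band-pass,
3D median filter (3×3×3; per-frame 2D with a warning when the stack is
shorter than the window), triangle threshold, opening + closing with a
radius-1 disk (the smallest structuring element that removes single-pixel
artifacts without merging neighbours), watershed on the distance transform
with regional-maxima markers (minimum height 10% of the distance range) to
split touching FAs, and a physical area gate of 0.2–20 µm². The LoG scale
defaults to σ = 1 px — the PSF scale: FAs are plaque-like (flat-topped)
rather than Gaussian, and a wider band-pass measurably erodes their masks
(on synthetic plaques, per-FA IoU drops from ≥ 0.9 at σ = 1 px to ~0.65 at
σ = 2 px).

Tracking solves the frame-to-frame linear assignment problem with squared
centroid distance, gated at 2 µm (non-link cost = gate²). Merges are
allowed: when a track ends within the gate of a segment already claimed by
another track, the larger-area parent continues through the merged segment
(ties to the lower track id) and the other parent terminates. A newborn
segment appearing within the gate of a parent that also continued flags
that parent as split; split tracks are excluded, as are tracks that move
excessively (net displacement > 2 µm with path length > 5× net — a declared,
configurable heuristic). Only tracks spanning ≥ 7 consecutive frames are
retained; gap closing is off because retention is defined on consecutive
frames. Assembly state uses the normalized size index (area × mean
brightness): baseline = mean of the first 3 frames; a later value > 130% of
baseline ⇒ assembling, < 70% ⇒ disassembling (first crossing wins), else
stable. The classification is invariant to global intensity rescaling.

## Dynamics: z-scores, rates, periods, lead-lags

Observations are standardized by temporal z-scoring pooled per cell (all
FA-time samples of one cell and metric share one mean/SD; per-FA
standardization is exposed as an option). Rates are central differences
(one-sided at the ends) scaled to per-minute units. FAs are classified by
ordinary-least-squares slopes of the raw force trace over a rolling 5-min
window: *increasing* when ≥ 50% of windows have slope ≥ 0.01 nN/min
(symmetrically *decreasing*; the ≥ 50% aggregation is a declared choice that
makes the label robust to single-window noise).

**Period.** The oscillation period is the lag of the first positive-lag
local maximum of the force-rate autocorrelation that exceeds the white-noise
band, refined by parabolic interpolation. The band is `z/√N` with `z`
Bonferroni-corrected over the searched lags: the per-lag 1.96/√N bound
false-alarms on a large fraction of pure-noise series when ~60 lags are
scanned, while the corrected band keeps the family-wise false-peak rate at
5% (measured ~1% on white noise).

**Lead-lag.** The cross-correlogram is computed per integer lag as the
Pearson correlation of the overlapping segments (both re-centred on the
overlap, so an exact integer shift reaches r = 1 exactly), searched over
±150 s (lags of interest are tens of seconds; a bounded search avoids
spurious far peaks). The peak is refined by parabolic interpolation through
its two neighbours, giving sub-frame lags; a peak already at r = 1 is not
moved (the vertex would overshoot the bound). Positive lag means the first
series leads. Gaps of one frame inside a track are linearly interpolated;
longer gaps drop the FA from lag analysis.

**Ensemble summaries.** Per-FA peak lags are aggregated as mean, median, SD
and IQR. The headline coupling strength is the peak of the *FA-averaged*
cross-correlogram: every FA shares the population lead-lag, so averaging
curves before peak extraction suppresses the max-over-lags selection bias
that inflates per-FA peak heights by ~+0.05 on 20-min traces (the per-FA
mean and median peak heights are reported alongside for comparison).
Whether lag structure exists at all is decided by a circular-shift surrogate
test: each FA's second series is rolled by a random large offset (destroying
cross-coupling, preserving autocorrelation), the ensemble peak recomputed 99
times, and the permutation p-value compared against 0.01 — conservative, so
a coupling claim must clear essentially the whole null distribution.

## Spatial organization

For a 10-min window of persistent migration, each frame's FA observations
are translated so the cell centroid sits at the origin, and all frames are
rotated by one common angle aligning the window-mean migration direction
with +x (a per-frame rotation would destroy FA-scale structure; persistent
migration implies a single direction). A window with net displacement below
1 µm has no defined direction and is an error. Aligned observations are
binned on a 2 µm grid (≈ pillar pitch) and averaged over time and FAs; maps
are compared by Pearson correlation over jointly defined bins in a region —
by default the leading-edge half-plane x > 0. The reported map correlations
are qualitative regime anchors (co-located force/FAK patterns vs an
independent area pattern), not exact reproduction targets, because the
original binning and region conventions are not recoverable.

## Migration metrics

Speed is total path length over duration (µm/min) and straightness is net
displacement over path length; both are computed after a 3-frame moving
average of the centroid trace (configurable off) because centroid jitter
inflates path length at long frame intervals. The average touches interior
points only, so straight paths keep their exact length. Both definitional
choices (path-length speed rather than mean instantaneous speed; net/total
straightness) are declared, with the alternatives exported.

The persistent-random-walk generator uses constant step length
`speed × Δt` and a wrapped-Gaussian heading walk; trajectories default to
20 h at 10-min sampling (the long-movie frame interval is a declared
default, not an inferred value). The heading SD that yields a target
straightness is found by bisection on direct simulation *through the same
measurement chain* (smoothing included), so calibration and measurement are
consistent by construction.

## Synthetic data: what it emulates and what it does not

**Trace generator.** Per FA, rate series follow a latent-factor model: a
shared unit-variance latent oscillation `S` (sinusoid of period 300 s
carrying 70% of the variance, plus a smooth broadband component —
Gaussian-smoothed white noise, σ = 15 s; a pure sinusoid would make the
autocorrelation analysis degenerate), with the FAK rate driven by
`S(t − τ₁)` and the area rate by `S(t − τ₁ − τ₂)` (defaults τ₁ = 32 s,
τ₂ = 21 s), plus independent smooth noises scaled by variance ratios
(v_F, v_K, v_A). Under this model the aligned Pearson correlation of two
channels is `1/√((1+v_X)(1+v_Y))`, so `calibrate_noise` inverts a target
correlation triple in closed form — the default triple (0.67, 0.61, 0.49)
yields (0.199, 1.241, 0.858); infeasible triples (any implied v < 0) are
rejected. The independent noises deliberately share the latent's smooth
spectrum: the pipeline integrates rates to levels and re-differentiates,
and white frame-level noise would be differentially attenuated by that
round trip, breaking the calibrated correlations. The latent is sampled on
a 1-s grid so the configured lags land exactly; levels are cumulative
trapezoid integrals plus strictly positive baselines (2 nN, ratio 1.4,
2 µm²; rate SD scales 0.5 nN/min, 0.05/min, 0.3 µm²/min). The frame
interval defaults to 10 s, which makes the embedded lags sub-frame and
exercises the interpolation path. Perturbation presets switch the latent
coupling per channel: `rock_inhibited` zeroes all couplings and holds force
at a low baseline with ~0.01 nN/min noise (every FA classifies steady);
`fak_inhibited` decouples only the FAK channel and drops its baseline to
0.8. Note the embedded force→area lag is necessarily τ₁ + τ₂ = 53 s under
this chain; the generator cannot simultaneously embed a shorter direct
force→area delay.

The generator emulates the statistical structure of per-FA series — shared
oscillation, lead-lag chain, calibrated coupling strengths — but not FA
birth/death, amplitude heterogeneity between FAs, nonstationary drift, or
measurement gaps. Passing recovery tests therefore demonstrates estimator
correctness under the assumed model, not robustness to every property of
real recordings.

**Stack generator.** Four channels are rendered for FAs sitting on pillars
inside an elliptical cell: pillar tops as Gaussian spots displaced by the
beam-equation deflection of their ground-truth force (deflection and force
are exactly related in the ground truth); FAs as PSF-smoothed disks whose
ECFP amplitude and true ratio fix the corrected-FRET amplitude, with the
FRET channel synthesized as `cFRET_true + α·I_ECFP + β·I_YPet` so the
pipeline's inversion is testable as an exact round trip (this deliberately
avoids any photophysical model). Uniform strictly positive backgrounds,
exponential bleaching, then Poisson-Gaussian camera noise (default SNR:
gain 1, read σ 2 on ~600-count signals). No cell-shape dynamics beyond a
translating ellipse are simulated.

## Problem sizes and runtimes

Validation uses 100-FA ensembles of 20-min traces at 10-s frames (40-min
for period recovery), 256×256 single-frame stacks with 10 FAs on a 4-µm
lattice at 0.2 µm/px, and 200-trajectory migration ensembles — sizes at
which every recovery statistic is stable across seeds while the full test
suite and the acceptance script each finish in well under a minute of
compute per stage.

## Known limitations

- The cantilever model ignores substrate warping and pillar-pillar
  crosstalk (pillars are mechanically independent by construction).
- The reference lattice assumes enough unloaded out-of-cell pillars are in
  view (≥ 6 anchors).
- The Costes fallback for perfectly correlated noise-free images is a
  degenerate-input convention; real noisy data terminate the walk normally.
- Ensemble lag summaries assume a common population lag; strongly bimodal
  lag structure would be averaged away.
- No statistical comparison across drug conditions is performed beyond
  exporting tables; no FLIM lifetime fitting; no sub-resolution nascent
  adhesion detection.
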