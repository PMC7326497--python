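# Methods

## The measurement

A GUV kinase assay images immobilized vesicles in two confocal
channels: a membrane dye marking each vesicle's equatorial
cross-section as a ring of roughly constant brightness, and a labelled
PX domain that binds PI(3)P and accumulates on the ring as the kinase
works.  The quantity of interest is the per-vesicle *initial rate* —
the slope, in arbitrary fluorescence units per minute, of the linear
segment of the reporter progress curve — and derived comparisons:
fold-changes between enzyme/lipid conditions, and the dependence of
activity on membrane curvature 1/R.  Absolute AU scales are instrument-
dependent; all scientific conclusions the pipeline supports are ratios,
slopes' signs, and significance calls.

Conventions: pixel coordinates are 0-based (row, col); lengths are in
micrometres; times in minutes since enzyme addition; image stacks are
(T, C, Y, X).

## Forward model (synthetic data)

The generator emulates the assay so that every downstream stage can be
tested against exact ground truth.

*Geometry.*  Vesicles are circles of radius R ∈ [1, 30] µm rendered as
annuli of thickness 0.5 µm (membrane cross-section); the default field
is 256×256 px at 0.25 µm/px.  Placement is rejection sampling with a
minimum edge separation (0.5 µm by default).  Vesicles are static, as
for avidin–biotin-immobilized GUVs.

*Kinetics.*  On-membrane reporter signal is piecewise
lag → linear → plateau:

    S(t; R) = clip(r_eff · (t − lag), 0, plateau),
    r_eff   = v + b / R,

with lag 10 min, plateau 120 AU and curvature coupling b (AU·µm/min,
0 except in the curvature fixture).  The piecewise-linear shape is
chosen deliberately: the rate-extraction step assumes a literal linear
region, so the generator must contain one.  The plateau default is set
above any fixture's 60-minute excursion so that the linear region is
never truncated within the default acquisition.

*Haze.*  Unbound reporter and small particles produce a spatially
uniform background B(t) = B_max·(1 − exp(−t/τ)), B_max = 20 AU,
τ = 4 min.  Because τ < lag, the haze rises before the enzymatic
signal — reproducing the hallmark negative baseline-corrected values
during the lag phase.

*Optics and detection.*  Channels are blurred with a Gaussian PSF
(σ = 0.2 µm) and detected as scaled Poisson photon noise plus Gaussian
read noise: I = Pois(g·I₀)/g + N(0, σ_r), g = 20 AU⁻¹, σ_r = 1 AU,
clipped at zero.  At the default membrane brightness (100 AU) this is
a per-pixel SNR of ~40 — a well-exposed confocal acquisition.  The
noisy pixel is unbiased for the noiseless pixel.  A "low-noise"
profile (σ_r halved, 30 vesicles) exists for conditions whose expected
fold-change is close to 1.

*Frames* are acquired every 2.5 min for 60 min (25 frames).

*Fixtures.*  A registry anchors ground-truth rate *ratios* to the
fold-changes the assay is used to detect (7×, 7×, 11×, 1.8×, 1.7×,
1.2×, and sign-only curvature/charge patterns); base rates are
arbitrary (documented in `guvkin.simulate.FIXTURES`).  Fixture scenes
use radii 2.5–5.5 µm so that ≥ 15 vesicles fit the default field.

What the generator does *not* model: photobleaching, vesicle drift or
fusion, depth-dependent aberrations, reporter-binding saturation, and
3-D geometry (analysis is of 2-D equatorial sections; Z-stacks are
handled by maximum projection before segmentation).  Passing tests
therefore demonstrate correctness of the measurement pipeline under
these idealizations, not robustness to every artefact of real data.

## Segmentation

Per frame and channel: difference-of-Gaussians band-pass (σ_small =
half the membrane thickness in pixels, σ_large = 3 σ_small; mirror
boundaries), then a threshold.  The default threshold is Otsu on the
response, floored at 3 robust standard deviations (1.4826·MAD) of the
response: without the floor, a frame with no ring structure (e.g. the
reporter channel during the lag phase) has a pure-noise response whose
histogram Otsu happily splits in half, flooding the mask.  A fixed
numeric threshold can be configured instead.

The two channel masks are unioned, smoothed by a binary *closing*
(disc radius 1 px), despeckled (components < 5 px dropped), and
hole-filled.  Closing rather than opening is deliberate: at default
geometry the thresholded rings are only ~2 px wide and an opening
severs them, so their interiors never fill; a closing repairs small
ring gaps and preserves topology.  The membrane band is the internal
morphological gradient of the filled mask — filled minus its erosion
by a disc of k = round(thickness/pixel) ≥ 1 — intersected with the
original union mask, which discards spurious signal inside vesicles.

Vesicles are labelled as 8-connected components of the filled mask on
a reference frame (default frame 0; vesicles are immobilized, so
regions are frame-fixed).  Components with equivalent radius
√(area/π) below 1 µm or circularity 4πA/P² below 0.7 are discarded —
the automated analogue of manual ROI curation; in particular, adjacent
vesicles merged by the mask fail the circularity filter and are
excluded rather than mis-measured.  Each region's membrane pixels at
frame t are that frame's membrane band within 1.5 R of the centroid.

Known bias: the filled component is bounded by the *outer* edge of the
detected ring, so the radius estimate exceeds the ring-centerline
radius by about half the membrane thickness plus ~0.5 px of mask
widening (≈ +4 % at R = 6 µm, proportionally more for small vesicles).
This module contains no randomness.

## Quantification

Traces are arithmetic means over each region's membrane pixels, per
channel and frame; a frame with an empty pixel set yields a missing
value (never silent zero), excluded from regression with a logged
count.  The baseline is estimated from GUV-free regions — by default
ten disc ROIs placed deterministically on the grid positions farthest
from any segmented vesicle (no RNG), or supplied manually.  Each
region contributes one per-frame mean profile; profiles are averaged
unweighted by area.  The baseline is subtracted from the reporter
channel only, per time point; negative corrected values are preserved.
`corrected + baseline == raw` is asserted on every table the pipeline
writes.

## Initial rates

The linear region is located automatically: all contiguous windows of
at least `min_points` samples are fitted by OLS; among windows with
r² ≥ 0.95 the steepest is selected, except that slopes within one
standard error of the steepest count as tied, and ties resolve to the
longer window, then the earlier start.  If no window qualifies, the
steepest minimum-length window is returned flagged `low_confidence`.
A manual window (the classical procedure) overrides the search.

Two numerical choices matter and were set by a bias analysis plus a
simulation study on the synthetic fixtures:

- *One-SE tie band.*  The literal argmax of the slope over many
  overlapping windows is upward-biased by roughly the slope SE of the
  shortest admissible window.  For weakly active conditions this
  inflates the denominator of fold-changes (e.g. a 0.1 AU/min
  condition read ~30 % high with 4-point windows), deflating 7–11×
  ratios well outside tolerance.  On noiseless traces the SE of an
  exactly linear window is zero and the band reduces to exact ties.
- *`min_points` = 14* (35 min at the default frame interval): long
  enough to make the residual selection bias ≤ ~3 % at fixture noise,
  short enough to sit inside every fixture's linear region.  For
  acquisitions with early plateaus this default should be lowered.

Recovered absolute rates carry a multiplicative attenuation (~0.64 at
default PSF and band geometry) because blur spreads ring intensity
beyond the measured band; it is common to all conditions of an
experiment and cancels exactly in fold-changes, which is what the
assay interprets.  Fold-change is the ratio of group means of per-GUV
rates (vesicles as replicates); groups are compared with a two-sided
Welch t-test (Welch–Satterthwaite df).  Both SD and SEM are reported.
Degenerate case: two zero-variance groups with equal means give p = 1,
flagged.

## Curvature analysis

Per vesicle, the corrected reporter intensity at the frame nearest
t_end (default 60 min) is paired with curvature 1/R (R from the 2-D
section, not a 3-D mean curvature); OLS of intensity on curvature with
a t-test on the slope (df = n − 2).  A least-squares (Kåsa) circle fit
is available for radius estimation from arbitrary boundary points and
is exact on noiseless circles.

## HDX-MS utility

Peptides pass the inclusion filter iff they meet *all* criteria, with
inclusive boundaries: intensity ≥ 5000, length ≥ 5, products per amino
acid ≥ 0.1, |MH⁺ error| ≤ 5 ppm, identified in ≥ 2 of 3 undeuterated
files.  Rejections carry every violated criterion.  Sequence coverage
is the union of residue spans over the protein length, computed on the
filtered set.  Uptake differences are per shared exposure
(Δ = bound − apo); a peptide is classified protected/deprotected when
|Δ| exceeds a configurable threshold (default 0.5 Da, a community-
conventional magnitude — the choice is an explicit configuration, not
a statistical test) at ≥ m exposures (default 1).  Theoretical maximum
uptake excludes the N-terminal residue and prolines.

## Numerical and degenerate-input policy

r² is defined as 1 when SS_tot = SS_res = 0 (exact constant fit);
slope SE is NaN for 2-point fits.  Collinear input to the circle fit,
shape-mismatched masks, non-increasing time grids, empty time grids,
thresholds of wrong sign, and out-of-range t_end all raise explicit
errors.  Erosion radii computing to 0 px clamp to 1 with a warning.
Missing acquisition metadata falls back to config values with a logged
warning, never silently.

## Problem sizes

Tests and the acceptance script run movies of 256×256 px × 25 frames
× 2 channels with 15–30 vesicles per condition and three replicate
seeds per comparison — enough that pooled ratio estimates are stable
to a few percent while a full acceptance run completes in about a
minute on one CPU.
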