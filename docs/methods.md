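# Methods

This note documents the models behind each analysis, the synthetic data the
package validates itself on, and the numerical choices that were genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Expansion-microscopy contact classification

**Model.**  A contact between a presynaptic bouton and a GFP-filled GnRH
dendron is scored on relative-intensity profiles: each channel is normalized
to its in-scan peak and the *overlap* is the longest contiguous span on which
both normalized channels are at or above a level (default 0.5, half-max).
A side-on apposition is a synapse when the overlap strictly exceeds
θ_side = 0.95 µm; a face-view (z-stack) apposition when it strictly exceeds
θ_face = 1.75 µm — both post-expansion.  Non-synaptic contacts split into
*close* (surface gap ≤ 1 µm post-expansion) and *separate*.  The 1 µm cut is
a package choice: published work reports a mean bouton–dendron distance for
non-synaptic contacts but no explicit cut; it is configurable
(`MorphThresholds.close_gap`).  The half-max level is likewise an explicit
convention — line-scan overlap figures in the literature do not state the
level at which overlap is read off — chosen because full-width-half-max is
the standard width convention and makes the measure monotone in the level.

**Pipeline.**  GFP is lightly smoothed, thresholded (Otsu by default,
absolute threshold configurable), connected components are reduced to
centrelines by projecting voxels onto the component's principal axis and
taking binned centroids (1 µm bins, smoothed, extended to the projected
extremes).  This centreline tracer assumes straight-to-gently-curved tubes,
which is the geometry of distal dendrons; it replaces voxel thinning, whose
grid zigzag inflates geodesic lengths and which proved unreliable on
anisotropic masks.  Mean radius follows from volume = π r² L.  Segments
shorter than `min_length_pre` (default 10 µm pre-expansion) are discarded.

Boutons are connected components in the kisspeptin (or synaptophysin)
channel, refined to the component above half of the component's own peak so
the equivalent diameter tracks the punctum's FWHM; the detector's smoothing
width is removed from the measured diameter in quadrature.  Boutons with
corrected equivalent diameter ≤ 0.4 µm are discarded.  Co-channel membership
requires ≥ 50 % of the refined mask to lie inside the co-channel's mask.

Orientation is *face* when the bouton-to-surface axis lies within 45° of the
optical (z) axis, else *side* (the cone half-angle is a package choice; the
original assessment is visual).  For boutons whose centre lies inside the
GFP mask, the direction is taken from the dendron axis with the along-axis
component projected out.  Side profiles are 1D line scans through the axis
point and the bouton centre at the xy pitch; face profiles are per-slice
means in a 2 × 2 µm box through the z-stack.  Overlap crossings are refined
by linear interpolation, so measured overlaps are not quantized to the
sampling pitch (verified against a 1 nm brute-force oracle).

In confocal modality (expansion factor 1) synapses cannot be resolved; a
contact is a *close apposition* when no voxel between the elements is dark
in both channels (dark = below the segmentation threshold), else separate.

**Census.**  Densities are reported per *pre-expansion* dendron length
(length_post / expansion factor; default factor 4.17 = 250/60, configurable
because published pre/post pairs imply 4.0–4.17).  `dendrons_per_fiber`
needs a bouton→fiber assignment (from the generator's ground truth in
simulations; from fiber tracing otherwise) and is NaN when absent.

## Calcium responder calling

ΔF% is implemented as 100·(F − F₀)/F₀, so baseline reads 0 and a "35 %
response" means a 35 % rise — the convention matching reported percentages.
F₀ is the mean of the leading `baseline_frames` (default 20) samples.

**Drift QC.**  Drift is |mean ΔF% of the trailing baseline-length window −
mean of the leading window|, i.e. the net baseline change across the
recording; recordings with drift ≥ 5 % are rejected (strict).  A pre-puff
linear fit extrapolated over the full 500 s was rejected as the estimator:
its slope error is amplified ~25-fold by the extrapolation, which would
reject most clean recordings at realistic noise.  The first-vs-last window
form assumes the response has largely subsided by the end of the recording,
which matches the emulated time course.

**Threshold.**  mean + 2 × sample SD (ddof = 1) of control aCSF changes.
Control changes of mean 4.5 %, SD 0.5 % give the canonical 5.5 %.

**Responder.**  |peak ΔF%| from puff onset onward must strictly exceed the
threshold (increases and decreases both count, sign retained), *and* |ΔF%|
must stay above threshold for at least 2 *consecutive* frames after the puff
ends.  The duration arm uses consecutive frames rather than a single frame
because at 2 % trace noise a lone supra-threshold frame occurs in most
artifact-only traces, which would void the mean+2SD construction; two
consecutive frames (~2.2 s at 0.9 Hz) keep the artifact false-positive rate
within the one-sided mean+2SD logic while leaving sustained responses —
which exceed threshold for minutes — unaffected.  Configurable
(`min_outlast_frames`).

**Group statistics.**  Per-timepoint mean with t-based 95 % CI across ROIs
(across-ROI, not across-animal, is the implemented convention), trapezoidal
AUC of the mean trace (s·%F), responder fraction, and rank-based tests:
Mann–Whitney (2 unpaired), Wilcoxon signed-rank (2 paired), Kruskal–Wallis /
Friedman (k groups) with a hand-rolled Dunn post hoc (rank-based z with
Bonferroni adjustment; no post-hoc library is assumed).  All-tied inputs are
reported as p = 1 with a `degenerate` flag.

## Photometry and LH coincidence

Scheduled samples are collapsed to one mean per 5 s on-burst.  ΔF/F divides
by a running 10th-percentile baseline (30 min window): the conventional
"basal fluorescence" denominator; dividing by instantaneous F (an
alternative reading of the printed formula in the source literature) differs
only by a factor and is not used.  SEs are `find_peaks` maxima strictly
exceeding 10 % of the recording maximum (per-recording maximum is the
implemented convention) with an abruptness requirement — the last upward
crossing of the 10 % level at most 2 min before the peak — and a 60 s merge
window.  A small absolute floor (0.5 % ΔF/F) guards against noise-only
traces, where "10 % of maximum" would otherwise label noise wiggles.

LH pulses: a local maximum (including a rising final sample, since a
recording may truncate a pulse) is a pulse when its rise from the preceding
nadir exceeds max(2·CV·nadir, 2·assay floor) with CV = 0.093 and floor =
0.04 ng/mL, the stated assay characteristics.  No published pulse-detection
algorithm accompanies the source data; this criterion is an explicit
stand-in scaled to assay noise.

Coincidence: each pulse is greedily matched to the nearest preceding
unmatched SE within 10 min (covering the 1–2 min lead of SEs over pulses
plus the 3–5 min blood-sampling granularity); matching is one-to-one and
fractions are reported over both denominators (NaN when a denominator is
empty).

## Synthetic data: what it emulates, and what it does not

**ExM scenes.**  Dendrons are straight cylinders (default radius 1.75 µm
post-expansion) along x; boutons are Gaussian-profiled spheroids whose FWHM
equals their diameter, displaced from the dendron surface by a planted
signed gap (negative = interpenetration).  The planted intended class is the
one implied by the half-max geometry: the GFP half-max support spans ±r on a
side scan and ±(√3/2)·r on a face box-profile (the height at which a
cylinder chord halves), so a planted face overlap needs thick processes —
consistent with face-view synapses being assessed at somata/proximal
dendrites.  Channels are blurred by an anisotropic Gaussian PSF
(σ_xy = 0.1 µm, σ_z = 0.3 µm), normalized, and corrupted with Poisson shot
noise scaled so that peak SNR = √(peak counts) equals `noise_snr`, plus 1 %
Gaussian read noise.  Voxels default to 0.1 µm in-plane / 0.6 µm z steps.
Not emulated: immunostaining variability, antibody penetration, gel
distortion anisotropy, tissue background, curved/branching dendrons.
Recovery results therefore show the *decision logic* is correct under
realistic optics and noise, not that segmentation is robust to every
histological artifact.

**ROI traces.**  0.9 Hz, 500 s, 90 s puff starting at 100 s.  The movement
artifact is a half-sine confined to the puff window with amplitude ~
Normal(4.5, 0.5²) %.  Responses ramp across the puff to ~35 % and decay
exponentially (τ = 100 s, so <5 % of peak remains by the recording end —
"subsiding across the post-puff window").  The default responder fraction is
0.91.  Drift is a linear ramp of the stated total.  Not emulated: x–y tissue
displacement (motion registration is out of scope), bleaching curvature,
correlated noise across ROIs.

**Photometry/LH.**  1.5 h sessions, 4 SEs/h placed near-uniformly with
jitter (with an end margin of the LH delay + two sampling intervals so the
final pulse is sampled), double-exponential transients (10 s rise / 40 s
decay, 10 % ΔF/F), 2 % acquisition drift, scheduled 5/15 s sampling at 1 Hz
within bursts.  LH: baseline 0.25 ng/mL (intact) sampled every 4 min; in
coupled mode each SE is followed 2 min later by an instantaneous-rise,
exponential-decay (τ = 6 min) pulse of 1.2 ng/mL; multiplicative assay noise
(CV 9.3 %) and a 0.04 ng/mL floor.  The uncoupled regime uses a flat
0.1 ng/mL baseline, emulating the very low invariant LH of Kiss1-null mice.
Not emulated: estrous-cycle modulation, isosbestic reference channels,
photobleaching nonlinearity.

## Problem sizes and determinism

Validation runs use 7 scenes × 30 appositions (≈ 210), 1000 ROIs per
responder condition, and 20 coupled + 100 uncoupled photometry sessions —
sizes at which the binomial uncertainty of the reported rates is well below
the acceptance margins while the full run stays in the minutes range.  All
generators draw from `numpy.random.default_rng(seed)` and are bit-for-bit
reproducible; the pipeline writes byte-identical outputs under a fixed seed.

## Known limitations

- The centreline tracer assumes one non-branching process per connected
  component; touching or branching dendrons would need a true skeletonization.
- Bouton detection assumes roughly isotropic puncta separated by more than
  the PSF; merged puncta are counted once (at the component's peak).
- The LH pulse criterion is assay-noise-scaled, not a re-implementation of
  any published pulse detector; absolute pulse counts on real data would
  need benchmarking against one.
- Face-view overlap recovery degrades when the dendron radius approaches
  θ_face / √3, since the GFP face-profile half-max span (≈ 1.73 r) then
  cannot exceed the threshold.
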