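# Methods

cardioquant reimplements, as a tested pipeline, four quantification
procedures used to characterize sarco-endoplasmic-reticulum disruption in
cardiac muscle: optical contractility analysis of single adult
cardiomyocytes, rhythm analysis of embryonic zebrafish heart chambers,
two-channel colocalization statistics, and iBAQ-based interactor-enrichment
scoring. Every stage is exercised against a synthetic-data generator whose
ground truth is available in closed form, so recovery can be verified
exactly.

## Single-cell contractility

**Model.** A spontaneously contracting, isolated myocyte is imaged as a
16-bit time-lapse movie (one frame per 40 ms). Contraction is read out as
fractional shortening (FS) of the cell length along its longest axis:
FS = (rest length − peak-contraction length) / rest length × 100%.

**Procedure.** Per frame: (1) binarize with the *image mean* as threshold
(inclusive `>=`, so boundary pixels of bright cells are kept), keep the
largest 8-connected component and fill interior holes; (2) trace the
sub-pixel 0.5-iso outline (marching squares) and smooth its x/y coordinate
sequences with a Savitzky–Golay filter, order 2, window 75 boundary samples,
periodic extension; (3) re-rasterize the smoothed outline; (4) measure the
chord of the mask under the longest-axis line, sampled at 0.25-px steps
(quantization error ≤ 0.5 px). The axis is the principal second-moment axis
through the centroid — robust to single-pixel protrusions, unlike a Feret
diameter — estimated once on the first valid frame and then frozen, so that
rigid rotation is not conflated with shortening. Isotropic shapes tie-break
toward the image x-axis and are flagged.

The length trace is normalized to the first rest plateau (first 1-s window
with coefficient of variation < 1%; cells are longest and quiet at rest;
fallback: 95th percentile of all lengths, flagged), then detrended by
subtracting a best-fit sixth-order polynomial. The polynomial fit is made
robust to the contractions themselves by iteratively excluding samples more
than 3 robust SD below the fit and refitting (3 rounds): without this the
pulses drag the baseline down and amplitudes are underestimated by ~10%
relative. Events are peaks of the negated residual ×100 with height ≥ 5% FS
and separation ≥ 0.2 s (well below physiological inter-beat intervals);
onset/offset are the nearest half-threshold crossings. The per-cell summary
is the arithmetic mean event amplitude and the frequency = 1 / mean period
between successive peaks; with fewer than two events the frequency is 0 with
an explicit below-detection flag.

Amplitude is measured against the local detrended baseline rather than
strictly against the initial rest length; for drift-free traces the two
coincide.

**Known limitations.** The chord definition matches "length under the line"
for convex cells and undershoots for concave ones. The fixed 75-sample
smoothing window is tuned to adult-myocyte scales: for cells whose outline
tips span much of the window (roughly < 150 px long axis) tip shrinkage
inflates measured FS by up to ~1 percentage point, which is why the test
movies use cells of 160–200 px.

## Zebrafish chamber rhythm

**Model.** Atrial and ventricular areas versus time, as produced by
semi-automated chamber delineation of bright-field movies. Beats appear as
end-diastolic area maxima; a healthy embryo beats 1:1 (atrium:ventricle);
atrioventricular (AV) block shows ratios like 3:1.

**Procedure.** Each profile is convolved with a discrete Gaussian
(default σ = 0.2 s; σ = 0.1 s is exposed as the common alternative — both
are defensible for embryonic rates and neither is asserted as canonical),
truncated at ±4σ and renormalized, then divided by its mean. Boundaries use
*odd (antisymmetric) reflection*: plain even reflection phase-cancels an
oscillation at the recording edge and silently drops the first/last beats
of a 15-s window, which corrupts beat counts by ~3–10%. Beats are prominent
maxima in the half-open window [0, 15 s) (no double-counted boundary peak);
bpm = count × 60/15. The prominence floor is 2% of the smoothed profile's
peak-to-peak *range*, not of its mean: Gaussian smoothing attenuates a
period-T sine by exp(−2π²σ²/T²) (≈ 74× at T = 3/7 s, σ = 0.2 s), so any
mean-relative floor would have to know the heart rate in advance, whereas a
range-relative floor adapts to the attenuated signal and keeps counting
scale-invariant. AV ratio = atrial count / ventricular count;
|ratio − 1| > 0.1 (boundary inclusive as synchronous) is dyssynchronous; a
silent ventricle reports "atrial-only". Penetrance is
100 × affected / total.

**Known limitations.** A range-relative prominence floor presumes a beating
signal dominates the profile; a zero-amplitude noisy trace yields spurious
counts (a flat noiseless trace correctly yields zero). Beat-count recovery
under noise is exact in simulation for 5%-of-mean white noise at periods
≥ 1 s with σ = 0.2 s; at periods near 0.4–0.5 s the σ = 0.2 s smoothing
pushes the signal below the smoothed noise floor and counting degrades —
use σ = 0.1 s for fast rhythms in noisy recordings.

## Colocalization

Pearson correlation is computed over voxel intensities within an optional
cell mask; 3-D stacks are treated voxel-wise as a whole. Percent overlap
uses per-channel Otsu thresholds within the mask;
`pct_a_in_b = 100 · |A⁺ ∩ B⁺| / |A⁺|` (voxel counts), with an
intensity-weighted Manders-style variant available. The original analysis
was performed in a commercial package without stated definitions; these
standard reconstructions are labelled as such in the output metadata, and
voxel-count overlap is the default because nothing in the reported
percentages indicates intensity weighting.

## iBAQ enrichment

MaxQuant-style tables (`Protein IDs`, `iBAQ <sample>` columns) are parsed
with zeros/empty cells normalized to an explicit not-detected marker
(MaxQuant dialects use both). Proteins detected in fewer than 3 of the 8
runs are excluded ("detected in only 2 of 8" is read as at-most-2, since
proteins seen in 0–1 runs clearly cannot be meant to survive). Per
condition, the mean iBAQ intensity is taken over detected runs; a condition
with zero detections gets its *average* replaced by 10 (the imputation is at
the condition-average level, on the raw iBAQ scale — no log transform is
implied anywhere), flagged as imputed. Fold change =
mean(transfected)/mean(control). Consequence of raw-scale imputation,
documented and tested: fold changes of fully detected proteins are invariant
to global intensity rescaling, while imputed-denominator fold changes scale
with it. No ANOVA/multiple-testing layer is included; ranking by fold change
is the deliverable.

## Synthetic data: what it emulates and what it does not

* **Cell movies** — a filled, rotatable ellipse whose long axis follows
  raised-cosine shortening pulses (smooth onset/offset; peak shortening is
  exactly 1 − contraction_ratio, so truth is closed-form); the short axis is
  held constant so "longest axis" stays unambiguous; additive Gaussian
  intensity noise. Defaults are the study conditions of the headline
  contractility experiment: 512×512 at 25 frames/s for 20 s, a
  200 × 80 px cell, contraction ratio 0.876 (true FS 12.4%), five 0.6-s
  events ~3.7 s apart (true frequency 0.27 Hz). No point-spread function,
  per-photon shot noise, or sarcomere texture — so passing recovery tests
  demonstrates correctness of the measurement chain, not robustness to
  optical blur or texture.
* **Chamber traces** — baseline × (1 + a·sin(2πt/T)) per chamber, sampled on
  the closed interval [0, duration] (so a cycle dividing the recording is
  sampled whole), with optional skipped beats (held at baseline from
  zero-crossing to zero-crossing, ±3T/4 around the deleted maximum, so no
  discontinuity or spurious plateau-maximum is introduced) and Gaussian
  area noise. Defaults model a healthy 140-bpm embryo (T = 3/7 s, 20%
  excursion, 15 s). No 2-D heart video is synthesized.
* **Colocalization pairs** — standardized Gaussian fields with
  B = ρA + √(1−ρ²)·noise, affinely mapped to 16 bits (mean 32000, SD 3500,
  so clipping is negligible); population Pearson correlation is exactly ρ.
* **iBAQ tables** — log-normal run noise around per-condition means
  (σ² = ln(1+CV²), mean-preserving) with Bernoulli detection dropout;
  truth fold changes follow the imputation rule in closed form. Default: two
  conditions × 4 runs (the 8-run design).

All randomness flows through one seeded `numpy` generator per call —
identical spec + seed gives byte-identical outputs (tested).

## Numerical choices

* Threshold comparison `>=` mean; smallest event amplitude accepted is
  exactly the 5% threshold (inclusive peak height).
* Sub-pixel chord sampling step 0.25 px; nearest-neighbour membership.
* Savitzky–Golay window shrinks to the largest odd value ≤ outline length
  when outlines are short (logged); order capped below the window.
* Detrend degree falls back to ⌊n/2⌋ − 1 for traces shorter than 14 samples.
* Gaps of ≤ 3 degenerate-mask frames in a movie are linearly interpolated;
  longer gaps raise.
* AV-tolerance comparison carries a 1e-12 epsilon so integer ratios like
  11/10 sit exactly on the inclusive boundary.
* Problem sizes in the test suite (256×256 movies, 8–10 s; 10⁶-voxel
  colocalization fields) were chosen as the smallest sizes at which the
  stated tolerances hold with comfortable margin.
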