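# Methods

## Problem and signal model

Camera-based (remote) photoplethysmography extracts the blood-volume pulse
from ordinary video of skin: each heartbeat changes arterial blood volume,
which modulates how much light the skin absorbs, producing a periodic
sub-quantization-step brightness oscillation at every skin pixel.  This
package implements a pipeline that turns a short (~4 s, 30 fps) facial video
into *pulsatile feature maps* — per-pixel descriptors of that oscillation —
and evaluates whether such maps carry subject-independent information about
emotional state.

The optical model is Beer–Lambert reflectance:

    I_λ(t) = I_{0,λ} · ( exp(−(A_DC,λ + A_pulsatile,λ(x, y) · s(t))) + R_S,λ )

with incident intensity `I_0`, static absorbance `A_DC` (tissue, bone,
average blood volume), per-pixel pulsatile absorbance swing `A_pulsatile`,
unit pulse waveform `s(t)` at the heart frequency `f_0`, and a specular
(pulse-free) surface reflection fraction `R_S`.  Reflected intensity peaks
at diastole (`s = −1`, minimal absorbance) and bottoms out at systole
(`s = +1`).

Two features are computed from frames sampled at the detected heartbeat
peaks (`I_max`) and troughs (`I_min`), five of each per clip:

* `I_AC = I_max − I_min` — the pulsatile amplitude, proportional to
  `I_0 · (R_D,max − R_D,min)`; invariant to additive offsets.
* `I_R = ln(I_max / I_min)` — the absorption amplitude, which cancels
  static absorbers; with negligible specular reflection it equals the
  peak-to-trough absorbance swing `2 · A_pulsatile`.  Invariant to
  multiplicative gain.

Each feature is a 224 × 224 × 5 block (five heartbeat events at high
spatial resolution), the classifier input.

## Pipeline stages and the choices inside them

**Face ROI.** Reflective clips: a pluggable per-frame detector runs on every
10th frame; per-frame boxes (largest, if several) are averaged
coordinate-wise and rounded, and the single averaged box crops all frames.
The default detector is a border-background blob finder (below) — adequate
for fixed-camera scenes; a trained face detector can be plugged in.
Thermal clips: the mean of 3 uniformly sampled frames (first, middle, last)
is min-max normalized, blurred with a 5 × 5 averaging kernel and
Otsu-thresholded; the warm side is the face and its bounding box the crop.
Constant images raise an explicit degenerate-input error.

**Skin segmentation.** On every 10th frame (12 frames of a 120-frame clip):
person/background separation (pluggable backend), then 2-means clustering of
blue-channel intensities inside the person mask — the larger cluster is
taken as skin, since facial skin dominates the person area in a chin-mounted
setup.  The bright chin stand is removed by a static threshold: gray level
≥ 185 counts as stand (the boundary value is removed).  Per-frame masks are
AND-ed across the sampled frames and opened with a 10 × 10 square
structuring element.  The opening pads with background before calling the
library routine, so the result equals the mathematical opening (union of
fully contained squares) regardless of border conventions — opening is
independent of the structuring element's origin, which sidesteps the origin
ambiguity of an even-sized element.

The default person backend estimates the background gray level from a low
percentile of the 2-pixel frame border (the darkest border pixels remain
background even after cropping brings hair or the chin stand to the edge)
and labels pixels more than 15 gray levels above it as person.  This is a
deliberately simple stand-in appropriate for a recording-booth scene;
deployments with varying backgrounds should plug in a semantic segmenter.

**Head-movement rejection.** The AND of the per-frame skin masks (after
chin-stand removal, before opening) measures how much the subject moved; a
clip is rejected when that overlap covers less than 35% of the frame
(`sum(mask)/(H·W) < 0.35`).  The rule is reported per clip, not silently
applied, so callers can count rejections like a curation pass.

**Heart-rate estimation (EHR).** The masked green channel is downsampled by
10 × 10 block averaging (averaging neighboring pixels suppresses
quantization noise in the temporal signals), each remaining pixel is
band-pass filtered to 0.75–3.5 Hz (45–210 bpm), and the per-pixel FFT
magnitude argmax within the band forms a frequency map.  A 3 × 3 spatial
median filter smooths the map and the EHR is the median of its non-zero
values.  Green is used because hemoglobin absorption and Bayer-sensor
characteristics give it the best SNR.

Numerical choices: the band-pass is a true 6th-order Butterworth band-pass
(three analog poles through the band transformation) run forward-backward
(zero phase), so extrema timing is not skewed — this matters for peak
indexing.  FFT length equals the clip length (no padding or window): the
frequency resolution is `fs/T` = 0.25 Hz for 4 s at 30 fps, which bounds the
achievable HR accuracy at ±one bin.  Argmax ties break to the lower
frequency (deterministic, conservative).  Medians of even-sized multisets
use the lower-median convention.  The median filter excludes zero
(non-skin) neighbors and never assigns values to non-skin pixels, so the
map cannot grow past the mask.

**Dual-resolution reshaping.** The square face crop is scaled to 56 × 56
(after 10 × 10 block averaging for RGB, 5 × 5 for the smaller-sensor NIR)
for clean temporal signals, and to 224 × 224 (after 2 × 2 averaging for
RGB) for spatial detail at a standard network input size.  Interpolation is
separable Keys bi-cubic with edge replication, implemented as two cached
1-D weight matrices so a whole clip resizes in one pass; rows sum to 1, so
constants are preserved exactly.

**Peak/trough detection.** Each 56 × 56 pixel's band-passed series is
scanned for local maxima with a minimum separation of
`d = ⌊(3/4) · T_HR / T_S⌋` samples — three quarters of a heartbeat period at
the clip-level EHR — which suppresses false positives between genuine beats;
conflicts are resolved greedily in favor of higher peaks.  Troughs are peaks
of the negated series with the same `d`.  Up to 5 of each are stored (the
first 5 in time when more exist, e.g. ~14 beats are possible at 210 bpm in
4 s; a keep-highest alternative is flag-selectable); shorter lists are
padded.  The pad sentinel is −1 internally because frame index 0 is a legal
peak time; exported arrays use zero padding with a validity mask alongside.
A band-passed series with total excursion below 1e−6 gray levels (far below
one quantization step) is treated as flat rather than letting floating-point
residue masquerade as a pulse.  The 56 × 56 index arrays are upsampled to
224 × 224 by nearest-neighbor repetition (each location fills its 4 × 4
block) and the high-resolution frames are sampled at those times — pure
indexing, no interpolation.  The n-th peak pairs with the n-th trough; a
position padded in either stack is 0 and invalid in the features.  The LWIR
channel shows no heartbeat information at these time scales, so its "stack"
is 5 uniformly sampled frames (indices 0, ⌊T/4⌋, ⌊T/2⌋, ⌊3T/4⌋, T−1).

**Feature guards.** `I_R` floors both stack values at ε = 1 gray level
(8-bit scale) inside the logarithm; activations at valid positions are
counted on the block.  On noisy data `I_AC` can be negative at some
positions (stacks sample raw frames at filtered-signal extrema); values are
passed to the classifier unmodified — clipping would discard information.

## Classification harness

Subjects are deduplicated, shuffled under a seed and partitioned into
disjoint groups of 5; each fold tests one group and trains on the rest
(leave-5-subjects-out), so identity can never leak between train and test.
Class imbalance is handled by a weighted loss, `w_c = N / (n_classes · N_c)`
(inverse class frequency; balanced data gives weight 1), rather than
resampling.  Training augmentation applies a rotation drawn uniformly from
{0°, 90°, 180°, 270°} and independently zeroes each spatial pixel's full
temporal vector with probability 1/124.  Hyperparameters follow the study
recipe: learning rate 0.001, batch size 64, dropout 0.5, 25 epochs
(the "iterations" count is read as epochs; configurable).  Feature blocks
are consumed raw, on the gray-level scale; an optional per-block
standardization (`normalize_inputs`) is available but off by default, since
no input normalization is part of the recipe.

The default backbone is a small NumPy CNN: an average-pooling stem to
28 × 28, three 3 × 3 convolution blocks (8/16/32 filters, ReLU, 2 × 2 max
pooling after the first two), global average pooling, dropout 0.5 and a
linear head, trained with Adam and the weighted cross-entropy above.  Every
fold trains a freshly initialized model (standard cross-validation).  A
flatten-plus-linear backbone is provided for fast statistical tests of the
training procedure.  The backbone is pluggable — any object with
`fit`/`predict` — so a large pre-trained CNN can be substituted where
available; input depth is a constructor argument, so concatenated
multi-feature blocks (depth 10, 15, …) are accepted.

Metrics per fold: the 5 × 5 confusion matrix (rows = true class), per-class
precision/recall/F1 (0/0 reported as 0 and counted), macro (unweighted
class-mean) metrics summarized as mean ± SD across folds, overall accuracy
as trace over total of the summed matrix, and the row-normalized summed
matrix.

## Synthetic data: what it emulates, what it does not

The generator renders the Beer–Lambert model over a scene: an elliptical
face of skin centered in frame, a darker hair/collar crescent around the
upper face (the non-skin person region that gives 2-means its real second
cluster), a dark background, an optional bright chin-stand rectangle
(≥ 200 gray levels, exercising the threshold-185 rule), optional linear
integer-pixel head translation (exercising the 35% rule), Gaussian camera
noise and 8-bit quantization (applied after noise, matching real camera
output).  Channel amplitude ratios B : G : R = 0.7 : 1.0 : 0.5 (G strongest,
NIR 0.35, LWIR 0) reflect hemoglobin absorption spectra and sensor SNR.
The pulse waveform is a pure sinusoid by default; a PPG-like asymmetric
waveform (fast systolic rise) is available behind a flag, since waveform
shape is not part of the model being tested.

Amplitude scale: no gray-level scale for the pulsatile component is
established in the literature for this setup, so defaults were chosen once:
base absorbance swing 0.02 around `I_0 = 220`, `A_DC = 0.5` gives a
peak-to-peak excursion of ≈ 5 gray levels in G against default noise of
1 gray level — per-pixel SNR of a few dB, i.e. recoverable but not trivial,
and consistent with the motivation for block-averaging before spectral
analysis.  The feature closed-form checks use swing 0.05 so quantization
(±0.5 gray level) stays well inside a 10% tolerance.

Cohorts draw per-subject baselines: incident intensity in [190, 240], static
absorbance in [0.35, 0.7] (a realistic skin-tone spread), heart rate in
[0.9, 3.0] Hz, roughly half the subjects with a chin stand; labels cycle
through the five classes so cohorts are balanced up to a remainder.
Class-dependent spatial patterns multiply the base amplitude.  The provided
disjoint templates are **concentric annuli** rather than quadrants: the
training augmentation rotates blocks by 90/180/270°, and annuli centered on
the face are invariant under those rotations, whereas quadrant-style regions
would alias across classes under the study's own augmentation.

Known limitations of the emulation: no photorealistic appearance, no
heart-rate variability (a single `f_0` per clip), no waveform morphology
beyond the optional asymmetric flag, no thermal-emission physics (LWIR is a
static intensity map), no illumination drift, and a three-gray-level person
(hair/skin/stand) whose 2-means geometry is cleaner than real faces.  One
consequence is visible in the cohort: for dark-skinned subjects recorded
with the bright stand, the optimal 1-D 2-means isolates the stand as its own
cluster and the "larger cluster" rule keeps hair in the skin mask; the
downstream stages tolerate this (hair carries no pulse), and it mirrors the
kind of clustering ambiguity reported for real chin-stand recordings.
Passing tests therefore demonstrate correctness of the *algorithms* under
the stated optical model, not performance on real faces.

## Benchmark experiments and problem sizes

Two end-to-end experiments (module `pulsemap.experiments`) are the package's
substitute for a validation dataset, sized to run in minutes on one CPU:

* **HR recovery** — 50 clips of 64 × 64 × 120 frames, pulse rate uniform in
  [0.9, 3.0] Hz, default noise; recovery is |EHR − f₀| within one FFT bin
  (0.25 Hz).
* **Classifier recovery** — 20 subjects × 5 clips of 80 × 80 × 120 frames
  through the full pipeline to `I_AC(G)` blocks, leave-5-subjects-out
  (4 folds).  The signal cohort uses the annular templates; the null cohort
  gives every class the same template, and its accuracy is checked against
  a binomial band around the 20% chance level.  Training uses 150 epochs:
  the 25-epoch recipe is tied to a ~14,000-clip dataset (hundreds of
  optimizer steps per epoch), and at ~75 training clips the equivalent step
  budget requires more passes; all other hyperparameters are unchanged.

## Degenerate inputs and failure behavior

Constant images make Otsu and 2-means undefined — explicit errors, never a
silent guess.  Clips shorter than the analysis window raise an exclusion
error (the caller decides to skip, as a curation pass would).  An empty skin
mask (before or after opening) aborts that clip's pipeline; cohort runs can
be configured to skip such clips the way curation drops them, and skips are
counted.  `fps ≤ 2 f_0` is rejected at generation time (aliasing).  Peak
detection on an empty or flat series returns fully padded arrays, which
propagate to all-zero, all-invalid features — the zero-amplitude clip maps
to an exactly-zero `I_AC` block end to end.
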