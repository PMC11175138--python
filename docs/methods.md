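# Methods

## The signal model

Jerk nystagmus is modelled as a periodic sawtooth in horizontal pupil
position: within each beat of period `P = round(fps / beat_frequency)`
frames, the eye drifts linearly through the slow-phase amplitude `A` over
`P − q` frame intervals (slope `A / (P − q)` px/frame) and is reset to
baseline by the quick phase over the remaining `q` intervals. Nystagmus
typically emerges some way into a positional test, so the waveform is zero
(and frames are labelled negative) before `onset_fraction · n_frames`;
every frame from onset onward is labelled positive. White measurement
noise (`noise_sd`, px) and a slow smoothed-noise baseline wander
(`drift_sd`, px) are added on top.

Normal traces are low-pass-filtered noise (Gaussian kernel, σ = 5 frames,
rescaled to 2×`noise_sd`) plus a smooth-pursuit sinusoid with amplitude
drawn from 0.5–1× the nystagmus amplitude and frequency 0.1–0.5 Hz. The
pursuit term is deliberate: it gives normal traces excursions comparable to
nystagmus, so the two classes cannot be told apart by variance alone and a
detector must learn waveform shape.

Default regime: `beat_frequency` 2–5 Hz (3 Hz default),
`slow_phase_amplitude` 8 px, `quick_phase_duration` 1–3 frames,
`noise_sd` 0.5 px, 30 fps. The clinical recorder's actual amplitude and
noise statistics are not published, so these are plausible values for
320×120 infrared VOG, chosen once and not tuned against any benchmark.

## Rendering and missing data

Frames are drawn as two eye halves (columns [0,160) and [160,320) of a
320×120 canvas): a bright sclera background, an iris disc, and a darker
pupil disc at the eye-half centre plus the commanded horizontal offset,
with optional specular glint and Gaussian pixel noise. The ground-truth
mask is exactly the rendered pupil support. Blinks are a homogeneous
Poisson process in time (rate in events/minute; the literature gives no
blink statistics for this recorder); each blink hides the pupil for a fixed
number of frames, rendered as a closed lid with an empty mask.
Missingness is always an explicit per-frame validity flag, never a sentinel
value, so no arithmetic can silently consume a gap.

What the generator does **not** emulate: iris texture, eyelashes, partial
lid closure, off-axis camera distortion, compression artefacts, vertical or
torsional motion, and inter-subject anatomy. Passing tests therefore
demonstrate that the pipeline machinery is correct and that the method
works in a clean regime; they say nothing about clinical performance.

## Segmentation

The segmenter is a standard U-Net: `depth` encoder levels of two 3×3
convolutions (ReLU) + 2×2 max pooling, a two-convolution bottleneck, and a
mirrored decoder using nearest-neighbour upsampling, a 3×3 up-convolution,
skip concatenation and two more convolutions, closed by a 1×1 convolution
to per-pixel logits. Defaults: depth 4, 16 base filters, 320×240 input —
sized to the preprocessing contract; the published architecture's exact
widths are not stated. Loss is per-pixel binary cross-entropy (also
unstated in the source; BCE is the conventional choice), optimised with
Adam at lr 10⁻⁴, 200 epochs, batch 16, keeping the minimum-validation-loss
weights. Images are resampled bilinearly and scaled to [0,1]; masks use
nearest-neighbour so they stay binary. Each training sample contributes
exactly three augmented variants (mirror; rotation uniform in ±15°;
horizontal shift uniform in ±5% of width), with image and mask always
transformed identically.

A reduced profile (depth 3, 8 filters, 96×72 input, lr 10⁻³) exists for
CPU-scale experiments; it reaches DSC ≈ 98% on held-out synthetic frames
after 15 epochs on 200 training frames.

## Tracking

Per frame: largest connected mask component → 0.5-level outer contour
(sub-pixel) → direct least-squares ellipse. The fit solves the Fitzgibbon
ellipse-constrained conic problem in the numerically stable Halir–Flusser
partitioning, after centring/scaling the points for conditioning; the conic
is converted to centre/axes/angle via the eigen-decomposition of its
quadratic part. Exact conic samples are recovered to machine precision;
degenerate inputs (< 5 points, collinear points, non-elliptical conics)
return `valid = False` rather than a number.

Plausibility gates (the source names the failure mode but no thresholds):
mask area outside [50, 0.3 × image area] px² at 320×240 (scaled with
resolution), centre jump > 40 px from the last valid frame, fit failure, or
a centre outside the image. Every invalid frame invalidates a ±5-frame
guard band (`flag_invalid`), since frames adjacent to a failed detection
are usually half-blinks.

Bridging fills each gap with the last detected position. Fill-forward is
idempotent, never alters a valid sample, and introduces no new extrema —
unlike linear interpolation it cannot fabricate a slow-phase-like ramp
across a blink, which is the entire reason for the rule. Leading gaps (no
prior detection) take the first valid value; that case is undefined in the
source, and backfilling keeps the no-new-extrema property. A trace with no
valid frame at all is returned unchanged and flagged unusable; the pipeline
skips such traces at the clip stage.

## Clips and splits

Clips are 1000 frames, tiled backward from the final frame; the leading
`T mod 1000` frames are discarded because symptoms concentrate late in a
recording, and anything shorter than one clip is dropped. The label rule is
strict: positive iff more than 1% of frames (i.e. > 10 of 1000) are
annotated nystagmus — a clip with exactly 10 positive frames is negative.
Clip inputs are normalised as `(x − median) / (sd + 1e−6)` (flat clips map
to zeros); the detector then sees waveform shape, not the arbitrary pixel
offset of the pupil rest position. Dataset splits are drawn per patient at
8:1:1 with largest-remainder rounding, so no subject's clips straddle
partitions; both eyes of a video contribute clip streams with the video's
label.

## Detectors

Both classifiers take one normalised 1000-sample trace and emit a sigmoid
score; both are 14 layers counting the input and the output activation:

* **CNN1D**: input → [conv3 ×2 → maxpool2] ×2 → conv3 ×2 → global average
  pool → FC → batch-norm → FC(1) → sigmoid.
* **CNN-LSTM1D**: identical conv stack but a third max pool instead of
  GAP, followed by an LSTM (last hidden state) and two FC layers.

The published figure with the exact layer widths is not machine-readable
and the text gives only totals, so widths are free parameters here:
defaults [16,16,32,32,64,64] filters and 64 FC/LSTM units (28,433 and
61,329 trainable parameters) chosen for CPU trainability. The published
totals (92,305 and 117,781) are documented but deliberately not matched —
there is no width setting derivable from the text that reproduces them.

Training follows the published recipe: Adam, lr 10⁻⁵, batch 32, MAE loss
between the sigmoid score and the {0,1} label, up to 200 epochs with early
stopping (patience 20 epochs, our choice; only "early stopping" is stated)
and best-validation-loss model selection. Hidden activations are ReLU
(unstated in the source). The CPU benchmark profile uses half-width filters
and lr 10⁻³ for ≤ 40 epochs; the recipe defaults remain the package
defaults.

All layers — 1D/2D convolution, pooling, GAP, dense, batch-norm, LSTM,
upsampling — are implemented in numpy with manual backpropagation
(`nystrack.nn`) and verified against central finite differences in float64
to ≲ 10⁻⁴ relative error. Determinism: every stochastic step draws from a
`numpy` generator seeded from one global seed; identical seeds give
bit-identical traces, frames, histories and reports.

## Evaluation

Hard calls at threshold 0.5 give the confusion matrix; sensitivity,
specificity, precision, accuracy and F1 are reported in percent. The ±
spreads are standard deviations over 1,000 bootstrap resamples of the
evaluation set (the source reports ± values without stating their origin;
bootstrap is our choice, and replicates with an undefined metric are
excluded for that metric). The ROC sweeps all distinct scores
(`sklearn.metrics.roc_curve`, no intermediate dropping) and AUC is its
trapezoid area; tests pin it to the Mann–Whitney U identity. Segmentation
quality uses the same pixel-level confusion metrics plus DSC =
2TP/(2TP+FP+FN), reported mean ± sd across images with undefined
per-image metrics excluded.

## Problem sizes of the benchmark

`nystrack.pipeline.synthetic_benchmark` (used by `scripts/acceptance.py`)
trains the reduced U-Net on 200 synthetic eye frames (20 validation, 30
held-out), measures trace recovery on a 150-frame noise-free rendering with
one 5-frame blink (RMSE on frames with valid detections, in 160×120
eye-frame pixels), and trains the reduced CNN1D on 1,600 balanced clips
with 400 held out. These sizes make the whole run take a few minutes on one
CPU while keeping every stage's acceptance margin comfortable.

## Known limitations

* Horizontal nystagmus only; vertical/torsional components are out of scope.
* The synthetic renderer's simplicity means segmentation DSC on synthetic
  data (~98%) is optimistic relative to clinical infrared video.
* Fill-forward bridging flattens genuine motion inside long gaps; that is
  the intended trade-off against fabricating slow phases.
* The detectors' widths, the segmentation loss, gate thresholds, guard
  width and bootstrap uncertainty are package design choices where the
  source is silent; each is noted above at the point of use.
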