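# Methods

`earlyvis` models how much face/non-face (and, with the validation-based
protocol, gender) information a *linear* decoder can extract from the
population responses of early visual areas, when stimuli vary in position,
size, orientation and background clutter. The pipeline has four parts: a
synthetic stimulus generator, fixed filter-bank encoders for LGN and V1 cell
classes, a cross-validated readout-training protocol scored in percent
correct and d′, and lesion/probing analyses on top.

## Encoding models

All four variants are two-stage: a fixed linear filter bank, then a
pointwise output rule, then a single trainable linear readout.

**V1 simple cells (V1S).** Cosine Gabor kernels

    k(x, y) = exp(−(x² + y²) / 2σ²) · cos(2π x′/λ + φ),

with x′ the horizontal coordinate rotated by the preferred orientation
(0° = vertical carrier, positive clockwise). Four wavelength channels in
one-octave steps, λ ∈ {256, 128, 64, 32} px (F0..F3 from low to high
spatial frequency); envelope σ = 0.4 λ; square support truncated at 1.5 λ
(rounded to integer pixels); 4 orientations × 4 phases per grid location.
Each channel tiles the 340 × 340 canvas with stride λ/2. In-bounds channels
place ⌊(W − support)/stride⌋ + 1 kernels per dimension, grid centered on
the canvas. The F0 kernels (support 384 px) exceed the canvas: that channel
places ⌊W/stride⌋ + 1 = 3 centers per dimension symmetric about the canvas
center and crops each kernel to the canvas. This is the one placement
convention consistent with the architecture's published per-channel totals;
counts come to 7,088 = (144, 144, 1024, 5776). Responses pass through
half-rectification, max(·, 0).

**V1 complex cells (V1C).** The four rectified phase responses at each
(channel, location, orientation) are summed — the biologically motivated
linear pooling variant of the energy model; 1,772 units. For a drifting
grating the pooled response is proportional to |cos δ| + |sin δ| in the
carrier phase δ, so it is not perfectly phase-invariant: its coefficient of
variation over phase is (π²/4 + π/2 − 4)^½/(√2 · … ) ≈ 9.8%, versus 100%
peak-to-trough modulation for a single rectified phase. Phase invariance is
therefore asserted as CV ≤ 10%, not as exact constancy (a squaring
quadrature pair would give exactly 0%).

**V1 linear receptive fields (V1L).** The Gabor bank without rectification.
A linear unit at phase φ + 180° is exactly the negation of the unit at φ,
and the readout's weights are signed, so the 180°/270° phases are dropped
as redundant; 3,544 units. This identity is asserted in the tests to float
precision.

**LGN.** Difference-of-Gaussians kernels, center σ_c = λ/12, surround
σ_s = 5 σ_c, surround gain 0.2 (center 1), on- and off-center polarities,
same support/stride/tiling rules; 886 = (18, 18, 128, 722) units, rectified.
"1/12th of the desired spatial frequency" is read as a length tied to the
period, σ_c = λ/12, since the center width must scale with the channel.

**Kernel normalization.** Every kernel is mean-subtracted (zero DC) and
L2-normalized. Without DC removal, cosine-phase Gabors and DoGs leak mean
luminance into every response, which the canvas-wide luminance differences
between backgrounds would turn into a trivial cue; normalization makes
channel magnitudes commensurate at the shared readout. Both are exposed as
`BankConfig` switches. Pixel luminance is divided by 255 before filtering
(`input_scale`), keeping activations of order one so the published optimizer
settings (learning rate 0.01, momentum 0.9) sit in their stable regime; on
the raw 0–255 scale the same settings still converge but reach lower
accuracy at equal epochs.

## Synthetic stimuli

The generator replaces photographic sets with procedurally generated
classes matched on the statistics that matter for the task structure:

* **Faces**: upright superellipse silhouettes (exponent 5–9), bounding-box
  elongation ~N(1.66, 0.12²) clipped to [1.35, 2], longest side exactly
  246 px on the 256 × 256 canvas; fixed internal layout (two dark eye
  blobs, bright nose ridge, dark mouth bar) over a per-seed illumination
  gradient and smooth texture.
* **Non-faces**: a heterogeneous mixture — compact blobs (p = 0.35,
  elongation 1–1.6), elongated bars (p = 0.47, elongation 2.6–5, randomly
  horizontal or vertical), and rings/oval confounders (p = 0.18) — with
  generic gradient/noise/stripe textures. The mixture weights were chosen
  once so the class means land near fraction-filled 0.56 vs ~0.4 and
  elongation 1.66 vs ~2.5, with the non-face elongation variance far larger.
* Opaque-pixel luminance is calibrated per image (face mean ~103, RMS
  contrast ~41.5; non-faces generated 15% darker), and the non-face set is
  brightened by 15% (clipped at 255) at set-construction time, mirroring
  the luminance-matching step of the original set construction. Target
  moments are imposed by an iterated affine rescale (3 passes) because
  clipping to [0, 255] perturbs them.
* **Scenes** are procedural: horizon sigmoid + 1/f texture + rectilinear
  high-contrast rectangles, stretched to the full 0–255 range; *blurred
  scenes* halve contrast about the mean and then blur with a σ = 3 px
  Gaussian (contrast first, then blur). Six further background kinds:
  uniform mid-gray 128, uniform gray matched to the foreground's opaque
  mean, 1/f random-phase noise (mean 128, RMS contrast 41.5 — a
  calibration, chosen to match the stimulus sets' average RMS contrast, as
  the noise contrast is otherwise unspecified), and 4 × 4 px block noise
  with uniform, binary, or foreground-sampled luminances.

What the generator does **not** emulate: photographic texture statistics,
within-class identity structure (hair, species, object categories),
occlusion, lighting direction consistency, or label noise. Passing tests
show that the pipeline recovers the *structural* results — model ordering,
graded degradation with nuisance variation, lesion patterns — under
controlled class statistics; they do not certify photographic accuracy
levels.

## Composition and nuisance transforms

A presentation scales the foreground isotropically (uniform in
[scale_min, 1]; isotropic preserves aspect ratio as in the set
preprocessing), rotates it about its own center (uniform ±rot_max,
clockwise positive), then composites it at the canvas center plus an
integer jitter uniform in ±42 px per axis. Both luminance and alpha are
warped bilinearly in one affine map directly into the 340 × 340 frame
(avoiding corner clipping for elongated shapes at 45°), and alpha is
re-thresholded at 0.5, so pixels outside the support show the background
exactly. Jitter that would push any opaque pixel off canvas is clamped
(using the transformed source bounding box, a conservative over-bound)
rather than wrapped, which would create artificial edges.

## Training protocol

Readout: single linear layer, face = 1 iff logit > 0; Kaiming-uniform
init (bound √(6/fan-in) — the linear-gain variant, as the exact gain is a
free choice), zero bias; binary cross-entropy with logits; SGD with
classical momentum (v ← μv − η∇, w ← w + v), learning rate 0.01, momentum
0.9, batch 64, shuffled. Face task: 50/50 split per class (odd counts put
the extra image in training), 1,500 presentations per class resampled with
replacement per run, 10 epochs with augmentation redrawn every epoch, test
on 1,500 fresh resamples from the held-out half; 100 runs by default,
summarized by the median. Gender task: 50/10/40 split, 400 resampled per
class, fixed 80 + 80 validation set, up to 40 epochs with early stopping
after 5 consecutive epochs without validation improvement, best-epoch head
returned. Evaluation transforms are drawn from the same condition ranges
as training, once per evaluation.

d′ = Z(hit) − Z(false alarm), or 2 Z(hit) in the symmetric shortcut; rates
of exactly 0 or 1 are mapped to the rate corresponding to the cap, and d′
is clipped at ±5.15 (99.5% correct).

## Lesions and probing

Channel lesions remove (or keep only) whole frequency channels; consistency
lesions score each unit by max(#positive, #negative) final-weight signs
across the full model's runs and keep/remove units at a threshold; both
retrain the readout. Zero weights count toward neither sign (measure-zero
under SGD). Consistency is computed per condition from final weights only.
The probing harness attaches an independently trained head to each stage of
any staged feature extractor; the five-conv reference stack's per-stage
input sizes are computed by exact convolution arithmetic
(⌊(n + 2p − k)/s⌋ + 1), needing no weights.

## Desk-scale benchmark

`earlyvis.benchmark.run_benchmark` fixes the problem sizes used by the
acceptance checks: 200 synthetic images per class (vs ~900 photographic),
10 runs per condition (vs 100), and the protocol's own 1,500 resampled
presentations per class and 10 epochs. Per-presentation composition is
replaced by a precomputed pool of K = 6 independently augmented,
featurized variants per base image; presentations sample (image, variant)
pairs, so training cost collapses to readout updates while per-presentation
stimulus statistics are preserved up to pool granularity. The hard
condition is the lesion-analysis condition (scale down to 50%, rotation
±45°, blurred-scene background); it drives the model comparison and the
lesions. The rotation sweep (0/45/180° on mid-gray) drives the degradation
check; the consistency threshold is 9 of 10 runs, the analogue of a 90%
criterion. At these sizes the keep-only consistency lesion reliably
*exceeds* the full model by ~4 points (with smaller inter-run spread):
pruning noise-dominated units buys more at 200 images per class than it
would at photographic set sizes, so the "within 3 points of the full
model" reading of equivalence is borderline at desk scale even though the
direction (as good or better, tighter spread) is stable.

## Numerical choices and edge cases

* Filtering uses exact inner products at grid positions (no FFT); batched
  float32 matmuls for training paths (~1e−5 relative error), float64
  elsewhere.
* All randomness flows from one master seed through named, CRC32-keyed
  substreams (split, resample, transform, background, init, order), so any
  component is reproducible in isolation and reruns are bit-identical.
* Degenerate inputs fail loudly: empty alpha masks, empty classes, dropping
  all four channels, lesions with no survivors, empty validation sets,
  non-finite training gradients.
* Uniform images are fixed points of scene degradation; constant images
  produce exactly zero activations in every variant (zero-DC kernels).
* Oversize-channel kernels are re-zero-DC'd and renormalized after
  cropping, per location.

## Known limitations

* The readout is the only trained component; no divisive normalization,
  surround suppression, or temporal dynamics.
* The pooled-feature training mode caps augmentation diversity at K
  variants per image; at K = 4 this slightly favors memorization relative
  to fresh composition, equally across model variants.
* Synthetic class statistics are calibrated at the set level, not per
  image; absolute accuracies are not comparable to photographic-set
  results, only orderings and differences are interpreted.
* The λ = 256 channel's placement convention is constrained only by its
  published unit count; other conventions with the same count would differ
  in edge coverage.
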