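# Methods

## The problem being modeled

A time-stretch imaging flow cytometer maps each broadband laser pulse onto
a one-dimensional line scan of the microfluidic channel: the spatial
profile across the ~25 µm field of view is encoded into the pulse
spectrum, dispersion maps spectrum to time, and a single fast
photodetector plus ADC records everything as one continuous waveform.
Cells flowing at ~1.3 m/s are each imaged by hundreds of consecutive
pulses (at 36.6 MHz repetition and 2.5 µm optical resolution, ~70 pulses
fall within one resolution distance — a large redundancy).  The package
classifies fixed-length windows of this waveform directly into SW-480
(epithelial cancer), OT-II (T lymphocyte) or blank, without reconstructing
images, so that the decision can reach a droplet sorter in time.

## Synthetic waveform model

No public waveform dataset exists for this instrument class, so the
simulator defines the study conditions.  It emulates the signal chain at
the waveform level:

* **Pulse train** — a raised-cosine envelope repeated every
  `round(sampling_rate / repetition_rate)` samples, with a random start
  phase per waveform.  The envelope is smooth, band-limited and trivially
  testable; the instrument's exact pulse shape is irrelevant to the
  classification task.
* **Cell imprint** — a cell multiplies the pulses it overlaps by
  `1 − contrast · g(x) · texture(s)`.  `g` is the cell's top-hat profile
  (diameter d) convolved with the optical-resolution Gaussian, in closed
  form via erf, with the FWHM-to-sigma conversion
  σ = resolution / (2√(2 ln 2)); it is clipped to exactly zero beyond
  d/2 + 4σ so that locality is exact and testable.  `texture` is a cosine
  along the intra-pulse (spectral/spatial) axis with a class-specific
  wavelength, standing in for internal morphology.  Phase/interferometric
  encoding, dispersion and amplification are deliberately not modeled:
  classes need only be statistically separable through the same
  1-D-to-2-D mapping the classifier consumes.
* **Classes** — SW-480-like: diameter 15 ± 1.5 µm, modulation depth
  0.55 ± 0.05, texture wavelength 5 µm; OT-II-like: 9 ± 1 µm, 0.30 ± 0.04,
  2.5 µm; blank: no cell.  The size and contrast ordering reflects the
  biology (epithelial cancer cells are larger and optically denser than
  T cells); the values themselves are chosen so that a small network can
  separate the classes — the generator validates the pipeline, it does not
  reproduce real-instrument difficulty.
* **Noise** — i.i.d. additive Gaussian, default sd 0.02 of the unit
  envelope peak (high-contrast, low-noise conditions).  Real detectors add
  structured noise (Raman amplification ripple, ADC quantization, baseline
  drift) that this model omits; passing tests therefore demonstrate
  pipeline correctness, not robustness to real-instrument artifacts.
* **Cohorts** — per waveform, the number of cells targets a blank-element
  fraction of 1/3 (with 50 % window overlap a cell center lands in ~2
  windows, so `n_cells = (1 − blank_fraction) · n_elements · (1 − overlap)`),
  class labels drawn 50/50, positions uniform with a minimum separation of
  one cell diameter (closer placements are rejected).

### Scaled preset

The full instrument scale (1366 samples per pulse, ~800 pulses per
element) produces ~55M-sample waveforms — correct but pointlessly heavy
for validation.  `SimConfig.scaled()` preserves the geometric ratios
while shrinking the arithmetic: 32 samples per pulse (lower ADC rate),
flow sped up 10× so ~7 pulses cover one resolution distance instead of
~70, 64-pulse elements, and a pulse-reduction factor of 4 (the same
~0.57 ratio of reduction factor to pulse redundancy as the full-scale
40 / 70.4).  All training-based tests and the acceptance experiment run
at this scale: 20 waveforms → 2000 elements of 16 × 32 pixels,
1600/200/200 split — about a minute of training on one CPU core.

## Data preparation choices

* Window length solves `L (n + (1 − n)·overlap) = T` (so 2/101 of the
  waveform at the default n = 100, overlap = 0.5); non-integer lengths are
  floored, starts are spread evenly, and the last window is anchored to
  the waveform end so coverage is preserved.
* Each window is trimmed to start at the next pulse boundary and to end
  on a whole pulse, then reshaped row-major to (pulses × samples/pulse).
  Because the random start phase can cost up to one pulse, all elements
  of a cohort are cropped to a common row count (nominal pulses − 1)
  before stacking.
* Pulse reduction keeps rows 0, f, 2f, … (first-of-group phase; the
  redundancy argument makes the retained phase immaterial).
  Reduction precedes normalization.
* Standardization is a per-element z-score (constant elements map to
  zeros).  Input scaling is otherwise unconstrained by the problem; the
  z-score stabilizes training and is switchable.
* Element labels: the class of the annotated cell center inside the
  window, nearest the midpoint on conflicts (earlier center on exact
  ties); blank when none.
* The default split shuffles elements, not waveforms, before the 80/10/10
  partition.  Overlapping windows of one waveform can therefore land in
  different splits — an information leak inherent to element-level
  splitting.  On the synthetic cohorts this inflates validation scores
  only marginally (classes are separable anyway), but callers can split
  at the waveform level by preparing per-waveform datasets.

## Network and training choices

* Block structure (4×16 → pool → 6×32 → pool → 6×64 → pool at defaults)
  is one concrete reading of "16 conv layers, 3 pools, channels 16→64";
  it follows the VGG doubling pattern and is fully configurable.
* Convolutions use "same" padding (only pools downsample); pool stride =
  window = 2, with odd trailing rows/columns cropped.
* L2 penalizes convolution and FC weights but not biases (standard
  practice; `include_biases=True` switches to penalizing everything).
* Dropout uses inverted scaling so eval mode is a true identity; it sits
  after the two hidden FC layers only.
* Initialization: He-scaled normals for weights, zero biases.
* Adam defaults: learning rate 1e-4 for the full-scale model (the scaled
  preset uses 1e-3 — small model, clean data, few epochs), β₁ = 0.9,
  β₂ = 0.999, ε = 1e-8, batch 64.  No early stopping; the epoch budget is
  explicit everywhere.
* The epoch's train metrics are running averages over its batches (the
  parameters move during the epoch); validation is evaluated once per
  epoch in eval mode.
* Non-finite loss aborts with a diagnostic; the random search records
  such trials as infinite validation loss and continues.
* All stochastic components (init, shuffles, dropout) draw from seeds
  derived via `numpy.random.SeedSequence`, so every run is exactly
  reproducible and stages are independently reproducible.

## Metric conventions

* 0/0 precision or recall → 0, with a degenerate-class flag.
* Balanced accuracy is reported as the mean of per-class recalls
  (multiclass form); the binary form (mean of sensitivity and
  specificity) backs the iso-BACC contours.
* ROC areas are trapezoidal, which equals the probability that a random
  positive outranks a random negative with ties counted ½ (property-tested
  against brute-force pair enumeration).  PR areas use step-wise
  interpolation in recall, avoiding the optimistic bias of linear
  interpolation; a switch is not provided because the step form is the one
  the tests pin down.
* Threshold sweeps use the unique scores in descending order with ties
  grouped.
* Micro averaging pools (example, class) pairs; macro averages the class
  curves on the union grid.  The **macro area is the mean of the class
  areas** (the standard definition, matching scikit-learn's one-vs-rest
  macro AUC); the interpolated mean curve is for plotting and its own
  integral can differ slightly wherever a class curve has vertical
  segments.

## Regularization search

L2 is sampled log-uniformly: plausible multipliers span four decades
(1e-4 … 1), where a linear-uniform draw would almost never produce values
below 0.1; a linear mode remains available.  The fine stage contracts to
one decade of L2 (×/÷ √10) and ±20 percentage points of keep probability
around the coarse optimum, clipped to the coarse bounds.  Every trial
trains its full epoch budget; the winner is the argmin of final-epoch
validation cross-entropy over all 24 trials.

## Sorting feasibility

Travel distance is the pure product latency × flow speed (reported
rounded to 0.1 mm); the minimum channel length multiplies in a safety
margin.  The charge map is total over the three classes; exact argmax
ties resolve to blank — no charge, i.e. the cell goes to waste rather
than into a collection tube, the conservative failure mode.  Latency
measurement excludes warm-up runs and reports mean per-example wall-clock
time per batch size; absolute values are hardware-dependent and never
asserted.

## Known limitations

* The simulator's amplitude-only, separable modulation model cannot probe
  phase-sensitive features; conclusions transfer to real instruments only
  at the pipeline-correctness level.
* The real sampling-to-repetition ratio is slightly non-integer
  (≈1366.12); the simulator forces an integer pulse period.  Handling
  fractional pulse drift in recorded data would require a boundary-tracking
  step the package does not implement.
* Element-level splitting leaks overlap between splits (see above).
* The numpy network is single-threaded-friendly but not fast; it is meant
  for correctness and small-scale experiments, not production inference.
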