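# Methods

## Problem and data model

An interictal epileptiform discharge (IED) is a transient — spike (~20–70 ms)
or sharp wave (~70–200 ms), usually followed by a slow wave — visible in
scalp EEG between seizures. In focal epilepsy the scalp region expressing the
discharges (frontal, temporal, occipital) carries diagnostic information, so
the package models two tasks on 1.5-s EEG epochs: *detection* (binary
IED/non-IED per region) and *localization* (three- or four-class including
non-IED).

A recording is a 19-channel signal in µV at a nominal 200 Hz, channels fixed
in the canonical 10–20 order `Fp1, Fp2, F3, F4, C3, C4, P3, P4, O1, O2, F7,
F8, T3, T4, T5, T6, Fz, Cz, Pz`. This order is a single source of truth: the
2D network's row semantics, the EDF writer, and every epoch tensor use it.
Annotations are half-open intervals `[onset_s, offset_s)` with a region
label; an event's *center* is its midpoint. Times are seconds from recording
start; sample windows are computed as `round((center − 0.75) · fs)` with
half-open extents, ties broken toward the earlier sample.

The package's defaults are anchored to a reference clinical cohort of 38
focal-epilepsy patients (15 frontal / 13 temporal / 10 occipital) and 232
controls with ≥30-min recordings: per-region IED totals 2112/1176/1269
(means 141/90/127 per recording), mean discharge durations 0.45/0.52/0.48 s.
Those counts live in `focalspike.cohort_reference`; all derived rates, means
and SDs are recomputed from them at run time.

## Synthetic cohort simulator

The clinical recordings behind the reference cohort are not distributable,
so `focalspike.synth` generates cohorts with the statistical structure the
pipeline assumes:

* **Background**: per-channel independent pink (1/f) Gaussian noise plus a
  shared common-mode pink term (40 % of the RMS) so average referencing is
  non-trivial; default RMS 15 µV. A waxing-and-waning ~10 Hz rhythm
  (frequency N(10, 0.3) Hz, default peak 20 µV) is added with posterior
  weights (O1/O2 = 1, P3/P4 = 0.6, …), emulating the awake-resting posterior
  alpha rhythm.
* **Discharges**: a biphasic Mexican-hat spike (duration sampled uniformly
  in 0.04–0.12 s) followed by an opposite-polarity half-sine slow wave; total
  duration clipped-normal around the region's configured mean (SD 0.1 s,
  clipped to [0.2, 1.2] s). The waveform is negative at the focus, as for
  surface-negative epileptiform potentials, with peak amplitude 100 µV by
  default (~6× background RMS). Only duration statistics of real discharges
  are published; the shape itself is a phenomenological choice matching the
  clinical spike/sharp-wave convention, not a biophysical (dipole/head-model)
  simulation.
* **Topography**: each region scales the template per channel — weight 1 at
  the peak electrodes (Fp1/Fp2, T3/T4, O1/O2), 0.7 over the rest of the
  region's electrode group, 0.1 far-field leakage elsewhere (kept ≤ 0.3 so
  discharges remain focal).
* **Placement**: uniform rejection sampling with a minimum inter-event gap
  (default 1 s); every event lies fully inside `[0.75 s, T − 0.75 s]` so each
  discharge can center a complete epoch. Infeasible requests raise a capacity
  error naming the approximate maximum that fits.
* **Counts**: per-patient IED counts are Poisson around the configured
  region mean, clipped ≥ 1. The reference cohort's dispersion is much larger
  than Poisson, but the per-patient distribution is unidentifiable from the
  published summaries; Poisson is the simplest reproducible choice.
* **Eye blinks**: positive raised-cosine transients of 0.2–0.4 s, 150 µV at
  Fp1/Fp2 with a steep frontal falloff, arriving as a Poisson process. The
  default cohort blink rate is 0 so the confound is an explicit, controlled
  manipulation (the confound experiment adds 10/min to every recording).

Every generator is a pure function of its configuration and seed
(`numpy.random.SeedSequence` spawning, one child per subject and stage).

**What the simulator does not emulate** — and hence what passing tests do
*not* show about clinical data: real electrode artifacts (movement, EMG,
electrode pops), sleep architecture, age- and syndrome-dependent IED
morphology and background variation, normal variants that mimic IEDs (wicket
waves, sharply contoured alpha), volume-conduction physics, and the
inter-patient variability that dominates real detection-rate spreads.
High-SNR synthetic results are a correctness check of the pipeline, not a
claim about clinical accuracy.

## Signal conditioning

Resample (polyphase) to 200 Hz → common average reference → band-pass
1–70 Hz. The filter is a 4th-order Butterworth applied forward–backward
(zero phase) so the discharge peak — and with it the epoch center — is not
delayed; scipy's reflect padding handles the edges. Whether a causal or
zero-phase filter was used in the original acquisition chain is unknowable
from published information; zero-phase is the choice here and is applied
identically everywhere. A 60 Hz notch is available but off by default
(synthetic data has no mains hum; clinical recorders typically notch at
acquisition).

## Epoching

One 19 × 300 epoch per annotation, centered on the annotation midpoint
(events whose window does not fit are skipped with a warning). Augmentation
draws `augment_factor − 1` additional integer-sample shifts uniformly from
±10 samples (±50 ms at 200 Hz), always retaining the unjittered copy, so the
augmented count is exactly `events × factor`. Spike-peak-based centering is
not implemented; midpoint centering is used uniformly. Non-IED epochs are
sampled without replacement from all window start positions whose 1.5-s
window is disjoint from every discharge's epoch window. Binary datasets are
balanced 1:1 by undersampling the non-IED pool; multiclass datasets are
undersampled to the smallest class.

Splits are stratified 6:2:2. The default split unit is the *source event*:
all jittered copies of a discharge stay in one split, preventing
near-duplicate leakage across train/test. Epoch-level splitting (the literal
protocol of training pipelines that split after augmentation) is available
via `split_unit="epoch"`.

## Networks and training

Both variants consume 19 × 300 epochs and share three blocks of
convolution → batch normalization → ReLU → max pooling (pool sizes 3, 2, 1,
stride 2; the pool-1 block is literal stride-2 subsampling), then flatten and
a dense softmax head. With valid padding the time axis evolves
300 → 295 → 147 → 142 → 71 → 66 → 33, giving flattened widths 64·33 = 2112
(`cnn1d`) and 19·32·33 = 20 064 (`cnn2d`). The 1D variant mixes all channels
in its first kernel (19 × 6); the 2D variant applies 1 × 6 kernels per
channel row, preserving the channel dimension to the flatten layer. The
binary head is a 2-unit softmax with categorical cross-entropy, and the
binary ROC score is the softmax probability of the discharge class.

Design points that were genuinely open and are fixed here: valid padding;
ReLU as the hidden nonlinearity accompanying batch norm; batch-norm placement
conv → BN → activation with running statistics at inference (momentum 0.9,
ε 1e-5); a single flatten → dense(n_classes) head; no dropout or weight
decay; variance-scaling uniform weight initialization, seeded.

Training: RMSprop (ρ 0.9, ε 1e-7), default learning rate 1e-5, batch size
64, up to 300 epochs, per-epoch shuffling seeded; the weights of the
highest-validation-accuracy epoch are restored (earliest epoch on ties), and
all reported test metrics come from those checkpointed weights. Non-finite
loss raises a divergence error naming the epoch.

The machinery (`focalspike.nn`) is a compact numpy implementation —
convolution as one GEMM per layer over an im2col matrix in `(C·K, B·L)`
orientation, explicit backward passes, gradient-checked against central
differences. Everything is float32 and bit-reproducible for fixed seeds on a
single CPU.

## Evaluation

Percentages are computed in double precision on a 0–100 scale; one-decimal
rounding is display-only. AUC is the trapezoidal area under the ROC, which
equals pairwise concordance with ties counted ½ (Mann–Whitney); the test
suite verifies this against exhaustive pair enumeration. Precision of a
never-predicted class is reported as 0 and flagged so F1 stays defined.
Confusion matrices are always in (frontal, temporal, occipital, non-IED)
order, rows = true. The per-patient detection rate equals the recall of the
patient's true class restricted to that patient's epochs.

Leave-one-patient-out cross-validation builds one fold per patient: the
held-out patient contributes no epochs (original or jittered) to that fold's
training or validation; control-derived non-IED epochs are split
train/validation within each fold; every fold records the (required-zero)
intersection of held-out and training epoch identifiers. At least two
patients per included class are required so every fold retains all classes.

t-SNE uses scikit-learn with 2 components, perplexity 30, early exaggeration
12, PCA initialization and a fixed random state; per-class subsampling to
≤1000 points is available for plotting.

## Scaled validation experiments

`focalspike.experiments` runs the whole loop at desk scale on one CPU; the
sizes below are the package's chosen study conditions for these checks.

* **High-SNR learning** (`ScaledDesign` defaults): 120-s recordings, 12
  IEDs/patient, amplitude 100 µV over 15 µV background, augmentation ×3,
  30 training epochs at learning rate 1e-3 (the step is raised because the
  scaled runs take ~10² minibatch updates instead of ~10⁵; the default
  TrainSpec keeps 1e-5). Occipital binary: 8 patients + 8 controls. Three
  class: 4 temporal + 4 occipital + 8 controls.
* **Blink confound contrast**: 6 patients + 6 controls per region, amplitude
  60 µV (moderate SNR so the detectors are off ceiling), 15 training epochs;
  per seed, four paired runs (frontal/occipital × without/with 10 blinks
  per minute added to every recording). Expected direction: the frontal
  detector loses more accuracy than the occipital one, because blink
  artifacts and frontal discharges occupy the same electrodes.
* **LOPO harness**: 3 temporal + 3 occipital patients + 4 controls, 10
  training epochs per fold, 1D variant (chosen for CPU thrift; the harness
  itself is variant-agnostic).

## Known limitations

* The numpy networks are CPU-bound; the 2D variant is several times slower
  than the 1D variant at equal batch size (its intermediate tensors are ~19×
  larger), so the scaled experiments train the 1D variant.
* The simulator's separability is optimistic; absolute accuracies on
  synthetic data do not transfer to clinical recordings.
* EDF writing pads the final one-second data record with zeros; the true
  sample count is recorded in the header's recording-id field and used to
  trim on read. Round trips are lossless only up to 16-bit quantization of
  the per-channel physical range.
* Only the three modeled regions are supported in annotations; multifocal
  and generalized discharge patterns are out of scope.
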