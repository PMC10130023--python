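# focalspike

Detection and localization of **focal interictal epileptiform discharges
(IEDs)** — the spikes, sharp waves and spike/sharp-wave complexes that mark
epilepsy between seizures — in 19-channel scalp EEG, together with a synthetic
cohort simulator so the entire pipeline can be built, trained and tested
without access to clinical recordings.

The package is aimed at clinical-neurophysiology and biosignal-ML researchers
who want a reproducible, end-to-end reference implementation of
region-specific IED classification: binary detectors for frontal, temporal and
occipital discharges, and three-/four-class models that localize a discharge
to its scalp region.

## The pipeline

1. **Simulation** (`focalspike.synth`) — annotated cohorts of 19-channel
   200 Hz recordings: pink (1/f) background with a posterior alpha rhythm,
   biphasic spike + slow-wave discharges injected with a focal scalp
   topography (negative at the focus), optional frontal eye-blink artifacts,
   and IED-free controls.
2. **I/O** (`focalspike.io`) — EDF signals (16-bit, µV) and TSV annotation
   tables (`subject_id, region, onset_s, offset_s`), normalized to the fixed
   10–20 montage `Fp1 … Pz` (T7/T8/P7/P8 aliases accepted).
3. **Conditioning** (`focalspike.preprocess`) — resample to 200 Hz → common
   average reference over the 19 channels → zero-phase 1–70 Hz band-pass
   (4th-order Butterworth, forward–backward).
4. **Epoching** (`focalspike.epoching`) — 1.5-s epochs (19 × 300 samples)
   centered on each annotated discharge; augmentation by random center jitter
   in ±50 ms (±10 samples, unjittered copy retained); non-IED epochs cut at
   random time points outside every discharge window; 1:1 class balancing by
   undersampling; stratified 6:2:2 train/validation/test splits (by source
   event, so jittered near-duplicates never straddle a split).
5. **Classification** (`focalspike.cnn`, `focalspike.nn`) — two CNN variants
   over the 19 × 300 input:
   * `cnn1d`: kernels span all 19 channels × 6 time samples; 64/128/64 filters,
   * `cnn2d`: 1 × 6 kernels slide over each channel row independently;
     32/64/32 filters,

   each as three blocks of convolution → batch norm → ReLU → max pool
   (pool 3/2/1, stride 2), then flatten (2112 features for `cnn1d`, 20 064 for
   `cnn2d`) and a softmax head of 2/3/4 classes. Training uses categorical
   cross-entropy with RMSprop, batch size 64, checkpointing the
   highest-validation-accuracy epoch. The network machinery is a compact,
   fully seeded numpy implementation written for single-CPU reproducibility.
6. **Evaluation** (`focalspike.evaluation`) — sensitivity/specificity/accuracy
   and trapezoidal ROC AUC for binary models; per-class precision/recall/F1
   with confusion matrices in the fixed (frontal, temporal, occipital,
   non-IED) order; per-patient **detection rate** (fraction of a patient's
   discharge epochs classified as their true region) under
   leave-one-patient-out cross-validation; t-SNE embedding of flattened-layer
   features (perplexity 30, early exaggeration 12).

## Worked example

```python
from focalspike.experiments import run_binary_experiment

result = run_binary_experiment("occipital", seed=1)
print({k: round(v, 1) for k, v in result.items()})
```

This simulates a fresh cohort of 8 occipital-IED patients and 8 controls
(120-s recordings, spike amplitude ≈ 6× the background RMS), conditions it,
builds a balanced jitter-augmented epoch dataset, trains the 1D CNN for 30
epochs, and scores the held-out test split. Output from the run above:

```
{'accuracy': 98.1, 'auc': 100.0, 'sensitivity': 98.1, 'specificity': 98.1,
 'n_test_epochs': 106, 'best_epoch': 8.0}
```

i.e. 98.1 % of the 106 test epochs were classified correctly and the ROC area
rounds to 100 % — on high-SNR synthetic data this task should be (and is)
close to ceiling. A command-line interface mirrors the stages:

```bash
focalspike simulate --out cohort/ --seed 3
focalspike run --config experiment.yaml --seed 1 --out runs/demo
```

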