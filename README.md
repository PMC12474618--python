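# eitbp — beat-by-beat aortic blood pressure from raw EIT voltages

Electrical impedance tomography (EIT) measures voltages on a belt of
thoracic electrodes while small currents are driven through them. The
cyclic redistribution of blood with every heartbeat leaves a pressure-
dependent signature in those raw voltages — pulse-wave propagation speeds
up at higher pressures and the pulse volume scales with pulse pressure —
so the raw 1024-value voltage frames (47.68 Hz) carry information about
aortic pressure without any image reconstruction.

`eitbp` implements a complete pipeline that turns such recordings into
beat-by-beat estimates of systolic, mean and diastolic aortic pressure
(SAP/MAP/DAP), evaluated the way method-comparison studies in hemodynamic
monitoring are evaluated. It is aimed at researchers in physiological
signal processing who want a fully testable, end-to-end reference
implementation: because no paired EIT/pressure animal dataset is publicly
available, the package ships a first-class synthetic-data module with
known per-beat ground truth, and every downstream stage is validated
against it.

## Pipeline

1. **Simulation** (`eitbp.synthdata`) — paired recordings per subject:
   a beat-templated 1 kHz aortic pressure waveform (raised-cosine systolic
   upstroke, exponential-like diastolic decay; per-beat extrema *are* the
   ground-truth labels), EIT frames with per-channel DC offsets, a ~0.3 Hz
   ventilation component, a cardiac component coupled to pressure in
   amplitude and arrival time, sensor noise, a drifting high-fidelity
   catheter channel, a beat-sparse fluid-filled reference, a 1 kHz timing
   pulse channel, and hemodynamic event schedules (vasoconstrictor-,
   hypoxia- and hemorrhage-like).
2. **Ingest** (`eitbp.ingest`) — HDF5 bundle I/O, frame-to-physiology
   synchronization via the rising edges of the timing channel (1 ms
   accuracy), and per-segment recalibration of the drifting trace against
   the fluid-filled diastolic reference.
3. **Beat segmentation** (`eitbp.beatseg`) — heart rate is detected from
   the EIT signal alone: per-channel DC removal, channel mean, a Fourier
   synchrosqueezing transform (STFT energy reassigned to instantaneous-
   frequency estimates), constrained ridge tracking in the cardiac band,
   and beat boundaries at 2π crossings of the integrated cardiac phase,
   anchored on the systolic upstroke. Premature beats and beats longer
   than 64 frames are excluded.
4. **Preprocessing** (`eitbp.preprocess`) — per beat: SAP/MAP/DAP labels
   from the recalibrated pressure (SAP = beat maximum, DAP = onset
   minimum, MAP = arithmetic mean between bounding minima), block-wise
   z-score of the unpadded block, zero-padding to 64×1024, and 0–1 label
   normalization with training-split bounds.
5. **Model** (`eitbp.model`, `eitbp.nn`) — a compact funnel CNN (kernel
   12, filters 8→4→2, batch normalization, flatten + dense(3)) trained
   with MSE, batch size 100, early stopping (patience 5), evaluated by
   leave-one-subject-out (LOSO) cross-validation; hyperparameter search
   ranks candidates by pooled MAP ICC. The network engine is pure numpy
   with explicit backprop, fully seeded.
6. **Agreement** (`eitbp.agreement`) — ICC(3,1) with absolute agreement
   (two-way ANOVA single-measure form) with Koo categories, Bland–Altman
   for repeated measurements, 4-quadrant trending concordance with a
   10 %-of-maximal-systolic-change exclusion zone, and five-zone
   clinical-risk error grids (A–E) for SAP and MAP.

## Worked example

```bash
cat > demo.yaml <<'YAML'
simulation:
  n_subjects: 4
  base_duration_s: 120.0
model:
  conv_rank: 1d
  strides: [[8, 8], [1, 1], [1, 1]]
  learning_rate: 0.003
  epochs: 10
  batch_size: 50
YAML
eitbp run --config demo.yaml --seed 7 --out demo_out
```

prints (about 1–2 minutes on one CPU):

```
SAP: ICC 0.740 (moderate), bias -3.79 mmHg, LoA [-36.4, 28.8], concordance 53.7%
MAP: ICC 0.744 (moderate), bias -3.09 mmHg, LoA [-30.3, 24.1], concordance 55.7%
DAP: ICC 0.740 (moderate), bias -2.20 mmHg, LoA [-23.1, 18.7], concordance 51.6%
```

Each line summarizes the pooled held-out predictions of the LOSO folds:
the intraclass correlation between estimated and reference pressures
(absolute agreement, so offsets count against it), the mean bias and the
95 % limits of agreement of the beat-wise differences, and the fraction of
consecutive beat-to-beat changes in which estimate and reference move in
the same direction. `demo_out/` additionally contains the density-coded
scatter plots, risk-zone histograms, the per-stage JSON log and the
simulated bundle. The library API mirrors the CLI; see
`eitbp.pipeline.run_pipeline` and `eitbp.study.run_reference_study`.

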