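# Methods

This note documents the models, algorithms, parameters and design
decisions behind `eitbp`, and what its synthetic-data results do and do
not demonstrate.

## Problem setting

The target is beat-by-beat estimation of systolic, mean and diastolic
aortic pressure (SAP/MAP/DAP, mmHg) from raw EIT voltage frames —
1024 values per frame at 47.68 Hz from a 32-electrode thoracic belt —
without image reconstruction. The physiological carrier is the cardiac
component of the thoracic impedance signal: its amplitude scales with
pulse volume (hence pulse pressure) and its arrival time shifts with
pressure-dependent pulse-wave velocity. A reference pressure is measured
invasively at 1 kHz by a high-fidelity intravascular sensor that drifts
over time and must be re-anchored to a stable fluid-filled catheter.
Evaluation is strictly leave-one-subject-out: the model never sees any
beat of the subject it is tested on.

## Synthetic cohort

No paired EIT/pressure dataset is publicly deposited, so the package
generates its own cohorts with known per-beat ground truth
(`eitbp.synthdata`). The generator is first-class, tested code; its
defaults define the reference study conditions.

**Pressure waveform.** Each beat is a template: a raised-cosine upstroke
from DAP to SAP occupying 30 % of the beat, then a normalized exponential
decay back to DAP (exactly DAP at the next onset). The decay constant is
solved per beat (bisection) so that the beat's sample mean equals the MAP
target; the achievable MAP fraction of pulse pressure is (0.17, 0.48) and
targets are clamped into it. Recorded ground truth is read back from the
generated waveform, so extrema and means are exact by construction.
Recordings cut off mid-beat (a truncated final template) as real ones do.

**Hemodynamics.** Subject baselines: HR 86–96 /min, DAP 72±3, pulse
pressure 46±4, MAP at 0.42±0.02 of pulse pressure above DAP (anesthetized
pig ranges). Three episodes per recording emulate intervention
consequences as pressure trajectories only: MAP deltas of +30, −35 and
+15 mmHg (SD 5; SAP and DAP scale by 1.25 and 0.8) over windows at
12–32 %, 42–62 % and 72–92 % of the record with 8 s ramps, in
subject-randomized order. Heart rate follows a baroreflex-like coupling
of −0.45 beats·min⁻¹ per mmHg of MAP; the slope is deliberately blunted
(anesthesia) so HR stays above ~64 /min and inside the default cardiac
analysis band — tracking a fundamental that leaves the band is a known
failure mode of band-limited ridge tracking. Per-beat variability: 2 %
fractional HR jitter and an AR(1) (ρ = 0.9, SD 1.5 mmHg) pressure
wander.

**EIT frames.** Frame values are
`dc + resp_gain·sin(2π·f_r·t) + cardiac_gain·w(t − delay) + noise` with
`w` the 1 s-moving-average-removed pressure waveform in mmHg. Per-channel
DC offsets (SD 0.5 V) dominate the raw signal; respiration
(f_r = 0.28–0.34 Hz, gain ~4·10⁻³ V) dominates the dynamic signal; the
cardiac component lives on 64 of 1024 channels (gain 2·10⁻⁴ V/mmHg with a
cohort-wide pattern scaled ±8 % per subject) and white sensor noise has
SD 2·10⁻³ V per channel per frame. The pulse-arrival delay is
`30 ms − 0.4 ms/mmHg · (MAP − 90)`, floored at 5 ms: higher pressure,
earlier arrival. Both the amplitude and the timing of the cardiac
component therefore carry pressure information. The cohort-wide gain
pattern (not per-subject random) is what makes cross-subject
generalization possible at all; with fully subject-specific gain patterns
LOSO performance collapses, which is a faithful miniature of the real
generalization problem.

**Reference channels.** The "Millar-like" trace is the true pressure plus
a linear drift (±3 mmHg/min per subject) and smoothed noise (SD
0.3 mmHg); the fluid-filled reference keeps only per-beat onset times and
DAP values with 1 mmHg jitter. A 1 kHz timing channel carries one 8 ms
pulse per EIT frame, on-grid within half a sample. Recordings are split
into three measuring segments (manual trigger marks).

**Seeding.** One master seed; per-subject streams derive from
`SeedSequence(master, crc32(subject_id))`, so cohorts are bit-identical
across processes and insensitive to subject order.

## Ingest

Rising edges are detected at 50 % of the sync channel's range; a count
mismatch with the frame count aborts (no guessed alignment), otherwise
frame *i* gets the time of edge *i* — accuracy is the 1 kHz resolution.
Recalibration estimates one constant offset per measuring segment as the
mean difference between reference DAP and the trace's local minimum
within ±150 ms of each reference beat onset; constant offsets leave pulse
pressure untouched, and the residual error under a linear drift is
bounded by half the within-segment drift. Whether the original correction
was per animal, per sequence or continuous is not documented anywhere we
could rely on; per-segment constants are this package's choice.

## Beat segmentation (EIT only)

The pressure channel is never consulted for segmentation; it only
supplies labels.

1. **Global signal:** per-channel subtraction of a sliding 10 s mean
   (DC/baseline removal), then the mean over all 1024 channels.
2. **FSST:** STFT with a 256-frame (~5.4 s) Hann window, hop 1, computed
   with the window `g` and its derivative `g'`; per bin the instantaneous
   frequency is `ω = f − Im(V_g′/V_g)/2π` and the bin's magnitude is
   reassigned to the nearest bin of ω (magnitude floor 10⁻⁸ of the column
   maximum). The magnitude-weighted mean of ω per reassigned bin is kept,
   giving sub-bin frequency resolution (a pure tone concentrates > 99.9 %
   of column energy within ±1 bin; a 1→2 Hz chirp is tracked to within
   0.002 Hz away from the record edges).
3. **Ridge tracking:** greedy forward pass in the cardiac band
   (default 1–4 Hz, 60–240 /min) constrained to ±0.1 Hz per step.
   Initialization maximizes a harmonic-aware score (candidate magnitude
   plus 0.7× its first harmonic) over a window that starts past the
   edge-biased first half-window of columns; without both measures the
   tracker occasionally locks onto the first cardiac harmonic. Quality is
   ridge magnitude over in-band magnitude; columns are unreliable when
   quality < 0.05 or the in-band share of total magnitude < 1 %.
4. **Boundaries:** cardiac phase φ = 2π∫hr dt (trapezoid; HR held
   constant over the half-window edge regions), boundaries at 2π
   crossings snapped to the nearest frame (ties to the earlier frame).
   Because beat-level HR jitter integrates into a slow phase drift that
   pure phase crossings cannot follow, boundaries are then anchored to a
   waveform landmark: the global signal is high-passed (0.45 s moving
   average removed), matched-filtered with a 13-frame rising-edge kernel,
   and each boundary snaps to the local response maximum within 25 % of
   the median beat length. The landmark is the steepest point of the
   systolic upstroke — the most sharply localizable feature; the
   diastolic foot sits in a flat noise-limited region. The within-cycle
   phase origin of a "beat" is a free convention; the simulator's
   EIT-timebase ground-truth boundaries use the same mid-upstroke
   landmark (plus the pulse-arrival delay), which is what makes
   boundary-error tests meaningful. Under the reference conditions ≥ 95 %
   of true beats are recovered with both boundaries within 2 frames.
5. **Exclusions:** a beat is premature if shorter than 0.75× the median
   length of its 10 nearest neighbors; it is dropped together with both
   flanking beats (rule and constants are this package's stipulation,
   exposed in config). Beats longer than 64 frames are rejected as
   overlong.

Known limitations: the upstroke anchor assumes the channel-mean cardiac
gain is positive (aortic filling increases thoracic conductivity); a
negative-mean montage would anchor on the downstroke, shifting all
boundaries by a constant phase. Sign-ambiguous montages would need an
explicit polarity check. Respiration is assumed spectrally separated from
the cardiac band; cardiorespiratory coupling sidebands in real data are
not emulated.

## Preprocessing

Per beat, in order: label extraction from the recalibrated pressure
(onset/end minima searched within ±200 ms of the interval ends; SAP =
maximum, DAP = onset-minimum value, MAP = inclusive arithmetic mean
between the minima — not the DAP + PP/3 estimator), block-wise z-score
with one scalar mean and SD over the unpadded block (zero-variance blocks
rejected), then zero-padding to 64×1024 (padded rows exactly zero because
normalization precedes padding; per-channel linear resampling to 64
frames is available as an alternative mode). Labels are normalized to
[0, 1] per target with min/max bounds from the training split only;
held-out labels may map outside [0, 1] and are not clipped, so the
inverse is exact. Block extraction operates on the DC-removed frames:
the static channel-offset pattern is a subject fingerprint that otherwise
dominates the z-scored blocks and lets a cross-validated model memorize
subject identity instead of pressure correlates (observed as near-zero
held-out ICC with converged validation loss).

## Model

The default regressor is a funnel CNN over the 64×1024 block as a single
feature plane: three 2-D convolutions with kernel 12×12, filters 8→4→2,
stride (2,2), 'same' padding, each followed by batch normalization and a
ReLU, then flatten (8·128·2 = 2048) and a dense layer to the 3 outputs —
about 13 000 parameters. A 1-D-over-frames variant treats the 1024
channels as input features (kernel 12×1; ~99 000 parameters, almost all
in the first layer). Interpreting the funnel steps (8, 4, 2) as filter
counts and 12 as the spatial kernel size is a modelling choice; the exact
original topology is not reconstructible, so parameter counts are treated
as an order-of-magnitude property (10⁴–10⁵), not a target. The ReLU is
likewise a choice: without any nonlinearity the network is linear and
cannot form the amplitude-ratio features the signal encodes.

Training: MSE on the normalized 3-vector, Adam (lr 10⁻³ default,
3·10⁻³ in the study profile), batch size 100, up to 100 epochs with early
stopping after 5 epochs without validation improvement,
best-validation weights restored. The engine is pure numpy (im2col +
GEMM convolutions with explicit backprop, verified against central finite
differences to ~10⁻⁷); runs are bit-reproducible for a given seed on a
given machine. Two engine-level optimizations matter on one CPU: the
first layer skips its input gradient (nothing consumes it), and its
im2col columns are precomputed once per fold since its input never
changes across epochs.

Cross-validation: one fold per subject; the remaining subjects' beats are
shuffled and split 90/10 into train/validation (stratified by subject
proportion, beat-level random, seeded); label bounds are recomputed per
fold from the training split; fold disjointness is hard-asserted.
Hyperparameter search evaluates each candidate by full LOSO and ranks by
pooled MAP ICC — MAP being the clinically decisive target.

## Agreement statistics

- **ICC:** the two-way ANOVA single-measure *absolute-agreement*
  coefficient `(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))` with
  beats as rows and the two methods as columns. "Absolute agreement"
  fixes the formula (it penalizes offsets); the implementation matches
  pingouin's ICC(A,1) to 10⁻¹⁰. Koo categories use left-closed intervals
  ([0.5, 0.75) moderate, etc.) to make the cut points deterministic.
- **Bland–Altman for repeated measurements:** bias is the unweighted mean
  of per-subject mean differences; the total SD combines the
  between-subject variance of those means (corrected for the
  within-subject sampling contribution, truncated at zero) with the
  pooled within-subject variance; LoA = bias ± 1.96 SD. With one subject,
  or one beat per subject, this reduces exactly to the simple variant.
- **4-quadrant concordance:** consecutive-beat changes within subject
  only; a pair is excluded when `max(|Δref|, |Δest|)` is below 10 % of
  the maximal absolute systolic reference change (central-square rule —
  the membership rule is underdetermined in the literature we follow, so
  it is exposed in config; the threshold anchors to the systolic series
  even when scoring MAP/DAP). Beat-to-beat label noise dominates
  consecutive deltas in the synthetic cohort, so per-beat concordance
  hovers near 50–55 % even when absolute agreement is good; trending
  over longer windows (the `trend_profile` smoothing option) is the
  appropriate lens for slow hemodynamic changes.
- **Error grids:** five risk zones A ("no risk") to E ("dangerous risk")
  as polygons in the (reference, estimate) plane, classified with A→E
  precedence and inclusive boundaries. The published grid coordinates
  are not reproduced here: the shipped files
  (`src/eitbp/data/*_grid_synthetic.json`) are clearly labelled synthetic
  approximations built from absolute/relative deviation bands
  (A: ±max(10 mmHg, 10 %) for SAP), with zone E a catch-all rectangle.
  They are pluggable data — pass a different JSON to use a validated
  grid. No grid exists for DAP.

## Reference study and problem sizes

`eitbp.study` pins the reference experiment: nine subjects, base duration
250 s with unbalance factor 1.6 (≈ 4000 beats), events enabled, the
1-D model profile (strides (8,8)/(1,1)/(1,1), lr 3·10⁻³, ≤ 15 epochs,
batch 100). These sizes were chosen so the whole study — simulation,
segmentation, nine LOSO trainings and evaluation — completes in a few
minutes on a single CPU while keeping several thousand beats; they are
the package's own desk-scale conditions, not a claim about any in-vivo
dataset. Under seed 1 the study yields pooled held-out ICCs near 0.87
for all three targets with |bias| < 1 mmHg.

## What passing tests show — and what they do not

The synthetic cohort demonstrates that the pipeline is *correct and
internally consistent*: segmentation recovers known beats, labels match
known truth, the model can exploit exactly the physical couplings the
simulator provides (beat duration via the padding boundary, cardiac
amplitude relative to fixed-level noise and respiration, arrival-time
shifts), and the statistics match independent oracles. It does not
demonstrate in-vivo performance: real EIT noise is neither white nor
stationary, electrode montages and cardiac gain patterns vary across
individuals far more than the ±8 % emulated here, respiration is not a
pure sinusoid, and real pressure waveforms vary in shape beyond this
two-parameter template. Results on the synthetic cohort are therefore an
upper bound under idealized coupling, not a clinical claim.
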