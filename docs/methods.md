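# Methods

## Problem and pipeline

`psgdetect` detects two families of scored sleep events in multichannel
polysomnography (PSG):

* **Leg movements (LM)** — tibialis-anterior EMG bursts exceeding the quiet
  baseline by more than 8 µV and lasting 0.5–10 s.  Series of ≥4 LMs with
  inter-movement intervals of 5–90 s are **periodic limb movements of sleep
  (PLMS)**; LMs occurring within 0.5 s before to 0.5 s after a respiratory
  event are **respiratory-related leg movements (RRLM)** and are excluded
  from PLMS by convention.
* **Sleep-disordered breathing (SDB)** — airflow reductions of ≥90 %
  (apnea) or 30–70 % (hypopnea) lasting ≥10 s, visible in the nasal-pressure
  and thoracic/abdominal effort channels.

The pipeline has four stages, each an independent module:

1. **Preprocessing** (`preprocess`).  Per-channel zero-phase Butterworth
   band-pass filtering at the native rate (EMG 10–50 Hz order 4; effort
   belts 0.1–15 Hz order 2; nasal airflow 0.03–50 Hz order 2), polyphase
   anti-alias decimation to 100 Hz, per-channel z-scoring with the N−1
   standard deviation, segmentation into non-overlapping 60 s windows
   (6000 samples), and rasterization of event intervals into per-sample
   binary labels `[LM, SDB]`.  Both label columns may be 1 at one sample —
   overlapping events are kept without prioritization.
2. **Temporal segmentation network** (`network`).  A 1-D encoder–decoder
   (U-Net) whose blocks run three parallel same-padding convolutions with
   kernels (5, 11, 17), concatenate and fuse them with a width-1
   convolution, then batch-normalize and apply ReLU.  Factor-2 max pooling
   between levels; multi-head self-attention (scaled dot-product, residual)
   at the bottleneck supplies global context; the decoder mirrors the
   encoder with nearest-neighbor up-sampling and skip concatenation.  The
   head is a width-1 convolution with an independent sigmoid per class —
   the classes are not mutually exclusive, so no cross-class softmax.
3. **Boundary optimization** (`crf`, `rules`).  Per class, a binary
   mean-field CRF smooths the probability sequence (unary −log P; Potts
   pairwise weighted by a bilateral time/probability Gaussian kernel and a
   pure time kernel; 5 iterations), then AASM rules merge LM candidates
   closer than 0.5 s, remove LMs outside 0.5–10 s and SDB shorter than
   10 s, flag RRLMs against the detected SDB events, and chain PLMS series.
4. **Evaluation** (`metrics`).  Point-wise precision/recall/F1 per class
   with macro averaging; event-level scores by one-to-one IoU matching
   (IoU strictly > 0.3, greedy in descending IoU); mean onset/offset/
   duration errors with the convention *predicted − truth* (positive =
   late); average precision by the interpolated precision-envelope area.

The top-level interface is statsmodels-shaped: `JointDetectionModel`
(records + annotations + configuration) whose `fit()` performs the 9:1
patient-wise split and Dice training and returns a `DetectionResults` with
`predict`, `evaluate`, `summary` and `save`.

## Training

The loss is the class-averaged soft Dice loss with Laplace smoothing 10⁻³;
`|X∩Y|` is the probability–label product sum, making the set overlap
differentiable, and an all-empty class contributes zero loss.  Dice is
pooled over all samples of a class in the batch (per-segment pooling is
available).  Optimization is Adam, learning rate 10⁻³, weight decay 10⁻⁴
(classic L2-in-gradient), batch size 128, 50 epochs at full scale, no
schedule or early stopping; the epoch with the lowest mean training loss is
the checkpoint kept.  Only segments containing at least one event are used
for training; evaluation uses every segment.  The output-head bias is
initialized to −2 so the network starts from a low event prior; with sparse
positive classes this removes the long initial plateau in which Dice
gradients are diluted by the |X| mass of a half-on prediction.

The network core is implemented directly on numpy: a small reverse-mode
autodiff engine (`psgdetect.nn`) with fused convolution, batch-norm and
softmax primitives, verified against central finite differences in the test
suite, plus a hand-written Adam.  Compute is float32 by default
(switchable; the gradient-check tests run in float64).  Determinism: all
parameter initialization and batch shuffling derive from explicit
`numpy.random.default_rng` seeds, so loss curves are bitwise reproducible
on one machine.

## CRF details

Features are f_i = (t_i, c_i) with c_i defaulting to the class probability
itself (a raw-envelope feature can be substituted).  Kernels:
K1 = exp(−Δt²/2θα² − Δc²/2θβ²), K2 = exp(−Δt²/2θγ²), weights ω1, ω2.  The
kernel parameters are not documented in the source material; the defaults
θα = 1 s, θβ = 0.1, θγ = 0.25 s, ω1 = ω2 = 1 put the time scales between
the sampling interval and the minimum LM duration so that fragmentation is
suppressed without erasing short events, and all are exposed in
`CRFParams`.  Probabilities are clipped to [10⁻⁶, 1−10⁻⁶] before −log.
Messages exclude j = i and are truncated at 3× the largest time scale
(exactly zero beyond), giving O(T·W) sweeps; a dense O(T²) reference
implementation (`mean_field_dense`) is kept for verification.

Two update conventions are implemented.  The pseudocode form propagates
Q_j(x) into the energy of label x, which — combined with a Potts
disagreement penalty — would *reward* disagreement if read as an energy
minimizer; `mode="potts"` (default) therefore uses the standard
energy-consistent update in which the message for label x aggregates the
neighbors' opposite-label mass, and `mode="literal"` follows the pseudocode
verbatim.  For binary labels the two move the argmax by message
*differences* of opposite sign and in practice produce identical labels;
both are tested against the dense reference.  Ties Q(0) = Q(1) resolve to
0 (no event), the conservative clinical choice.  The CRF runs per 60 s
segment by default.

## Rules details

Merging precedes duration thresholding, so two sub-events split by a
momentary signal dropout survive as one event.  The inter-movement interval
for PLMS chaining is measured onset-to-onset (the WASM/AASM convention;
offset-to-onset is a config switch).  "Within 0.5 s" for RRLM is read as
interval intersection with the SDB interval padded by 0.5 s on both sides
(onset-containment is a config switch).  A gap shorter than 5 s between LMs
breaks the periodic chain but does not merge the movements.  Indices are
events per hour: LMI (all LMs), PLMI (PLMS-flagged only), AHI (SDB).

## Synthetic data

No public corpus carries joint LM/SDB annotations on this channel set, so
the simulator (`synth`) generates ground-truthed recordings:

* **Schedule.**  SDB counts are Poisson at `sdb_rate_per_h` (default 25/h,
  an OSA-range AHI); durations log-normal with median 27.55 s and sigma
  matched to the reported interquartile range, clipped to ≥10 s.  PLMS
  trains are Poisson at 4/h, 4–8 members, onset-to-onset gaps uniform in
  [10, 60] s; isolated LMs at 15/h; LM durations log-normal (median
  1.85 s) clipped to [0.5, 10] s.  With probability `p_rrlm` (default 0.3)
  each SDB event spawns an LM near its offset — the leg jerk at airway
  re-opening — guaranteed to intersect the ±0.5 s window.  Within-class
  overlap is forbidden (rejection placement with a capacity error after
  bounded retries); cross-class overlap is allowed.  RRLM/PLMS truth flags
  are assigned by the definitional predicates themselves, so accidental
  periodicity among isolated LMs is labeled as a scorer would label it.
* **Signals.**  Five channels at 200 Hz (decimated to 100 Hz by the
  pipeline, so the down-sampling path is exercised).  Legs: Gaussian
  baseline (sd 2 µV) plus 10–50 Hz band-limited bursts with 10–40 µV
  envelopes and 0.1 s ramps.  Nasal: quasi-sinusoid at 0.25 Hz with slow
  frequency jitter whose amplitude drops to ≤0.07 during apneas and
  0.3–0.7 during hypopneas with ~1 s smooth ramps; Thor/Abdo: correlated
  effort sinusoids with partial reduction.  Apnea/hypopnea subtypes are
  rendered but collapsed into one SDB class for labeling.

What the simulator does **not** emulate: EMG spectral nonstationarity,
movement and electrode artifacts, gradual hypopnea onsets, desaturation or
arousal coupling, sleep-stage structure, and between-patient variability
beyond the seed.  Passing the end-to-end checks therefore demonstrates that
the pipeline's machinery is correct and well calibrated on signals that
meet the scoring definitions — not that clinical-grade accuracy would be
reached on real recordings.

## Scaled-down experiments

`psgdetect.experiments` fixes the desk-scale study conditions: 20 simulated
records of 10 minutes, a reduced network (depth 3, base width 8, 2 heads;
~170 k parameters; bottleneck length 750), 15 epochs at batch 16, 4 records
held out by the patient split.  The joint-vs-single comparison trains a
leg-channel-only LM detector (8 epochs — LM is the easier class and
converges sooner) and evaluates both strategies on 4 records generated with
`p_rrlm = 1` and SDB at 60/h, the regime where respiratory-coupled LMs
recur at 5–90 s intervals and would masquerade as PLMS without RRLM
exclusion.  `scripts/acceptance.py` reruns both experiments from one seed
and writes every measured quantity as JSON.

## Numerical choices and edge cases

* Constant (dead) channel: z-score returns zeros instead of raising.
* Label intervals are half-open `[onset, offset)`, onset sample
  `floor(onset·rate)`; touching intervals have IoU 0 and remain distinct.
* Zero-denominator conventions: precision/recall 0 when undefined by
  counts; F1 = 0 when P + R = 0; mean boundary errors are NaN (not 0) when
  no events matched; AP is NaN when the truth has no positive samples.
* "Exceeds 0.3" for event matching is strict (>); Hungarian assignment is
  available as a cross-check for the default greedy matching.
* The Nasal filter order is not documented; order 2 is the default and is
  configurable.
* Evaluation stitches segment rasters back onto the record timeline before
  event extraction, so events crossing segment borders are counted once.

## Known limitations

* Batch normalization uses running statistics at inference; with very few
  training steps these lag the batch statistics slightly.
* The CRF is run independently per class and per segment; a cross-class or
  full-night CRF is out of scope.
* EDF input is optional (via `mne` when installed); EDF export is not
  provided.  The native interchange formats are a columnar CSV for events
  and NPZ for signals.
* The published clinical scores (private dataset) are not reproducible
  here; the package verifies analytic identities among the published
  values and its own end-to-end behavior on simulated ground truth.
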