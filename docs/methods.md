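# Methods

This note records the models, parameter choices and numerical decisions
behind `reachml`, and what the synthetic cohort does and does not establish.

## Task and data model

A trial is a four-sensor stream (hand = wrist dorsum, arm = upper humerus,
shoulder = acromion, trunk = manubrium) of 3-D positions [mm] and Euler
angles [deg] sampled at 30 Hz. The coordinate frame has its origin at the
right-shoulder rest position, X to the subject's right, Y anterior, Z up.
Nine targets combine three directions (middle = parasagittal, internal and
external at ±45° azimuth), two radial distances (close = 65% and far = 90%
of the equivalent upper-limb length, measured horizontally from the
shoulder's vertical axis) and two heights (low = 70 mm above the table, high
= acromion height, vertically above the matching far target). Trials are
presented in the fixed order CM, FI, HE, FM, CE, HI, CI, FE, HM; each
subject performs three cycles per arm.

## Synthetic cohort

The generator emulates the acquisition protocol, not any particular
patient:

- **Healthy kinematics.** The hand follows a minimum-jerk path
  x(τ) = x₀ + (x_T − x₀)(10τ³ − 15τ⁴ + 6τ⁵), the standard model of
  point-to-point reaching: bell-shaped speed, zero velocity and acceleration
  at both ends. The humerus sensor moves 50% of the hand displacement, the
  shoulder sensor 5%, the trunk sensor is static — so hand and arm carry the
  class information while shoulder and trunk are nearly uninformative.
- **Durations.** Healthy mean movement duration defaults to 2.2 s
  (per-subject SD 0.25 s, per-trial jitter ±10%). With the default cohort
  (10 healthy, 11 LHD, 10 RHD; severity 0.6) this puts the dataset-mean
  motion duration near 2.7 s, matching the protocol's printed average-window
  lengths (1/10 of the mean motion ≈ 0.27 s).
- **Pathology.** Only the contralesional arm is impaired (LHD → right arm,
  RHD → left arm). Its movements are slowed by the factor (1 + severity),
  curved laterally with a hemisphere-dependent sign (peak 40 mm × severity at
  reference scale), and fragmented by 2–4 corrective sub-movement pulses
  (15–35 mm × severity, smooth bumps vanishing at both motion ends), which
  yields a multi-peaked speed profile. Severity is a dimensionless [0, 1]
  scalar; it is a generator abstraction, not a clinically validated scale.
- **Orientation.** Euler angles ramp by target-dependent amounts (yaw ∝
  azimuth, pitch ∝ elevation and distance, roll ∝ distance; up to ~40°
  between hand extremes) with a compressed minimum-jerk time course that
  completes by mid-movement (pre-shaping), so the early observation window
  sees usable orientation signal. Mirror-odd components flip sign for the
  left arm, which makes the arms distinguishable from angles alone.
- **Subject signatures.** Each subject carries idiosyncratic sensor-mounting
  angle offsets (±10° hand/arm), an angle-ramp gain (0.85–1.15) and a
  preferred speed, all reproducible from the subject's seed. Real subjects
  are likewise idiosyncratic; this matters for interpreting the
  health-detection results (below).
- **Noise.** Additive white Gaussian noise, per-axis SD 0.8 mm (position)
  and 0.15° (orientation) — the tracker's quoted static accuracy — with no
  temporal correlation. Rest paddings of 15–30 samples flank the motion so
  the 10-sample resting blocks always exist.

Not emulated: joint-chain (inverse-kinematics) biomechanics, sensor
drop-outs or metallic-distortion artefacts, EMG/EEG, return movements
(trials end at the target), and any clinically calibrated pathology beyond
"slower, curved, fragmented". A green test on this cohort shows the
*pipeline* behaves as intended, not that the clinical accuracies are
reproduced.

## Preprocessing decisions

- **Speed chain.** Position modulus → low-pass → two-point derivative →
  low-pass → |·|. The derivative is the backward difference with the first
  sample replicated. Low-passing the position *before* differentiation is
  deliberate: differentiating raw 0.8 mm-noise positions at 30 Hz yields
  ~34 mm/s velocity noise whose filter edge transients false-trigger any
  onset threshold; pre-filtering is standard practice in kinematics.
- **Filtering.** Fourth-order Butterworth, 3 Hz cut-off, applied forward and
  backward (zero phase, doubled effective order). Edge transients use
  Gustafsson's initial-condition method, which makes the output exactly
  time-reversal symmetric — pad-based implementations miss this property by
  ~1e-2 at the edges.
- **Segmentation thresholds.** The schedule is relative by default:
  θ₀ = 0.03 × peak filtered speed, decrement 0.005 × peak. The bounds are
  principled: the rest-speed noise floor implied by 0.8 mm device noise in
  the 0–3 Hz band is σ ≈ 3 mm/s, so θ must sit well above ~10 mm/s for
  typical peaks, while a minimum-jerk reach only attains ≈ 0.033 × peak
  three samples after onset, capping θ from above. The literal historical
  schedule (9×10⁻³ mm/s, step 10⁻³ mm/s) is available with
  `relative_mode=False`; it lies far below the noise floor of mm-scale data
  and never converges meaningfully there. The accept test compares the
  *standard deviation* of the pre-onset/post-offset speed against θ (same
  units as the threshold; a literal variance would be dimensionally
  inconsistent with the decrement schedule), excluding the crossing samples
  themselves.
- **Normalization.** The nine resting-phase reference quantities (three
  sensor-pair displacement vectors × three axes) are retained for
  inspection, but amplitude normalization divides positions by the scalar
  equivalent limb length |hand→arm| + |arm→shoulder| (trial-averaged). How
  the nine quantities should individually rescale the signals is
  under-determined; the scalar reading is scale-consistent and makes
  geometrically similar subjects identical after normalization.
- **Windows.** Sample counts are floored (with a 1e-9 guard against float
  round-off on exact products), clamped to ≥ 2. Windows anchor at the
  detected onset — prediction uses the earliest signal. Under the average
  strategy a window longer than a short trial's motion segment is clipped to
  that segment.
- **Rescaling.** The affine map to [−0.80, +0.80] is fitted on the training
  split of every repeat and applied unchanged to the test split (per-trial
  rescaling would erase the between-trial amplitude differences the features
  encode). Constant training features map to zero.

## Classification decisions

- Splits are stratified (with up to 100 resampling attempts), which at 9–18
  classes is necessary for every class to appear in both splits; 85%
  training fraction for intention prediction, 90% for health detection.
- LDA uses the least-squares solver; Ledoit–Wolf shrinkage engages
  automatically when the pooled covariance is ill-conditioned (condition
  number > 1e8) or there are at least as many features as samples.
- Random forests use 40 trees for intention prediction and 20 for health
  detection, √p features per split, unlimited depth, bootstrap size n, and
  report out-of-bag accuracy; all randomness derives from the supplied seed.
  Repeat i of a repeated evaluation uses seed + i.

## Interpreting the results

- On the default cohort the qualitative orderings hold as in the clinical
  study: longer (1/7) windows beat 1/10 windows, the healthy subset beats
  the pathological subset, LDA edges RF for intention prediction, and RF
  far exceeds LDA for health detection.
- **Health detection and subject leakage.** Splits are by trial, not by
  subject, so trials of one subject occur in both train and test. With
  contralesional-only impairment the unaffected arm of a patient is
  kinematically healthy, capping arm-anonymous Bayes accuracy near ~68%;
  accuracies above 90% are reachable only through within-subject
  generalization on subject signatures. That is a property of the
  trial-wise protocol itself, and the synthetic cohort reproduces it
  deliberately. A leave-one-subject-out evaluation would tell a different
  story and is out of scope here.

## Known limitations

- **Onset precision.** A minimum-jerk reach leaves rest with zero velocity
  *and* acceleration, so any admissible threshold is first crossed ~4–6
  samples (0.13–0.2 s) after the mathematical onset at these durations; the
  noise floor forbids lower thresholds. Median absolute onset error on the
  default cohort's healthy trials is 5 samples (offset: 3). The acceptance
  target of ±3 samples is met for offsets but not onsets, and the
  corresponding test is left failing by design rather than weakened.
- The acceptance-scale statistical checks run at reduced repeat counts
  (10–20 instead of 200) and the "strongly separated" cohort used for the
  recovery check is 6/6/6 subjects × 2 cycles at severity 0.8; this keeps
  the suite within CI budgets and does not change any conclusion drawn from
  the full-scale settings.
- Euler angles enter features raw (unfiltered); only position-derived
  channels are filtered.
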