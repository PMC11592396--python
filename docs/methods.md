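# Methods

## The chain in one paragraph

Symbolic music is tokenized into a melody stream (one MIDI pitch per onset,
top voice on ties) and a harmony stream (sorted sets of 3–5 distinct pitch
classes formed from notes whose onsets fall within a 50 ms window). A
PPM-smoothed variable-order Markov model assigns each token a conditional
probability `p`, and `IC = -log2 p` (bits) is the event's surprisal. EEG is
reduced to per-second frontal band power via a complex Morlet
decomposition, and ordinary least squares measures how well each of three
per-second regressors — pleasure rating, melody IC, harmony IC — explains
the power time course of each band, per subject and piece. Per-fit t-values
become z-scores by an exact CDF transform, and a one-sample t-test across
all (piece × subject) z-scores gives the group-level answer per
(band × regressor).

## Surprisal model

* **PPM with escape method C, interpolated back-off.** Counts are kept for
  every context up to `max_order` (default 2). Prediction starts at the
  longest matching context; at each level the observed continuations
  contribute `n/(N+d)` and the escape mass `d/(N+d)` (`d` = distinct
  continuations, `N` = total) is passed to the next-shorter context. The
  chain terminates in a uniform distribution over the alphabet plus one
  reserved "unseen" slot, so every symbol — including one never observed —
  has probability > 0 and every IC is finite. The escape method is a named
  strategy; only "C" is currently registered.
* **both+**: the long-term model (ltm) is trained on a background corpus
  and *continues to learn* the piece being scored; the short-term model
  (stm) starts empty and learns only the piece. Both predict each event
  before observing it — scoring is strictly causal. Their distributions are
  merged by a normalized weighted geometric mean with weights
  `(normalized entropy)^(-bias)`; `bias` defaults to 1 (confident models
  dominate), and 0 gives the plain geometric mean. The merge rule is a
  design choice: entropy-weighted geometric pooling is the standard way to
  combine the two model families when the exact published weighting is not
  specified.
* **Alphabet policy.** The prediction support is the union of the corpus
  alphabet and the symbols seen so far in the piece, extended with the
  current event's symbol just before scoring it. This keeps IC causal (no
  dependence on later events) while still assigning novel symbols a proper
  probability through the uniform floor.
* **Harmony encoding** is the sorted distinct pitch-class set
  (octave-invariant, not transposition-invariant), bounding the chord
  alphabet at 2^12; windows with fewer than 3 or more than 5 distinct
  pitch classes produce no token. Absolute harmony IC values therefore
  depend on this encoding and are not comparable across other encodings.

## Spectral analysis

* Filters: zero-phase 4th-order Butterworth band-pass 1–60 Hz
  (second-order sections, forward-backward) and a 2 Hz-wide 50 Hz notch,
  then common-average re-referencing. The sampling rate must exceed
  120 samples/s.
* Morlet family: `σf = f0/7`, `σt = 1/(2π σf)`,
  `w(t) = (σt√π)^(-1/2) exp(-t²/2σt²) exp(2iπ f0 t)`, truncated at
  `±4σt`, sampled and scaled by `1/fs` so the discrete convolution
  approximates the continuous one. Energy is `|w * s|²` on the integer
  grid 1–45 Hz. Two convolution routes (FFT-based and direct time-domain)
  are implemented and agree to ~1e-15 relative; tests hold them to 1e-9.
* Edges: the signal is reflection-padded so the output keeps the input
  length; the first/last `4σt` seconds per frequency remain
  edge-contaminated (about 4.5 s at 1 Hz, tens of ms in γ). Band power is
  the mean energy across the band's integer frequencies, then the mean per
  half-open 1-s bin anchored at the recording start; a trailing partial
  bin is dropped so power and regressor series align. Power is raw — no
  log transform, no baseline correction (a log option exists, default
  off).
* `run_study(..., drop_edge_bins=True)` masks the edge-contaminated bins
  of each band out of the fits. The default is to include them, but the
  package's own calibration experiments exclude them: simulated null
  studies showed a systematic δ-band × pleasure bias (mean z ≈ −0.7) that
  is purely an artifact — boundary bins have inflated low-frequency
  energy, and the rating regressor deterministically ramps from neutral
  over exactly those opening bins.

## Regressors and fitting

* Ratings (integer 1–4; 1 neutral, 4 peak pleasure/chills) are treated as
  a held-key step function and averaged within each 1-s bin (fractional
  values at change points). Bins before the first press are neutral.
* IC regressors are per-bin means of the events in the bin; note-free bins
  are masked invalid rather than zero-filled — a zero would fabricate "no
  surprise" evidence. No lag correction is applied by default; a lag
  parameter exists for sensitivity analyses.
* Each fit is OLS with intercept on the jointly valid bins (minimum 3).
  Zero-variance regressors (e.g. an all-neutral rating trace) and
  zero-residual fits are flagged degenerate, excluded downstream, and
  counted in the run manifest, so valid + excluded always equals
  pieces × subjects per cell.
* `t → z` uses the exact probability-integral transform through the t and
  normal CDFs (survival functions on the positive side for tail
  precision) rather than the crude `z ≈ t` approximation, because pieces
  of different lengths give fits with different df.
* Group tests are two-sided, one z per piece × subject combination, no
  multiple-testing correction across the 15 (band × regressor) cells —
  raw p-values are reported as such. Spearman correlation (average ranks
  on ties) pairs each note event's IC with the subject-averaged pleasure
  of the bin containing the event, pooled across pieces.

## Synthetic data: what it emulates and what it does not

* **Music**: stationary order-1 Markov sources (Dirichlet-random
  transition tables) over 8 melody pitches / 6 chord symbols, 2 melody
  events/s and 1 chord/s. True IC is `-log2` of the generating
  probability — the quantity the surprisal engine should recover.
* **Ratings**: per-second IC is smoothed with a 3-s moving average
  (prevents 1-bin flicker), delayed 2 s (behavioural response lag),
  perturbed with per-subject Gaussian noise (sd 0.3), and cut at
  thresholds (1.8, 2.6, 3.4) bits into ratings 1–4. Bins before the first
  (lagged) note are neutral.
* **EEG**: each channel is 1/f-amplitude-shaped Gaussian noise (sd 1.0)
  plus white noise (sd 0.5). Frontal ROI channels additionally carry a
  sinusoid at the coupled band's midpoint (22 Hz for β) whose envelope is
  `max(0, baseline + gain × lagged regressor)`; gain 0 and regressor
  "none" give pure noise. The default geometry mirrors a realistic study
  (8 pieces × 15 subjects, 30 channels at 512 Hz); the experiment helpers
  use a desk-scale reduction (2 pieces × 10 subjects, 60-s pieces,
  128 Hz, the 8 frontal channels) so replicate ladders run in minutes.
* Not emulated: blinks/EMG artifacts, volume conduction, inter-channel
  correlation, silence cycles between pieces, tempo/expressive timing.
  Passing tests therefore demonstrate the *chain's* correctness and
  calibration, not robustness to real-world EEG artifacts, which the
  pipeline expects to have been removed upstream (externally cleaned
  recordings are accepted as-is; no ICA is performed here).

## Calibration experiments and recorded constants

* **Null calibration** (50 studies, 1000 piece × subject recordings): the
  pooled per-fit z is compared with N(0,1) by KS distance and the group
  rejection rate with its binomial CI at α = 5%. Typical values: KS ≈
  0.01, rejection ≈ 4–5%.
* **Coupling recovery** (20 replicate β-coupled studies): gain 1.0
  (`RECOVERY_GAIN`), calibrated once in a pilot so binned β power
  correlates > 0.9 with the driving regressor; the β group test is
  significantly positive in ≈100% of replicates and θ rejects at ≈5%.
* **Convergence ladder** (order-1 source, 40 targets × 100 events,
  alphabet 8, corpora of 5/50/500 sequences): mean |IC error| falls
  monotonically and ends below `PILOT_MAE_BOUND_BITS` = 0.9. The floor
  (~0.75 bits) is set by the stm's contribution to the both+ mixture, not
  by ltm estimation error — with a stationary source the stm is pure
  contamination, which is the price the both+ design pays for its
  sensitivity to within-piece structure.

## Numerical and degenerate-input policy

* Probability floors guarantee finite IC; predictive distributions are
  normalized and validated to 1e-9.
* Markov sources validate their transition tables (sum to 1 within 1e-12,
  no negatives, context length ≤ order) and name the offending context.
* Empty rating traces and empty IC series produce flagged all-neutral /
  all-invalid series rather than errors; empty chord streams are valid
  (melody-only pieces).
* Per-(piece, subject) failures inside `run_study` are caught, attributed,
  and logged in the error manifest while the run continues.
* All randomness flows from `numpy` SeedSequence children of one root
  seed; identical config + seed reproduces studies bit-identically.

## Known limitations

* Group tests treat the z of each piece × subject as exchangeable, but
  within a piece all subjects share one regressor realization; with very
  few pieces, chance regressor overlap produces piece-level pseudo-
  replication visible in uncoupled cells of small demo studies.
* Absolute IC scales depend on the chord encoding and PPM configuration;
  only relative/temporal structure is meaningful across configurations.
* The wavelet's spectral skirt lets a strongly driven 22 Hz carrier leak
  into the 31–45 Hz band: a γ effect accompanies a strong β effect by
  construction of continuous wavelet analysis, not as an artifact of the
  statistics.
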