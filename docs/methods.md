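# Methods

`aptanomaly` implements a semi-supervised anomaly detector for the
drain-current time series produced by aptamer-functionalized field-effect
transistor (FET) biosensors, together with a synthetic signal generator used
to exercise and calibrate the pipeline.

## The measurement model

A sensing experiment records a univariate drain current at a fixed time step
while the analyte concentration in the sensor's PDMS well is raised
step-wise: an initial load period with no analyte (e.g. 1000 s for an
adenosine-type protocol, 600 s for an oestradiol-type one), then injections
at a fixed interval (500 s / 300 s) walking up a concentration ladder
(pM–μM).  The stretch of signal at constant concentration is a *segment*.
A healthy sensor shows (i) a current peak right after each injection whose
amplitude grows with concentration, relaxing back over tens-to-hundreds of
seconds, and (ii) a steady monotone drift (rising or falling depending on
the chemistry).  Each segment carries a quality label assigned at collection
time — `normal`, `marginal`, `no_sense` (the device ignores the analyte) or
`broken` (failed transistor); everything but `normal` is an anomaly.

## Detection pipeline

1. **Normalization.** Each entire signal is z-scored with its own mean and
   sample standard deviation (n−1 denominator).  Scaling is per signal, not
   per segment, and no detrending or filtering is applied.
2. **Segmentation.** Each concentration window contributes its last
   L samples, where L is the injection interval in samples (500 for the
   adenosine-type protocol, 277 for the oestradiol-type).  The initial load
   window is longer than L; truncating to its tail keeps the steady state
   closest to the first injection while giving the networks a uniform input
   size.  Windows are half-open, 0-based sample ranges.
3. **Training (semi-supervised).** Only normal segments are used to train
   three reconstruction networks:
   * *vanilla autoencoder* — one hidden layer of 16 units
     (undercomplete), sigmoid encoder, identity decoder.  The identity
     output layer is deliberate: inputs are z-scored and therefore signed,
     so a bounded decoder could not reproduce them without hidden
     rescaling.
   * *ULSTM autoencoder* — sequence-to-sequence stack
     LSTM(32) → LSTM(16) → LSTM(32) → per-time-step linear map to one
     channel, each segment entering as a length-L sequence of scalars.
   * *BLSTM autoencoder* — the same stack with every LSTM layer run in both
     temporal directions (outputs concatenated).
   The 16-unit latent layer is shared by all three networks so each decoder
   receives similarly sized features.  Training minimizes mean squared
   reconstruction error with Adam (learning rate 1e-3), minibatches of 5,
   reshuffling every epoch, an epoch cap of 50, Glorot-uniform weight
   initialization and zero biases, all driven by one seeded NumPy generator.
   The networks, their gradients (backpropagation through time for the LSTM
   stacks) and the optimizer are implemented directly in NumPy; gradient
   correctness is pinned by finite-difference checks and the LSTM cell by a
   scalar-loop re-evaluation of the gate equations.
4. **Thresholding.** The per-segment reconstruction MSEs of the training set
   form a sample R = {r_1 … r_m}.  Their distribution is estimated by a
   Gaussian kernel density estimate with the Gaussian-reference plug-in
   bandwidth H = 1.06 σ m^(−1/5) (σ the sample standard deviation, m−1
   denominator).  A 90% *central* confidence interval [τ_l, τ_u] is read
   off the estimated distribution by inverting its CDF — a closed-form
   equal-weight mixture of Gaussian CDFs — with a bracketed root find
   (|CDF(τ)−p| ≲ 1e−10; no density gridding).  τ_u (the 0.95 quantile) is
   the decision boundary; τ_l is ignored because an unusually *good*
   reconstruction is not suspicious.  A one-sided variant (τ_u at the 0.90
   quantile) is available behind a configuration switch.
5. **Decision and integration.** A segment with error r > τ_u is an anomaly
   (ζ = 0); r ≤ τ_u is normal (ζ = 1), boundary inclusive.  Five models are
   reported: the three single-network detectors plus two integrated models
   (ULSTM+vanilla, BLSTM+vanilla) in which a segment is normal only if both
   the LSTM and the vanilla detectors pass it — equivalently, the integrated
   anomaly set is the union of the two component anomaly sets.
6. **Evaluation.** Confusion counts and sensitivity, precision, F1 and
   accuracy, with the anomaly class positive by default (both conventions
   are written to the report).  Zero-denominator metrics are reported as
   not-applicable rather than 0.

### A note on the decision inequality

The decision is a comparison of the *reconstruction error* against τ_u.
An alternative reading that compares the *density value* ρ(r) against τ_u
is dimensionally inconsistent (a density against a quantile) and
contradicts the operational description of thresholding — samples to the
right of the upper bound are the anomalies — so this package compares the
error itself.

## Synthetic signal generator

The generator emulates the statistical anatomy the detector consumes, not
the electrochemistry (no Langmuir binding or Debye-screening physics):

* deterministic component: baseline + linear drift
  (`baseline_current + segment_drift_rate · t`), plus, in each injection
  window k ≥ 1, a peak term `k · peak_gain · exp(−Δt / peak_decay_time)`
  relaxing toward the drift line.  The peak lives within its own window, so
  the amplitude right at injection k is exactly `k · peak_gain` above the
  drift line — a closed-form law the tests check pointwise;
* i.i.d. Gaussian noise of standard deviation `noise_sd`.

Defaults (arbitrary current units, chosen once as a realistic mid-scale
aptasensor regime): adenosine-type schedule (1000 s load, 500 s injections,
1 s step, six-rung ladder), baseline 100, drift +0.01 units/s (a ~35%
rise over a full run), peak gain 3 per ladder rank (peaks of 3–15% of
baseline, "noticeable but not dominant"), relaxation 150 s, noise sd 0.5.

Anomaly classes:

* `abnormal_points` — a few isolated ±10-unit spikes; qualities stay
  `normal` (isolated interference is noise, not sensor failure);
* `abnormal_interval` — a contiguous run of whole windows (default 2)
  overwritten with level-preserving high-variance values; exactly those
  windows become `marginal`.  Real marginal signals are not quantitatively
  characterized anywhere; this class is a stand-in;
* `broken_transistor` — the whole series replaced by a flat line + noise
  (`flat`) or a high-variance random walk (`erratic`); all windows
  `broken`;
* `no_sense` — the deterministic peak component multiplied by a suppression
  factor (default 0, i.e. removed); all windows `no_sense`.

What the generator does *not* reproduce: slow baseline wander, 1/f noise,
temperature excursions, heterogeneous per-device response curves, and the
label noise of human annotation.  Passing tests therefore demonstrate that
the pipeline's machinery is correct and that it separates the synthetic
anomaly classes — not that the same accuracy would be achieved on real
sensor recordings.

## Calibration benchmark

The canonical benchmark trains on 60 normal segments (10 simulated signals)
and tests on 20 normal plus 20 anomalous segments (10 broken-flat, 10
no-sense), with per-stage seeds derived from one global seed.  At these
settings the vanilla detector reaches accuracy ≥ 0.90 and every detector's
median anomaly error exceeds its median normal error by orders of
magnitude.  The hardest cases, and the expected residual misses, are the
no-analyte and lowest-concentration windows of no-sense signals: the
no-analyte window carries no peak even in a healthy signal, so suppressing
peaks barely changes it — those segments are near-indistinguishable by
construction, which mirrors the real labelling convention of marking *all*
segments of a non-sensing signal anomalous.

Problem sizes for routine runs were chosen to keep a full
three-network benchmark in the minutes range on one CPU: L = 500 segments,
60 training segments, 50-epoch LSTM training.  The KDE calibration check
uses m = 5000 fitted points and 100 000 fresh draws, where the KDE's
smoothing bias (≈ +0.5 percentage point of over-coverage at this m) is well
inside the ±1.5-point band.

## Numerical choices and edge cases

* Constant signals cannot be z-scored and raise a degenerate-signal error;
  identical reconstruction errors raise a degenerate-sample error (no
  bandwidth exists).
* The train/test split draws `round(train_fraction · total)` normal
  segments (half-away-from-zero rounding) uniformly without replacement;
  an infeasible fraction reports the maximum feasible one.
* The sigmoid is evaluated in the overflow-safe two-branch form.
* Training aborts with the epoch index if the loss goes non-finite.
* The vanilla bottleneck shrinks below 16 only if the input is shorter than
  17 samples (unit-test scale), keeping the network undercomplete.
* HDF5 model artifacts store float64 weights, so save/load round-trips are
  bit-exact; segment/signal CSVs print 17 significant digits for the same
  reason.

## Known limitations

* The vanilla AE is trained with Adam rather than scaled conjugate
  gradient; with a fixed epoch budget this leaves a mild underfit of the
  largest-peak archetypes and hence a right tail in the training-error
  sample that inflates τ_u somewhat.  Longer training without
  regularization overfits segment-level noise and collapses τ_u instead;
  the 50-epoch default sits between the two regimes.
* Marginal-quality signals have no quantitative definition; the
  abnormal-interval class only gestures at them.
* Decisions are per-segment and independent; no temporal smoothing across
  segments of one signal is attempted.
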