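# Methods

## Device model

The encoder is modeled behaviorally, not physically: encoding only depends on
where the drain current crosses the thresholding current and how the current
behaves near that crossing, so the transistor is reduced to a monotone,
smooth map from effective gate drive to log-current.

Charge balance between the two gates is captured by a single effective drive
`d = V_PSV + cap_ratio·V_TG − v_on` with `cap_ratio = C_TG/C_BG = 2.2`, the
measured transfer-curve slope. (The dielectric thicknesses and constants of
the reference device imply ≈1.95; the model adopts the measured 2.2 as ground
truth and records the discrepancy here.) The log₁₀-current is

* a line of slope `1/ss` (subthreshold swing `ss = 0.3 V/dec`) anchored at
  `i_ref = 100 pA` when `d = 0`;
* blended by a softplus knee (width 12 mV) into a much shallower line of
  slope `1/ss_sat` (`ss_sat = 150 V/dec`) above `knee_current = 530 pA` — a
  nearly pinned post-threshold current;
* held between a leakage floor `i_floor = 0.1 pA` and a saturation ceiling
  `i_sat = 2 nA` by sharp smooth-max/min clamps (40 dec⁻¹).

The pinned post-threshold region is the model's one non-obvious commitment,
and it is forced by the reported energetics: the per-spike energy expression
averages `I_PSC·V_DS·t_p` over all 32 pulses of a window, and at full
stimulus (where >80% of pulses spike with `I_ST = 500 pA`, `V_DS = 1 V`,
`t_p = 10 ms`) the observed ≤5 pJ envelope requires the mean pulse current to
stay within a few tens of pA of `I_ST`. A plain exponential clamped at a
ceiling high enough to support 1 nA thresholding (the measured
threshold-vs-gate curves extend there) would instead give 9–20 pJ. The pinned
slope reproduces the envelope while remaining strictly increasing, so unique
spiking thresholds exist for any current between floor and ceiling.

Because the current depends on the gates only through `d`, the spiking
threshold is exactly affine in the sampling-gate voltage with slope
`−cap_ratio` at every thresholding current, and interchanging the gate roles
rescales the slope to `−1/cap_ratio`. The threshold solver finds the crossing
in `d` by bracketed root finding (Brent, |error| < 1e-9 V) over
`d ∈ [−80, 120] V` — wide because thresholds for currents in the pinned
region sit tens of volts up the shallow slope.

Readout noise is a multiplicative log-normal factor (`σ = 0.1` in
log-current) applied per pulse; the device never quantifies its noise, so
this scale is chosen to keep near-threshold spike decisions stochastic. It
interacts with the pinned current: a spiking pulse carries only
~`log10(knee/I_ST) ≈ 0.025` decades of margin, about 0.6 noise standard
deviations, so even strongly super-threshold pulses fire with probability
≈0.87 rather than 1. This softens the measured transfer curve relative to the
noise-free closed form (which is why the closed-form oracle comparisons in
the tests disable readout noise) and inflates the across-trial rate spread —
both consistent with the reported ≈10 Hz encoding error bar.

### Calibration

`default_calibration()` (the rate/count/timing demonstrations) fixes
`v_on = −2.3 V` and `knee = 530 pA` so that, simultaneously: the 500 pA
spiking threshold at `V_TG = −2.5 V` falls at 3.41 V inside the 0–5 V
stimulus window; the rate-mode spike probability at 0 V is 0.026 (dark pixels
nearly silent) and 0.82 at 5 V; the window-averaged energy stays within the
1–5 pJ envelope at every level; and the across-trial rate standard deviation
averages ≈9.5–10 Hz under the reference protocol. `C_TG = 32 fF` makes the
gate-charging term ½·C_TG·V_TG² ≈ 100 fJ at the rate-mode operating point,
an order of magnitude below the drain-dissipation term, as reported.

`mnist_calibration()` serves the classification front end, which samples the
top gate from a wider, more negative distribution (`μ_TG = −5.5 V`,
`σ_TG = 1 V`, `I_ST = 200 pA`). That operating point is incompatible with the
default calibration — the threshold midpoints implied by the two protocols
differ by `cap_ratio·3 V − ss·log10(2.5) ≈ 6.5 V`, more than the whole
stimulus window — so the front-end device is re-biased (`v_on = −8.9 V`,
`ss = 1 V/dec`), placing the 200 pA threshold midpoint at 3.5 V. There the
Bernoulli rate map is nearly proportional to pixel intensity with a small
zero-pixel offset (p(0 V) ≈ 0.06, p(5 V) ≈ 0.75). Proportionality matters: a
bias-free rectifier network is positively homogeneous, so a pure rescaling of
its input preserves every argmax, while an additive offset on all inputs does
not — near-lossless ANN-to-SNN conversion therefore wants the encoder's rate
map to pass close to the origin.

## Photodiode front end

The sensor is a photovoltaic-mode load line: a photocurrent source
(`responsivity · P_LED`) in parallel with an ideal diode and a load resistor;
the operating voltage solves the current balance by bracketed root finding.
Illuminance is an arbitrary linear unit — the reference figures print no axis
values — and the defaults are declared illustrative, chosen so a three-decade
sweep covers the 0–5 V window (linear in the load resistor at low light,
saturating toward the open-circuit voltage).

## Encoding protocols

Defaults follow the reference experiment: 32 pulses of 10 ms per trial, 16
trials per stimulus level, 512 sampling points per level. The spike rule is
strict (`current > I_ST`). The rate statistic is the inverse mean interspike
interval, with intervals measured center-to-center between consecutive spike
slots; trials with fewer than two spikes fall back to
`count/(N·t_p)`, keeping the estimator defined (0 Hz when silent) instead of
dropping trials. This estimator has heavy upper tails at dim stimuli (two
adjacent spikes read 100 Hz regardless of how empty the rest of the window
is), which is the main contributor to the ≈10 Hz mean error bar.

Count and timing ramps are derived from the device calibration: endpoints are
the sampling-gate voltages whose thresholds sit at the edges of the stimulus
range, extended by margins in units of the pulse noise. Count uses symmetric
1σ margins. Timing extends the bottom margin to 3σ so that even a 0 V
stimulus reliably elicits a (late) spike and deactivates the encoder —
without it, a few percent of dim-stimulus trials never spike, never
deactivate, and the energy curve kinks upward at the bottom of the range,
contradicting the observed monotone decrease. A `half` ramp preset spans
0–10 V instead of 0–5 V, capping the in-window count at ~16 of 32 pulses;
the reference Methods quote a maximum count of 16 and a maximum of 30
timesteps despite 32-pulse trials, and the exact ramp calibration behind
those numbers is not recoverable, so both presets ship and neither is
asserted canonical.

Energy follows the window-normalized expression (divide by `N`, count only
active pulses); `per_spike=True` divides by the spike count instead, with NaN
for silent trials. The energy symbol printed with the drain term is
dimensionally a current and is implemented as the postsynaptic current.
Timing-mode energy decreases with stimulus in trend but carries a sub-0.01 pJ
ripple between neighboring 0.5 V levels: the 32-step ramp advances the
threshold 0.21 V per pulse, so the spike-pulse current margin aliases against
the level grid. The monotonicity test asserts the trend (rank correlation and
endpoint decrease) rather than adjacent-pair ordering for that one curve.

## Imaging

Images quantize to the experimental grid `v = round(pixel·5/255 / 0.5)·0.5`
(11 levels; exact halves round to even, though none occur for integer gray
values). Every pixel is encoded with pixel-indexed substreams; rate and count
modes concatenate all 16 trials (T = 512), timing records one pass of the
ramp (T = 32, one latency per pixel). Reconstruction never uses per-image
statistics: rate mode inverts the closed-form Gaussian-CDF transfer back to a
voltage estimate (the linear "scale by expected maximum count" alternative
cannot reach sub-grid-level error once the calibrated transfer curve is
visibly convex over the window); count mode scales by the expected
full-scale count at time t; timing mode maps first-spike index to gray, raw
(earlier = darker, the contrast-reversed rendering) or re-inverted via
`reverse=True`. Correlation traces for timing are computed on the re-inverted
image. Final-frame Pearson correlations on a 64×64 gradient are ≈0.98 (rate),
≈0.99 (count), ≈0.96 (timing) at the defaults.

## Classification

`train_ann` is mini-batch gradient descent (batch 32, no momentum) on softmax
cross-entropy with a ReLU hidden layer, a linear output layer, no biases and
no regularization. Gradients are summed over the mini-batch, so the learning
rate (default 1e-4, as in the reference protocol) is a per-sample step size;
with mean reduction the same rate and epoch budget visibly underfits even the
synthetic fixtures. Threshold balancing replays encoder-generated calibration
spike trains through the layers in order, setting each layer's threshold to
the maximum observed pre-activation. Inference accumulates output spikes and
predicts by argmax (ties to the lowest class index); a membrane readout
(integrated drive) is available behind a flag. Thresholds stay fixed after
balancing.

The full-scale digit benchmark (60k/10k MNIST images in IDX format) is
reachable through the CLI when the user supplies the files; nothing is
downloaded. The test suite exercises the same pipeline on synthetic
blob-digit fixtures: 10 Gaussian-bump class templates (peak `contrast·25`
gray levels, default contrast 8) plus additive pixel noise (default σ = 20),
balanced labels. At 1000 training images the converted SNN matches the ANN on
≥99% of a 500-image test set at 500 timesteps, the error is nonincreasing in
the timestep budget, and sweeping `σ_TG` or `I_ST` reproduces the
characteristic U-shapes (too little spread or too little/too much firing both
hurt; the minimum sits at the reference operating point).

## What the synthetic data does and does not show

The fixtures (gradients, checkerboards, disk phantoms, blob digits) exercise
every code path with known ground truth: monotone stimulus maps, exact
quantization counts, separable classes. They do not reproduce the statistics
of natural images or handwritten digits — blob classes are far more
separable than MNIST digits, so the fixture classification errors (≈0 at the
optimum) say nothing about absolute MNIST accuracy, only about conversion
fidelity and the direction of parameter effects. Likewise the device model
reproduces calibrated transfer behavior, not device physics: no hysteresis,
no temperature dependence, no drift, and a noise scale chosen rather than
measured.

## Numerical choices

Root finding uses Brent's method with bisection fallback (tolerances in the
device section); the Gaussian CDF and its inverse come from
`scipy.special.ndtr`/`ndtri` with fractions clipped to `[1/(2(t+1)),
1 − 1/(2(t+1))]` before inversion. All randomness flows from
`substream(seed, *labels)` — a PCG64 generator keyed by the root seed plus a
stable hash of the label tuple (module, trial, pixel, …) — so runs are
bitwise reproducible and adding levels, pixels or trials never perturbs
existing streams. Degenerate inputs are rejected with diagnostics: non-finite
voltages, thresholding currents outside (floor, ceiling), negative
illuminance, constant images in correlation traces, single-class training
sets, empty calibration sets.
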