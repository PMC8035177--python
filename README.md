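# spikecoder

A behavioral simulator of a biomimetic spike encoder: a dual-gated MoS₂
field-effect transistor whose stochastically sampled top gate converts analog
stimulus voltages into spike trains, the photodiode front end that produces
those voltages from light, and the ANN-to-SNN conversion pipeline that
classifies spike-encoded images with integrate-and-fire neurons.

Spiking neural networks need hardware encoders that play the role of sensory
neurons: something that turns an analog quantity (illuminance, pixel
intensity) into stereotyped all-or-none events in time, with the inherent
stochasticity found in biological sensory transduction. This package
reproduces, as a calibrated numerical model, the behavior of such an encoder
and everything downstream of it, for computational-neuroscience and
neuromorphic-engineering work where the physical device is replaced by its
transfer characteristics.

## The model in brief

The encoder is an n-type FET with two gates acting through one effective
drive, `V_eff = V_PSV + (C_TG/C_BG) · V_TG`, where `V_PSV` is the analog
stimulus on the back gate and `V_TG` a sampling pulse on the top gate. The
drain current follows a monotone log-current map (exponential subthreshold
rise, soft knee, pinned post-threshold current, leakage floor); a **spike** is
registered whenever the current exceeds a thresholding current `I_ST`. The
stimulus at which that happens — the spiking threshold `V_ST` — is affine in
the sampling-gate voltage with slope `−C_TG/C_BG ≈ −2.2`, independent of
`I_ST`.

Three neural codes are implemented by shaping the sampling pulses:

* **rate** — pulse amplitudes drawn i.i.d. from `N(μ_TG, σ_TG²)`. A pulse
  spikes exactly when its amplitude exceeds the stimulus-dependent gate
  threshold, so the per-pulse spike probability is the Gaussian CDF
  `Φ((V_PSV − V_mid)/(2.2·σ_TG))`; the statistic is the firing rate (inverse
  mean interspike interval, 100 Hz ceiling at `t_p = 10 ms`).
* **count** — amplitudes ramp to larger magnitudes over the 32-pulse window
  (plus `N(0, σ_TG²)` noise); the statistic is the spike count.
* **timing** — the mirror-image ramp; the first spike deactivates sampling
  and its 1-based index (time to first spike) is the statistic, so stronger
  stimuli spike earlier and cost less energy.

Per-trial encoding energy averages gate charging plus drain dissipation over
the `N`-pulse window:

    E_en = (1/N) · Σᵢ ( ½·C_TG·V_TG,i² + I_PSC,i·V_DS·t_p )

which lands in the 0.2–4.8 pJ range across the 0–5 V stimulus window at the
default calibration.

For classification, a bias-free 784-100-10 rectifier network is trained by
mini-batch gradient descent, then converted to a spiking network: ReLU units
become integrate-and-fire neurons, `V_mem(t+1) = V_mem(t) + Σ w·X(t)`, firing
and resetting to zero when `V_mem` crosses a per-layer threshold set by
threshold balancing (the maximum pre-activation over encoder-generated
calibration spike trains).

## Worked example

Encode the 0–5 V stimulus grid with the reference rate protocol
(`μ_TG = −2.5 V`, `σ_TG = 0.8 V`, 32 pulses × 16 trials, `I_ST = 500 pA`):

```python
import numpy as np
import spikecoder as sc

dev = sc.default_calibration()
prog = sc.rate_program(seed=1)
results = sc.run_encoding_sweep(np.arange(0, 5.5, 0.5), prog, dev, i_st=5e-10)
tab = sc.sweep_table(results)
tab["energy_pJ"] = tab.pop("energy_per_spike") * 1e12
print(tab.round(2).to_string(index=False))
```

```
 level  statistic  statistic_std  energy_pJ
   0.0       1.95           4.42       0.23
   1.0      34.67          39.65       0.58
   2.0      16.66           6.52       1.39
   3.0      34.52           8.35       2.44
   4.0      54.58           9.23       3.72
   5.0      67.42           9.37       4.63
```

(abridged to whole-volt levels). `statistic` is the mean firing rate in Hz:
it rises monotonically with stimulus intensity in expectation — single-seed
16-trial means still wobble at the dim end, where the interspike-interval
estimator has heavy tails (the 39.65 Hz error bar at 1 V is that tail). The
across-trial standard deviation averages ≈10 Hz over the 11 levels, and the
window-averaged energy climbs from 0.23 to 4.63 pJ as more pulses spike.

The same protocol drives images and classification from the command line:

```bash
spikecoder fixtures --kind gradient --shape 64x64 --out gradient.pgm
spikecoder encode-image --in gradient.pgm --mode rate --seed 1 \
    --out spikes --cc cc.csv            # Pearson CC reaches ~0.99 at t=512
spikecoder fixtures --kind blob-digits --classes 10 --count 600 --out digits/
spikecoder snn-train   --images digits/ --out model.npz
spikecoder snn-balance --model model.npz --images digits/ --out model.npz
spikecoder snn-infer   --model model.npz --images digits/ --timesteps 300
```

`snn-train`/`snn-infer` also read MNIST IDX files directly (supply your own
copies; nothing is downloaded) to reproduce the full-scale digit benchmark.

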