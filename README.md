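# hairbundle

Analysis of mechanically coupled hair-bundle oscillations under efferent
stimulation.

Hair bundles of the inner ear oscillate spontaneously (5–100 Hz, tens of
nm): the bundle hops between a channel-closed and a channel-open state, so
its position histogram is bimodal. When several bundles contact an
overlying membrane they couple mechanically and synchronize, and
activating the efferent nerve reshapes their dynamics. This package
provides the full analysis chain for such experiments — and a synthetic
generator of coupled active-bundle dynamics so every stage can be
verified without recordings:

* **tracking** — sub-pixel spot positions from image stacks
  (intensity-weighted centroid + Levenberg–Marquardt 2-D Gaussian fit),
  projected onto the principal direction of motion;
* **preprocessing** — polynomial / moving-average detrending in series,
  and segmentation into pre / during / post stimulus windows;
* **oscillation profile** — Hartigan's dip statistic (exact, with a
  bootstrap p-value) plus a kernel density estimate classify a trace as
  oscillatory; amplitude = half the mode separation, open probability
  P_open = density mass above the antimode, frequency from the Hilbert
  analytic phase;
* **synchronization** — zero-lag normalized cross-correlation
  cc(x,y) = cov(x,y)/(σ_x σ_y); cells with cc > 0.2 against the membrane
  trace (the threshold is 4–5 null σ with σ ≈ 0.046) count as coupled;
  correlation matrices can be rearranged to expose partially
  synchronized (chimera-like) ensembles;
* **Kolmogorov entropy** — the truncated rate K ≈ S₁ − S₀ (nats per
  delay τ) of a binary symbolic partition of the D = 5 delay embedding
  (2⁵ = 32 cells); 0 for periodic motion, ln 2 at the noise ceiling;
* **pipeline** — percent changes, coupled-vs-control Welch t-tests and
  report tables over a whole battery of pulse-train (5–100 Hz) or
  step (25–200 µA) efferent protocols.

## Worked example

Simulate six plate-coupled bundles through a 10/10/10 s protocol with a
150 µA efferent step, then profile one cell and the ensemble per segment:

```python
import numpy as np
from hairbundle import (CouplingConfig, EfferentDrive, default_params,
                        simulate_bundles, detrend, segment,
                        classify_oscillatory, amplitude, open_probability,
                        mean_instantaneous_frequency, correlation_matrix,
                        kolmogorov_entropy)

params = default_params(6, seed=42)            # natural frequencies 10-30 Hz
coupling = CouplingConfig.uniform(6, k=0.35)   # rigid-plate coupling
drive = EfferentDrive(kind="step", intensity=150.0)
run = simulate_bundles(params, coupling, drive, fs=500, duration=30, seed=42)

for name in ("pre", "during", "post"):
    segs = np.array([getattr(segment(detrend(tr, 500), run.protocol),
                             name).samples for tr in run.traces])
    mem = getattr(segment(detrend(run.membrane_trace, 500), run.protocol),
                  name).samples
    osc, dens = classify_oscillatory(segs[0])
    freq = mean_instantaneous_frequency(segs[0], 500)
    cc = correlation_matrix(segs, mem)
    ke = kolmogorov_entropy(segs[0], 500)
    print(f"{name:7s} osc={osc}  amp={amplitude(dens):5.1f} nm  "
          f"p_open={open_probability(dens):.2f}  f={freq.mean_hz:5.1f} Hz  "
          f"K={ke.k_nats_per_tau:.3f} nats/tau  "
          f"<cc_mem>={cc.membrane_cc.mean():.2f}")
```

prints

```
pre     osc=True  amp= 31.2 nm  p_open=0.51  f= 24.6 Hz  K=0.408 nats/tau  <cc_mem>=0.83
during  osc=True  amp= 29.2 nm  p_open=0.35  f= 33.7 Hz  K=0.461 nats/tau  <cc_mem>=0.77
post    osc=True  amp= 31.1 nm  p_open=0.48  f= 24.6 Hz  K=0.401 nats/tau  <cc_mem>=0.83
```

During the step the cell oscillates faster (24.6 → 33.7 Hz), with smaller
amplitude, lower open probability (the bundle spends more time with its
channels closed — the oscillation becomes spike-shaped), higher entropy
(more irregular motion), and slightly reduced synchronization with the
membrane — all of which recover after the stimulus ends. A pulse-train
drive instead entrains the coupled group 1:1 to the drive frequency.

See `docs/methods.md` for the oscillator model, the efferent drive
mapping, every estimator's definition, and the numerical choices.

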