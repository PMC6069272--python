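# meaflow

Sample-synchronous, bit-faithful streaming processing of multi-electrode-
array (MEA) biosignals: fixed-point filters, adaptive event detectors,
closed-loop trigger routing with artifact blanking, and a ground-truthed
synthetic signal generator.

## Who this is for

Electrophysiologists and neuroengineers who process multichannel
extracellular recordings — neural cultures spiking and bursting, local
field potentials, or the sub-Hz slow potentials of pancreatic islets — and
who need the *exact* semantics of a real-time, full-hardware processing
chain: integer arithmetic, constant latency, runtime-tunable parameters,
and deterministic, replayable behavior.  `meaflow` models such a chain in
software, down to the shifts and truncations, so that detection algorithms
can be designed, calibrated and verified before (or instead of) committing
them to hardware.

## The model in brief

A processing chain is a DAG of units that each advance once per sample
period ("tick").  The unit library is small and composable:

- **Filters** — first-order IIR sections with power-of-two coefficients,
  `y_n = y_{n-1}(1 − 2^-k) + x_n 2^-k`, cutoff `Fc = 1/((2^k−1)·2π·Ts)`,
  cascaded up to 8th order with low/high/band-pass taps; and a streaming
  stationary (à-trous) wavelet transform with integer kernels,
  `d^j_n = Σ_k g[k]·a^{j-1}_{n−2^j k}`.
- **Decision units** — a closed-loop noise estimator that regulates its
  output so 15.9 % of samples exceed it (the one-sided Gaussian exceedance
  at +1σ, hence an estimate of σ itself); a two-threshold hysteresis
  comparator; a leaky event counter (`C_n = max(C_{n-1} + X_n·s_U − s_D, 0)`,
  firing at `Q`); an alternating extrema detector with amplitude gate Δ;
  and a shift-add spatial averager using `A = ⌊2^W/N⌋`.
- **Combined detectors** — adaptive AP detection (threshold =
  multiplier × σ̂ on a band-passed or wavelet-transformed signal), LFP
  detection, burst detection with spike cleaning, cross-channel
  synchronization ("more than m events in w ticks"), event-frequency and
  plateau-fraction meters, slow-potential detection in the 0.2–2 Hz band,
  and four-bank channel sorting with a user logic expression.
- **Output control** — event-to-trigger routing with pulse stretching and
  0–25 ms post-stimulus blanking of detection (never of acquisition).
- **Cost model** — the clock-cycle and memory-bit cost of each unit's
  hardware realization, affine in the channel count (e.g. σ estimator
  `9N+4` cycles; adaptive AP detection `16N+6` cycles, `512N` bits).

All state is integer and every run is bit-reproducible.  See
`docs/methods.md` for the full account.

## A worked example

`examples/02_adaptive_spike_detection.py` generates 21 s of one synthetic
channel — Gaussian noise of 20 LSB with 1 ms biphasic spikes of 120 LSB
peak (SNR 6) inserted at 10 Hz — and runs the linear adaptive detector at
4 × σ̂ with a 3 ms cleaning period:

```
$ python examples/02_adaptive_spike_detection.py
true spikes:        203
detections:         195
sensitivity:        0.956   (fraction of true spikes found)
precision:          0.990   (fraction of detections that are real)
final sigma est.:   20.6 LSB on the band-passed signal
```

Sensitivity is the fraction of inserted spikes matched by a detection
within ±1 ms; precision the fraction of detections matching a real spike.
The σ estimate printed last is the converged closed-loop noise estimate on
the band-passed signal — no per-channel threshold was ever set by hand.

The other examples cover the filter/cutoff algebra (`01`), islet
slow-potential monitoring under a glucose step (`03`), closed-loop
triggering with blanking (`04`), and declarative chain configuration with
the hardware cost model and recording budget (`05`).

## Command line

A thin CLI wraps the library for shell use:

```
meaflow synth --preset neural --seed 7 --duration 60 --out rec.bin --truth truth.csv
meaflow run --config chain.yaml --input rec.bin --out-events events.csv
meaflow budget --channels 64 --rate 10000 --bits 16 --card 32GiB
meaflow cost --kind ap_detect --channels 60
meaflow validate-config chain.yaml
```

Recordings are interleaved little-endian int16 with a JSON sidecar; event
logs are CSV; chain configurations are YAML or JSON.

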