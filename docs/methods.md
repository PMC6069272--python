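# Methods

`meaflow` is a software model of a sample-synchronous, fixed-point
processing architecture for multichannel extracellular recordings: the kind
of signal chain a full-hardware (FPGA) electrophysiology platform runs on
64 channels at 10 kHz.  This note describes the model, the algorithms of
each unit, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical and design choices made where
the design was genuinely open.

## The execution model

The atomic time step is one **tick** — one sample period `Ts`.  A chain is
a DAG of processing units; on each tick every unit advances exactly once,
in fixed topological order, consuming its inputs from the same tick.
Within this model all units are combinational (zero group delay in ticks);
the latency a hardware realization would exhibit is reported separately by
the cost model in clock cycles and never simulated.  Consequences:

- **Determinism.** All state is integer, all arithmetic exact, all shifts
  two's-complement arithmetic shifts (Python `>>`).  Identical input +
  identical configuration ⇒ bit-identical output, on any platform.
- **Causality.** A unit's output at tick *t* depends only on inputs at
  ticks ≤ *t*; feedback loops between units are rejected at build time (in
  the real system the only loop closes through the biological preparation).
- **Consistent reconfiguration.** Parameters are either *static* (channel
  count, data width, filter order, wavelet levels — fixed at build) or
  *dynamic*.  Dynamic updates are queued and applied atomically at the next
  tick boundary, quantized to the parameter's fixed-point grid and clamped
  to its documented range (with a warning); every applied update is logged
  with the tick from which it took effect.  No unit ever observes a
  half-applied value, so recorded data stay coherent through an update.

State initializes to zero everywhere (power-on register reset), with one
exception: the extrema detector seeds its running maximum/minimum from the
first sample so a nonzero baseline cannot fabricate an event.

Samples are signed `W`-bit integers (default `W = 16`, the ADC width).
Where an operation can exceed full scale (high-pass differences, filter
accumulators) the implementation saturates rather than wraps, and counts
saturation events; silent wrap-around would corrupt detection invisibly.

## Filters

**First-order power-of-two IIR.**  Each section evaluates
`y_n = y_{n-1}(1 − 2^-k) + x_n 2^-k` — one shift-and-add per tick, cutoff
`Fc = 1/((2^k − 1)·2π·Ts)`, `k ∈ {0..17}` (`k = 0` is a pass-through).  The
accumulator keeps `G = 19` guard fraction bits (max `k` plus two).  A bare
16-bit accumulator would exhibit a dead zone for large `k` (the increment
`x·2^-k` truncates to zero); with `G ≥ k` the per-tick truncation error is
below one output LSB and does not accumulate — verified against a
double-precision oracle over 10⁵ samples.  One fixed `G` for all sections
(rather than per-`k`) lets `k` change at runtime without rescaling state.

Up to eight sections cascade in a *filter unit* with three taps: with
`y[0] = x` and `y[j]` the cascade output after section `j`,
`lp = y[lp_tap]`, `hp = x − y[hp_tap]`, and `bp = y[lp_tap] − y[hp_tap]`
(the high-pass tap must sit deeper in the chain, so its cumulative cutoff
forms the lower band edge).  `hp + y[hp_tap] = x` holds exactly.

**Stationary wavelet transform.**  The streaming à-trous transform computes
detail/approximation coefficients by integer convolution with kernels
dilated by powers of two, from per-level zero-initialized delay lines,
rescaled by an arithmetic shift (`coeff_scale` a power of two).  Two
dilation conventions are implemented: `"paper"` uses lag `2^j` at level `j`
on the level-`j−1` approximations, the `"textbook"` convention uses
`2^(j−1)`; they differ only in how fast the kernels stretch with level, and
the streaming output matches a brute-force dilated-convolution oracle
integer for integer under both.  The default mother wavelet is Haar with
integer kernels `g = (1, −1)`, `h = (1, 1)`, `coeff_scale = 2`.  Kernels of
length `L+1` are indexed `0..L`.

## Elementary decision units

**Sigma regulator.**  Instead of computing moments, the noise-amplitude
estimator regulates its output to a fixed exceedance quantile: per tick,
`est += s_up` if `x > est`, else `est = max(est − s_dn, floor)`.  At
equilibrium the fraction of samples above the estimate is
`s_dn/(s_up+s_dn)`; the defaults 841/159 pin it at 15.9 %, the one-sided
probability that a zero-mean Gaussian sample exceeds +1σ, so on Gaussian
noise the estimate converges to σ itself (to within 0.2 %, since
z(15.9 %) = 0.9986).  Because only the marginal quantile matters, sparse
spiking barely perturbs it — which is why the unit provides a
activity-immune image of noise amplitude for thresholding.

The estimate carries `F = 14` fixed-point fraction bits and the steps are
expressed in estimate LSBs.  The regulator is a constant-step stochastic
approximation, so its equilibrium ripple scales with √(step size): at
`F = 8` the ripple reaches ~25 % of a 20-LSB noise sigma (drowning any
threshold margin), at `F = 14` it is a few percent while cold-start
convergence from zero still takes only a few thousand ticks (~0.3 s at
10 kHz for typical amplitudes).  Detection scoring therefore excludes a 1 s
settle period.  A configurable `floor` bounds the estimate from below for
quantization-degenerate channels (see LFP detection).

**Hysteresis comparator.**  Asserts at `t_set`, deasserts below `t_clear`,
holds in between; equal thresholds degrade to a plain `x ≥ t` comparator.

**Leaky event counter.**  `v = count + x·s_u`; fires when `v ≥ q`; the
count then resets to zero (one-shot mode, used for synchronization) or
continues as `max(v − s_d, 0)` (free-running mode, used for burst
envelopes).  The constant leak makes the count a measure of recent activity
against a reference rate of `s_d/s_u` events per tick.

**Extrema detector.**  A two-state machine: while seeking a maximum it
tracks the running maximum `M`; when the signal drops to `M − Δ` it emits a
maximum event and re-arms for a minimum seeded at the current sample
(mirrored for minima).  Events strictly alternate and ripples smaller than
Δ peak-to-peak are ignored.  The two-clause update equations for `M`/`m`
are not executable as literal single-state rules; the second clause is
realized as this re-arming transition.  The peak-to-peak excursion between
the last two extrema is exposed for amplitude gating.

**Spatial averager.**  The reciprocal is computed once as a Euclidean
division `A = ⌊2^W / N⌋`; a frame's selection sum `S` is then averaged by
shift-add over the set bits of `A`: `Y = Σ_{i:aᵢ=1} (S >> (W−i))`.  Each
term truncates, so `|Y − S/N| ≤ popcount(A) + N·max|X|/2^W` — verified
against the exact rational mean on 10⁶ random 64-channel frames.  Taking
the specified per-bit divisor as `2^(i+1)` would halve the mean; the
implementation uses the decomposition above, which reproduces the stated
intent (`N = 1` passes through exactly).

## Combined detectors

**AP detection** composes band isolation → sigma regulator → comparator at
`multiplier × σ̂` (multiplier quantized to 1/256), one event per rising
crossing, with an optional cleaning (refractory) period that discards the
secondary crossings a multiphasic waveform can produce.  Three variants:

- *linear*: the default band-pass is `k = [2, 4]` (~106–530 Hz at 10 kHz).
  The low-pass edge matters: it averages the 2–3 samples of a millisecond
  spike's depolarization lobe, acting as a crude matched filter.  A bare
  227 Hz first-order high-pass was measured to cost ~20 % of peak amplitude
  while leaving the detection statistic white, whose 4σ upcrossing rate
  then floors precision; the band-pass raises peak-to-noise to ~8:1 at
  input SNR 6 and correlates the noise so false crossings become rare.
- *wavelet*: detection on `|d[j_det]|` with σ̂ estimated on level `j_thr`.
  Defaults: Haar, 2 levels, `j_det = j_thr = 2` — estimating the threshold
  on the detection level keeps the multiplier scale-consistent.  A split
  (detect on level 4, threshold from level 1) is configurable but performs
  poorly with Haar at 10 kHz, where level 4 smears a 1 ms biphasic wave to
  near-zero mean.
- *fixed_threshold*: plain comparator, optionally after a filter.

When the threshold is non-positive (e.g. the σ estimate still at its
power-on zero) the comparison is strict, so silence never fires.

**LFP detection** is the linear variant in a ~1.6–106 Hz band with a
*second-order* upper edge (`k = [4, 4, 10]`): one first-order pole leaves
~−20 dB of a 1 kHz transient, enough to masquerade as a field potential;
two poles give ~−40 dB.  The σ estimate has a default floor of 4 LSB —
inside this narrow band the white front-end noise shrinks to ~2 LSB and an
unfloored adaptive threshold collapses onto the integer quantization grid
and chatters.

**Burst detection** gates incoming AP events with a cleaning window
(minimum inter-event interval `clean_window + 1` ticks), integrates cleaned
events in a free-running counter (defaults `s_u = 500`, `s_d = 1`:
reference rate 20 Hz at 10 kHz), and reads the count through a hysteresis
comparator (`t_set = 1500`, `t_clear = 750`): the envelope rises after
roughly three rapid spikes and clears as the count drains, giving separate
onset and offset time sensitivities.

**Synchronization detection** mixes events from masked channels into one
one-shot counter; channels contributing since the counter was last empty
are flagged on firing.  The window rule "more than `m` events within `w`
ticks" maps to `s_u = w/2`, `s_d = m·s_u/w` (leak drains one event's worth
over exactly `w` ticks) and `q = m·s_u + 1`.  The demonstration rule —
more than 4 APs across 6 channels in 25 ms — becomes `s_u = 125`,
`s_d = 2`, `q = 501` at 10 kHz.  A leaky counter is a sliding-window
*approximation*: events are forgotten gradually rather than expiring
abruptly, so widely spread in-window patterns score lower than clustered
ones.  Setting `q = (m+1)·s_u` instead would tolerate no leak at all and
fire only on exactly simultaneous events.

**Event frequency / FOPP.**  The 0/1 event indicator (or burst envelope) is
scaled to 2^14 and smoothed by one or two first-order sections with unit DC
gain; the mean is read back as events/s (or duty-cycle fraction).  The
scaling is required because the integer filter quantizes at 1 LSB: without
it a 1 % event probability would be unrepresentable.  The time constant is
`(2^k − 1)·Ts`.

**Slow-potential detection** band-passes to ~0.19–1.56 Hz (`k = [10, 13]`),
runs the extrema detector with amplitude threshold Δ on the filtered
signal, and emits an event per extremum of the configured polarity (default
maximum, matching the convention that spikes ride the downward phase; the
choice is configurable since either end of the oscillation is a valid
marker).  A minimum peak-to-peak gate and a refractory period (the
counter's role in the hardware block, interpreted here as one event per
recovery period) are available.  With a sinusoid of input amplitude `A` in
the band, the filtered peak-to-peak is `2·g·A` with `0.5 < g < 1`, so
events appear for `A > Δ` and never for `A < Δ/2`.

**Channel sorting** accumulates per-epoch statistics (peak |raw| amplitude,
event counts per type, synchronization contribution), evaluates four
criterion banks at the epoch boundary (default 1 s, or on an explicit
close request), combines them channel-wise with a user boolean expression
over `b1..b4` (parsed from a restricted `ast`, no evaluation of anything
else), and latches the result until the next boundary regardless of
within-epoch statistics.

## Output control

The **trigger router** maps any set of event sources onto `M` lines
(any-to-any OR), asserting on the event tick itself (zero latency in
ticks) and stretching pulses to `pulse_ticks`, with retrigger extension.
The **blanker** opens a gate of 0–25 ms (0.1 ms steps) on the trigger tick
and drops detection events on masked channels while it is open; a
retrigger restarts the window.  Only event streams are gated — raw samples
pass untouched, modeling digital (not analog) artifact rejection.
Triggers themselves are not blanked by default (self-retrigger is the
experimenter's choice).  Stimulator protocols beyond a TTL line are out of
scope; the trigger log records (tick, line, rise/fall).

## Cost model

`estimate_cost(kind, N, params)` evaluates the documented affine
latency/memory formulas of each unit class (e.g. sigma estimator `9N + 4`
cycles; linear adaptive AP detection `16N + 6` cycles, `512N` bits;
`k`-section filters `2Nk + 2`).  Ranged rows (wavelet variants) take a
`bound` parameter for the min/max end of the documented range.  The burst
detector's memory figure is transcribed verbatim as `128N × 216` bits with
a warning note: the documented factor is ambiguous (plausibly `2^16`) and the
value is not used functionally.  Trigger routing has no cycle formula
(equipment-dependent); requesting a kind with no documented formula raises.
Clock cycles are never converted to seconds: the system clock frequency is
not part of the model.

## Recording budget

`recording_budget` uses binary megabytes (2²⁰ bytes): 64 channels × 10 kHz
× 2 bytes × 60 s = 73.2421875 ≈ 73.24 MB/min, which is exactly the
reference figure — decimal units would give 76.8.  The 7-hour capacity
check therefore reads the 32 GB card as 32 GiB (447 min ≈ 7.5 h); a
decimal 32·10⁹-byte card would fall 3 minutes short of 7 h, so the binary
convention is applied consistently.

## Synthetic recordings

The generator produces phenomenological stand-ins with controlled
statistics, not biophysics:

- **Noise**: white Gaussian per channel (the σ regulator's working
  hypothesis), rounded to integers and clamped to 16 bits.  An optional
  coloured component is deliberately absent from the defaults.
- **APs**: a 1 ms difference-of-Gaussians template (sharp positive lobe,
  σ = 0.12 ms; negative lobe 0.6 of peak at +0.3 ms; near-zero area so
  spectral energy sits above 200 Hz), inserted at Poisson times — tonic
  (default 10 Hz, an active dissociated culture) or grouped into bursts
  (intraburst rate > 10 Hz, fixed burst length, periodic burst onsets with
  a random phase).  Ground truth records the template peak tick.
- **LFPs**: damped sinusoids below 100 Hz at Poisson onsets.
- **SPs**: an asymmetric cycle (half-cosine rise over 30 % of the period,
  half-cosine decay over 70 % — continuously differentiable, so energy
  concentrates at the fundamental) at 0.2–2 Hz, shared in phase across
  channels (syncytial behaviour); a stepwise protocol can reschedule
  frequency/amplitude mid-recording, emulating glucose steps.  Truth
  records each cycle's maximum and minimum ticks.

What passing tests on these signals show: correct arithmetic, calibrated
thresholds, and recovery of events whose statistics match the model.  What
they do not show: robustness to electrode drift, coloured noise, waveform
diversity, overlapping spikes from multiple units, or real stimulation
artifacts — none of which the generator emulates.

## Problem sizes used in verification

The verification suite runs at desk scale: σ-calibration on 10⁶ samples;
filter-vs-oracle comparisons on 10⁴–10⁵ samples; averager bound on 10⁶
64-channel frames; detection recovery on ~20 s single-channel records with
~200 true events (scores exclude the first second while the σ estimate
converges); slow-potential protocols of 100 s.  Event-count results on
living cultures are not reproducible from synthetic data and are replaced
throughout by the property checks above.

## Known limitations

- The tick model hides intra-sample pipeline structure; per-unit hardware
  latency is available only through the cost model.
- The leaky-counter window rule is an approximation of a true sliding
  window (see above).
- First-order band edges roll off at 20 dB/decade; where that is too
  gentle (LFP upper edge) sections are stacked, but sharper filters are
  out of scope by design.
- The sigma regulator assumes a unimodal, roughly symmetric noise
  distribution; heavy-tailed noise shifts the 15.9 % quantile away from σ.
- Wavelet detection defaults are tuned to Haar at 10 kHz; other mother
  wavelets must be supplied as integer kernel pairs with a power-of-two
  scale.
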