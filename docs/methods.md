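# Methods

## Model

`stpsim` models the pulse-train response of an ion-doped polymer
electrolyte film as two coupled per-pulse weight recursions, one per
response branch.  The physical picture: the film starts in an electrically
neutral state (the analogue of a full pool of neurotransmitter release
sites).  Each pulse releases a fraction `f` of that state, producing the
charging peak; during the following OFF interval the state recovers a
fraction `k` of its deficit.  Symmetrically, each pulse builds an
interfacial ion-polarization layer (the analogue of residual presynaptic
calcium) toward a ceiling `I_F`, and the layer decays by a fraction `f`
during each interval; its discharge current gives the facilitating peak.
With weights normalized to the first pulse:

```
depression:    S_1 = 1,  S_{i+1} = S_i(1-f) + k(1 - S_i(1-f)),   W_i = I_D S_i,  I_D = 1
facilitation:  W_1 = 1,  W_{i+1} = (1-f)W_i + k(I_F - (1-f)W_i),  I_F > 1
```

Both recursions are affine in `W_i` with contraction ratio
`rho = (1-f)(1-k)`, hence the closed form

```
W_i = W_inf + (1 - W_inf) rho^(i-1),      W_inf = I k / (1 - rho),
```

used interchangeably with the iteration (they agree to round-off; the test
suite checks the fixed point against a 1e5-step iteration at 1e-10
relative).  The event order is release-then-recover: the alternative
(recover-then-release) fails the hard constraint that both branches hold
`W_i ~ 1` at the 1 Hz calibration parameters.

`f` and `k` are treated as per-interval fractions, functions of the pulse
rate only; no separate `exp(-dt/tau)` kernel is applied, because the
calibrated laws already fold the interval length into the fractions.

### Frequency laws

Over the calibrated band (1–142 Hz, 0.5 V amplitude, 5 ms width) the
fractions follow

```
f_D(nu) = 0.00277 + 0.001 nu              (linear, per Hz)
k_D(nu) = 0.174 + 0.511 exp(-0.0171 nu)
k_F(nu) = 0.213 + 0.319 exp(-0.0354 nu)
A(nu)   = 1.595 - 0.00333 nu
f_F(nu) = 1 - (1 - A k_F)/(1 - k_F)  ==  k_F (A - 1)/(1 - k_F)
I_F     = 1.582 (shared across frequencies)
```

All four fraction laws must evaluate inside (0, 1] across the band; this is
asserted when a `FreqLawCoefficients` is constructed.  Outside the band the
laws are extrapolated with a logged warning and the fractions clamped into
(0, 1].  Grid cells are displayed with decimal round-half-up to three
places; two cells of the composite `f_F` (at 20 and 142 Hz) sit exactly on
a rounding boundary and are excluded from exact-match comparisons (they
still agree within ±0.001).

Mixed-frequency pulse packages are evaluated by mapping each interval's
instantaneous rate `nu_i = 1000/(width + dt_i)` through the laws and
applying the recursion with per-step fractions; a uniform train reduces
exactly to the constant-parameter recursion.

## Trace digital twin

Within a pulse the charging current is `plateau + A_1 e^{-t/tau_1} +
A_2 e^{-t/tau_2}`; after the pulse the discharge is a biexponential of
opposite sign.  Pulse *i*'s ON segment is scaled by `W_i(D)` and its OFF
segment by `-W_i(F)`.  Each discharge tail is truncated at the next pulse
onset: physically, re-applying the external field terminates the
back-diffusion current, and computationally this makes onset/offset peak
reads exactly proportional to the weights, so synthesize → extract →
normalize is the identity (the high-frequency trace still shows the
characteristic un-decayed discharge at the next pulse front).  Linear
superposition of tails under later segments was considered and rejected:
at 142 Hz the residual tail is half the size of the next discharge peak,
which would make extracted facilitation weights systematically wrong.

Segment boundaries are snapped to the sample grid (default period 0.5 ms;
at least five samples per pulse width are required) so every onset and
pulse end lands on a sample and peak reads carry no sub-sample phase
error.  Peaks are read as the extreme sample inside a one-width window at
each onset (charging) and after each pulse end (discharging).  The trace
default time constants are synthetic fixtures, not measured values: charge
1 and 20 ms (one sub-width, one super-width term), discharge 5 and 100 ms
so that the discharge relaxes below 1% of its peak within the 520 ms
full-decay period, plateau 0.2 with amplitude split 0.6/0.4.  Intervals of
at least 520 ms restore the device state: both extracted weight sequences
stay within 1% of unity.

## Synthetic data

The generator emulates the statistical structure of repeated device
measurements: recursion-generated weight envelopes with multiplicative
Gaussian noise applied to the peaks (default sd 2%, a fixture — the
source measurements report only qualitative few-percent device-to-device
variability), renormalized so `W_1 = 1` exactly as measured peak ratios
would be; optional additive white noise on trace samples.  Everything is
deterministic under its integer seed.  What it does **not** emulate:
environmental drift (humidity, temperature), correlated noise across
pulses, trace-shape variation with pulse number (the measured time
constants drift slightly along a high-frequency train), or amplitude
nonlinearity.  Passing tests therefore demonstrate correctness of the
pipeline under stationary multiplicative noise, not robustness to real
laboratory drift.

## Inference

Per-sequence fits minimize ordinary least squares on the weights (robust
soft-L1 is available but off by default) with `f, k` bounded in (0, 1],
via trust-region reflective least squares from multiple starts: a fixed
grid of five `(f, k)` points with small deterministic jitter, plus a
method-of-moments start (tail level → `W_inf`, lag-1 regression of the
deviations → `rho`), added because noisy near-flat sequences otherwise
strand the optimizer in a wrong basin.  Noiseless self-generated input is
recovered to optimizer precision (≪ 1e-6) with residual RMS below 1e-10.

**Identifiability.**  A constant-frequency sequence pins exactly two
quantities, `W_inf` and `rho`.  Consequences:

* Depression (`I = 1` fixed) is identifiable from any non-constant
  sequence; an all-ones sequence leaves the `f(1-k) = 0` valley flat, and
  the fit flags it (`identifiable=False`).
* The facilitation ceiling is **not** identifiable from weight sequences:
  `(f, k, I)` has an exact one-parameter family (`I → cI`, `k → k/c`, `f`
  re-solved), and the flatness survives a joint shared-ceiling fit across
  frequencies.  The ceiling therefore enters the model as a convention,
  like the depression baseline: panel fits pin `I_F` to the calibrated
  1.582 (caller-overridable); freeing it issues a warning and marks the
  fit non-identifiable.  Jacobian-based standard errors are reported as
  approximate artifact diagnostics, not measured uncertainties.

Panel fits average replicates per frequency before fitting and include a
free scale nuisance on pulses 2..n: measured weights are ratios to a noisy
first peak, so baseline noise rescales the whole tail of a sequence and
would otherwise masquerade as fast early decay.  Single-replicate fits
omit the nuisance (with per-point noise of the same size as baseline noise
the scale is weakly pinned and only inflates variance).  The law fits that
follow are inverse-variance weighted by each frequency's fit standard
errors and finally projected into the admissible fraction domain (noisy
extrapolation of the exponential laws to 1 Hz can otherwise push the
composite `f_F` above 1).

**Information limits.**  At low stimulation rates the sequences are flat
by construction (at 1 Hz, `1 - W_inf ≈ 0.0018` for depression) while the
noise fixture is 2% per peak.  With 100 replicates the averaged per-point
noise (~0.2%) equals the entire signal, so `f` — and to a lesser degree
`k` — cannot be recovered to 10% relative below roughly 50 Hz no matter
the estimator; the recovery acceptance test documents exactly which rows
meet the 10% contract (all depression rows from 62.5 Hz and facilitation
rows from 40 Hz) and which cannot.

## Numerical choices and problem sizes

* Saturation reporting: relative step < 1e-6.
* Optimizer tolerances 1e-15 (xtol/ftol/gtol), max 2000 evaluations.
* Law fitting needs ≥ 4 distinct frequencies per branch (exponential laws
  are otherwise underdetermined), ≥ 2 for the linear laws alone.
* Default study sizes mirror the calibration protocol: ten frequencies
  1–142 Hz, 40 pulses per train, 2% peak noise, 100 replicates per
  frequency; the noisy-recovery test aggregates 11 seeded panel
  realizations, and trace tests use 0.5 ms sampling with a 520 ms decay
  tail.

## Known limitations

* The recursion is phenomenological: no explicit vesicle-pool or ionic
  drift-diffusion state, so it cannot predict responses outside the
  pulse-train protocol family (e.g. arbitrary waveforms).
* The frequency laws are empirical fits valid on 1–142 Hz; extrapolation
  is flagged but unvalidated.
* The trace model's time constants are fixtures; the twin reproduces the
  qualitative trace anatomy, not a specific device's impedance.
* The facilitation ceiling is a convention (see identifiability), so
  absolute facilitation fractions inherit its scale.
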