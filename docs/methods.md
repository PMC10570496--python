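# Methods

## Model

`betadfc` treats each of the three nuclei — subthalamic nucleus (STN,
glutamatergic), external globus pallidus (GPe, GABAergic with
self-inhibition) and pedunculopontine nucleus (PPN, glutamatergic) — as a
single lumped population in the neural-mass tradition: the state of a
population is not a set of spiking cells but an average postsynaptic
potential per afferent channel, and rate-to-potential conversion happens
through a linear synaptic filter while potential-to-rate conversion
happens through a static sigmoid.  The assumptions this inherits are the
usual ones: spatial homogeneity within a nucleus, separation of synaptic
timescales from spike timescales (so only pulse densities matter), and
noise that enters additively through the external drives rather than
through intrinsic spiking variability.

Eight synaptic channels make up the state (three afferents to STN, three
to GPe, two to PPN), each a critically damped second-order filter

    v̈ = (g/x)·u − (2/x)·v̇ − v/x²,

with effective gain `g = λ·H` for internal pathways and `g = H` for
external drives.  The DC gain of a channel is `g·x`; this closed form is
used as a test oracle for the integrator.  A nucleus's LFP is the signed
sum of its channel potentials (inhibitory channels negative), and that
LFP is both the observable (spectra, indices) and the signal available to
the feedback controller — consistent with the view of the LFP as
summed synaptic currents.

## Parameters

Per-population constants (shared by both presets):

| population | H (mV) | x (s) | r (s⁻¹) | y (mV⁻¹) |
|---|---|---|---|---|
| STN | 20 | 0.006 | 300 | 0.1 |
| GPe | 20 | 0.014 | 400 | 0.1 |
| PPN | 20 | 0.005 | 200 | 0.1 |

`x` sets each population's intrinsic band (1/(2πx) ≈ 27, 11 and 32 Hz);
the STN–GPe loop interaction places the collective rhythm near 22 Hz.
Pathway gains λ₁–λ₅ (GPe→STN, STN→GPe, GPe→GPe, STN→PPN, PPN→STN):
normal (1.12, 19, 6.6, 10, 3), pathological (5, 20, 2, 13, 1).  The
pathological preset strengthens reciprocal STN–GPe coupling and weakens
GPe self-inhibition — the dopamine-depletion signature — which moves the
operating point across a Hopf-type boundary into a stable beta limit
cycle.  External drives are `mean + sd·ξ` per step with (27, 2, 20) s⁻¹
and sd 0.1 throughout; the sd is small enough that the external noise
perturbs, but never creates or destroys, the rhythm.

Presets ship as YAML (`betadfc/presets/*.yaml`); the loader rejects
unknown keys outright so a typo cannot silently fall back to a default.

## Stimulation

The controller is the linear delayed-feedback law `w(t) = K(v_src(t−τ) −
v_src(t))`, zero before its onset (1 s).  `w` enters the model as a
potential offset inside the target's sigmoid, `u = S(v + w)`: the
stimulation biases the population's firing without appearing directly in
the recorded LFP.  The alternative reading — adding `w` to the target's
pulse-density output — was evaluated and rejected: under it the A and B
presets lose their suppressive effect entirely, while the sigmoid-offset
reading reproduces all published preset behaviours.  No amplitude limiter
is applied to `w`; a clinical controller would saturate it, but the
model's sigmoids bound the effect of arbitrarily large `w` anyway.

Strategy presets: A = STN←STN-LFP (K=0.4, τ=25 ms), B = GPe←GPe-LFP
(−2, 2 ms), C = GPe←PPN-LFP (−2, 4 ms), D = STN←PPN-LFP (3, 8 ms).  The
sign pattern is structural: strategies targeting the excitatory STN
suppress only with K > 0, those targeting the inhibitory GPe only with
K < 0.  The C pairing deserves a note: descriptions of this family of
strategies sometimes state it with the roles of GPe and PPN reversed
(PPN stimulated with the GPe LFP).  That reversed pairing targets an
excitatory population with a negative intensity, which contradicts the
sign rule above, and numerically it fails to suppress the rhythm at
(−2, 4 ms) — or at any intensity in [−30, 30] at that delay — whereas
GPe←PPN-LFP at exactly (−2, 4 ms) reduces the summed OI by three orders
of magnitude.  The package therefore defines C as stimulating GPe with
the PPN-derived signal, the only reading consistent with both the sign
structure and the published operating point.

## Numerics

* **Integrator**: forward Euler, dt = 0.1 ms, T = 3 s (N = 30000 steps).
  Explicit Euler is the protocol's method, not a numerical-necessity
  choice; the stability limit of the fastest channel (dt < 2x = 10 ms) is
  two orders of magnitude away.  The hot loop is numba-compiled; a
  plain-Python single-step reference implementation is exposed as
  `step()` and the test suite asserts trajectory agreement between the
  two to 1e−9, including through the delay/feedback path.
* **Initial conditions**: all 16 state variables start at 0.  The first
  ~0.3 s transient is excluded from every metric (OI and extrema use the
  final second; stimulated-run spectra use the post-onset window), so
  initialisation only affects the discarded portion.
* **Noise convention**: one `numpy.random.Generator(PCG64)` stream per
  run, three standard-normal draws per step in fixed order (cortex,
  striatum, GPi), redrawn independently every step.  Runs are
  reproducible bit-for-bit from (seed, config).
* **Delay discretisation**: τ is rounded to the nearest whole step; at
  dt = 0.1 ms every preset delay is an exact multiple, so no rounding
  error enters.  The delayed sample is read from the simulated history
  itself (the onset at 1 s guarantees ≥ 1 s of genuine history, and
  configurations with τ > onset are rejected).  The feedback signal
  computed at step *i* acts in the same step's sigmoid evaluation — no
  hidden extra step of latency.
* **Degenerate inputs**: non-finite LFPs abort the run with the step
  index (reachable only with absurd dt; the sigmoids otherwise bound the
  drive); sigmoid exponents are clamped at 700 so extreme potentials
  saturate rather than overflow.
* **Step-size consistency**: under common random numbers (noise drawn on
  the coarse grid, held across fine substeps) halving dt leaves the
  dominant frequency in the same 1/3 Hz bin, and the OI discrepancy
  between dt and dt/2 shrinks by ≈0.5× again from dt/2 to dt/4 — the
  expected first-order signature.  OI itself carries an O(dt) amplitude
  bias of a few percent at the protocol's dt; conclusions should rest on
  OI ratios (suppressed vs baseline, spanning orders of magnitude), not
  on its third significant digit.

## Metrics

* **OI** is implemented literally as the sum of squared deviations from
  the window mean over the final second, divided by the number of samples
  in one second — i.e. the biased variance of the final-second window, in
  mV².  A natural alternative is its square root (an RMS amplitude, in
  mV); `oscillation_index(..., sqrt=True)` provides it but the quadratic
  form is the default and is what every sweep and test uses.
* **EI** is the mean of `w²` over samples from 1 s to 3 s — the window in
  which stimulation may act — so an always-off controller scores exactly
  0 and EI scales quadratically with signal amplitude.
* **Spectra** use a plain rectangular-window DFT of the mean-subtracted
  segment, one-sided, normalised so bins sum to the segment variance
  (Parseval is asserted in tests).  No taper and no peak interpolation:
  the dominant frequency is the raw argmax bin, reported at the window's
  native resolution (1/3 Hz for a full unstimulated run).  Unstimulated
  runs are analysed over the whole 3 s; stimulated runs over the
  post-onset 2 s, mirroring the transient-exclusion rule of OI.  Windows
  shorter than 1 s are rejected (resolution too coarse for beta-band
  statements).

## Sweeps and islands

`run_sweep` evaluates a (K, τ) grid cell-independently: each cell runs R
seeded replicates and averages OI per nucleus, EI and last-second LFP
extrema.  Replicate seeds are derived by hashing (base seed, K, τ,
replicate) through `SeedSequence`, so refining a grid never changes the
values of existing cells.  Diverged replicates are skipped and counted
out of `n_ok`; an all-diverged cell holds NaN.

"Suppressed" has no universal numeric definition at the population
level; the package defines it as replicate-averaged summed OI (three
nuclei) below 10 % of the summed unstimulated baseline — successful
control in this model undershoots that threshold by orders of magnitude,
so results are insensitive to the exact fraction (it is a parameter of
`suppressed_mask`/`island_center`).  The primary suppression island is
the largest 4-connected suppressed component of the grid, and its centre
is operationalised as the cell minimising summed OI (ties: smaller EI,
then smaller τ).  One caveat is documented deliberately: inside an
island the OI floor is flat (suppressed by 6–9 orders of magnitude), so
the argmin locates a shallow minimum of the residual noise floor rather
than a sharp optimum.  For strategies with narrow islands (A, B, C —
suppressed τ-bands of ~3–6 ms width at their preset intensities) this is
immaterial; strategy D's band is broad (≈3–20 ms at K = 3) and its
OI-minimising delay (≈12 ms) should be read as "anywhere in the band
works", not as a precise tuning prescription.

Default replicate count is 20, matching the study protocol for
single-point comparisons; grid sweeps default to 5 replicates per cell —
with cell-to-cell OI varying by orders of magnitude across an island
boundary, 5 replicates already pin the mask, and it keeps a full
4-strategy delay sweep (4 × 50 × 5 = 1000 runs) around ten seconds of
compute.

## What the noise generator does and does not emulate

The stochastic element is the Gaussian external drive: stationary white
noise of fixed small amplitude on three inputs.  This emulates
unmodelled afferent fluctuation well enough to test robustness of the
limit cycle and of its suppression, and it is what makes replicate
averaging meaningful.  It does not emulate real LFP data in other
respects: no 1/f background, no measurement noise on the recorded LFP
(the controller sees a clean signal), no nonstationarity or bursting
statistics, and no electrode/volume-conduction effects.  Passing tests
therefore demonstrate properties of the model under its stated drive —
not that the strategies would survive realistic sensing noise.

## Known limitations

* Three nuclei only; cortex, striatum and GPi are boundary inputs, so
  loop effects through them are absent.
* The feedback signal is unlimited in amplitude and the sensing path is
  noiseless and instantaneous apart from the designed delay τ.
* Forward Euler at the protocol's dt biases oscillation amplitude by a
  few percent (see Numerics); frequencies and suppression ratios are
  robust to this.
* Island "centres" from flat basins are reported as OI-argmin cells by
  convention; treat wide-island centres as bands (see Sweeps).
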