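# Methods

This note documents the model equations as implemented, the numerical
choices, what the synthetic data emulate (and what they do not), and the
design decisions taken where the underlying formulation left room.

## Model blocks

**Cell (LN) block.** The phototransduction stage is fixed: a causal
exponential kernel with τ_L = 40 ms, truncated at 8 τ and normalised to
unit sum, followed by the Hill-form voltage nonlinearity

    V(l) = −26.4 · l^4.92 / (l^4.92 + 0.542^4.92) − 45   [mV].

Unit DC gain means binary light maps the linear output into [0, 1], so
the cone spans −45 mV (dark) to ≈ −70.16 mV (sustained light). The
baseline LN model for bipolar cells instead uses a biphasic
photoreceptor impulse kernel

    k(t) ∝ −((t/(γτ_r))³ / (1 + t/(γτ_r))) · e^(−(t/(γτ_d))²) ·
           cos(2πt/(γφ) + τ_phase)

with τ_r = τ_d = 70 ms, φ = −π/5, τ_phase = 100 treated as a radian
phase offset (the printed form mixes units; see "Open formulation
choices"), and only the time-scale γ free. The kernel is normalised to
unit peak magnitude; any gain ambiguity is absorbed by the free
sigmoid that follows.

**Calcium drive.** u(V) = 0.078 · (41 − V) · g(V) + 0.05 with the
Boltzmann activation g(V) = 1/(1 + exp(−(V + 39.3)/4.88)). The drive
is strictly increasing over the working range [−75, −30] mV and floors
at the resting calcium term 0.05. The activation (rather than
inactivation) sign is required for depolarisation to deplete the
vesicle pool, and matches the worked values u(−70) ≈ 0.066 and
u(−30) ≈ 4.871.

**RAB kinetics.** The two-state system has a shared rate factor
b(u) = A_s·u^B_s + C_s and rates α = b·(k^n + u^n)/k^n,
β = b·(k^n + u^n)/u^n. Three identities used throughout:

* A∞(u) = β/(α+β) = k^n/(k^n + u^n)  (pool falls with drive),
* τ_r(u) = 1/(α+β) = A∞(1−A∞)/b(u),
* steady release r∞ = α·A∞·N = b(u)·N.

The governing ODE dA/dt = β(1−A) − αA is forced by the steady state and
time constant above. τ_r at −70 mV is the depression recovery constant
probed by paired pulses, because recovery takes place at the
hyperpolarised holding potential.

**Output stages.** CBC variant: a sigmoid m/(1+exp(−(r−half)/slope)),
reported relative to its value at the dark resting release, so the
model output is a membrane potential relative to rest. Cone-release
variant: convolution with a 60-ms exponential kernel standing in for
the glutamate-sensor impulse response.

## Numerics

* Fixed 1-ms grid everywhere (`Trace` enforces dt = 1 ms); units are
  ms, mV, 1/ms; the drive is dimensionless.
* Kinetics advance by exponential Euler,
  A′ = A∞ + (A − A∞)·e^(−dt/τ), which is exact per step for
  piecewise-constant drive. Composition over n steps therefore equals a
  single n·dt step to machine precision — this is tested at 1e−12.
* In the full cascade the filtered drive ramps smoothly *within* each
  1-ms interval, so the per-step constant is taken at the interval
  midpoint (average of adjacent drive samples), and the sensor
  convolution likewise consumes midpoint release values. This
  second-order treatment keeps the 1-ms path within 0.5% of a 0.01-ms
  brute-force forward-Euler integration for every preset; end-sample
  hold left 1.5–4% errors for presets with fast dark-side kinetics.
  Voltage-clamp input (`synaptic_block_only`) keeps sample-hold,
  because clamp commands genuinely are piecewise constant; feeding the
  cascade's own cone voltage back through the clamp path therefore
  reproduces its release only up to this discretisation (≲3%).
* Convolution history before stimulus onset is padded with the dark
  baseline, consistent with stable-state initialisation; all
  simulations start from the dark fixed point (V = −45 mV,
  A = A∞(u(−45))).
* Square waves start with the light half-cycle (the dark rest precedes
  the trace); each period's on/off durations are quantised to the 1-ms
  grid with an error accumulator so every cycle keeps exactly 50% duty.
  Naive rounding of cumulative half-cycle edges was rejected: at
  333 Hz it modulates the local duty cycle between 1/3 and 2/3 on a
  ~1-s timescale, which the 40-ms filter passes as a spurious
  low-frequency response.
* Default stimulus duration is max(4000 ms, 8 periods) rounded up to
  whole periods, so the final repeat (the feature window) is near
  cyclo-stationary.
* All model time constants are constrained to ≥ 1 ms over the working
  voltage grid [−75, −30] mV (1-mV steps); fits enforce this through a
  penalty growing linearly in the worst violation, continuous at the
  feasibility boundary.

## Protocols and features

* **CBC peak response**: signed maximum of the baseline-relative output
  over the last full period. At high frequencies the output sits below
  rest for the whole period, so the signed peak is negative; this is
  deliberate ("the transient has disappeared") and the tuning-range
  rule and acceptance checks use the signed value.
* **Cone peak response**: max over the final second minus the resting
  sensor output; negative when the response is suppressed below rest.
* **Tuning range**: f_start is the highest tested frequency whose peak
  stays ≥ 95% of the 1-Hz peak, f_end the lowest whose peak is ≤ 5% of
  it; both thresholds are parameters, and open bounds are flagged.
* **1-Hz peak-to-base ratio** (fitting feature): peak over the
  magnitude of the mean output across the last 50 ms of the light
  half-cycle in the final period. It pins the amplitude scale of the
  feature vector, which pure peak differences leave loose.
* **PPD**: baseline −70 mV, two 10-ms pulses to −30 mV, Δt measured
  pulse-offset to pulse-onset, default 12 log-spaced intervals in
  [10 ms, 20 s]. Each pulse's peak release is measured above its
  immediately pre-pulse baseline; because the peak occurs at pulse
  onset, the ratio reduces analytically to A(Δt)/A∞(−70) and the
  exponential fit recovers τ_r(−70) almost exactly — the 15% test band
  covers discretisation and fit error.

## Fitting

Free parameters: LN {γ, m, half, slope}; LNS-cbc
{A_s, B_s, C_s, k_s, n_s, N, m, half, slope}; LNS-cone
{A_s…n_s, N}. All are positive and optimised in log space. The CBC
objective is the equally weighted L1 mismatch of per-frequency peaks
plus the 1-Hz ratio; the cone objective is the L1 mismatch of traces
after rest subtraction and peak-magnitude normalisation (the fit is
scale-free; N and the sigmoid are partially redundant with it, a
non-identifiability we accept).

The L1 feature objective is kinked and multimodal; Nelder-Mead from
random starts stalls far above the noise floor. The optimiser therefore
runs a seeded differential-evolution exploration over the log-parameter
box (sobol initialisation, rank-based selection, no polishing), then
Nelder-Mead refinement from the template model and the best distinct
explorer candidates, with a final tighter Nelder-Mead polish. Fits are
bit-reproducible given the seed. Because the cell block of the LNS
model is fully fixed, the per-frequency calcium-drive traces are
precomputed once per fit; a single objective evaluation then costs
under a millisecond, which is what makes the multi-replicate recovery
experiment affordable on one core.

## Synthetic data

Presets are built backwards from declared adaptation targets:
`design_rab` solves the rate-law constants exactly for a requested
(τ_r(−70), A∞(−70)) pair given shape parameters (n_s, B_s, and the
split of the rate factor between its drive-independent and
drive-dependent parts), and sets N so the dark resting release is a
fixed reference value. Derived properties are re-checked against the
declared targets at construction. The five presets:

| preset | τ_r(−70) | A∞(−70) | role |
|---|---|---|---|
| cbc_fast | 100 ms | 0.54 | fast CBC channel (cb2-like) |
| cbc_slow | 600 ms | 0.60 | slow CBC channel (cb3a-like) |
| cone_az | 90 ms | 0.90 | acute-zone UV cone: large pool, fast recovery |
| cone_dorsal | 110 ms | 0.55 | dorsal UV cone: AZ-like recovery, smaller pool |
| cone_nasal | 400 ms | 0.45 | nasal UV cone: small pool, slow recovery |

Two structural lessons from the design space are worth recording.
First, strongly drive-dependent rate factors make dark-side kinetics so
fast that the pool tracks the 40-ms voltage ramp quasi-statically and
the light-off transient vanishes; the cone presets therefore use
(nearly) drive-independent factors. Second, whether a cone channel
retains a response at 16 Hz is controlled by the recovery flux
β·(1−A) at light-phase drives relative to the resting release b(u_dark):
the acute-zone preset's large pool and fast recovery push its
cyclostationary mean release above rest at 16 Hz, while the nasal
preset's does not — reproducing the regional specialisation the model
family is meant to capture.

Noise is additive Gaussian with configurable SD — a stand-in, since the
emulated recordings do not constrain the real noise structure. Noisy
peaks are truncated at zero only where the noiseless peak is
non-negative (transient amplitudes stay amplitudes; negative
plateau-dominated entries keep unbiased noise). The generators do not
model sensor photon statistics, indicator nonlinearity, recording
drift, or electrophysiological artifacts; passing the recovery
experiment therefore shows the inference pipeline is sound under the
stated noise model, not that it is robust to every laboratory
disturbance.

## Validation experiments and problem sizes

* Kinetics exactness: 1000 random parameter draws, closed form vs
  integrator at 1e−12.
* PPD/analytic consistency: designed kinetics at τ ∈ {100, 300, 600} ms,
  fitted τ within 15%.
* Oracle equivalence: all presets, 4-Hz stimulus (4 s), 1-ms path vs
  0.01-ms forward Euler, ≤ 1% of the output peak.
* Blind recovery: 10 seeded replicates per CBC preset at 2% feature
  noise (relative to that preset's 1-Hz peak), fitted from a neutral
  template. Pass criteria: median relative τ error ≤ 20% and fast<slow
  ordering in every replicate. The replicate count and the optimiser
  budget (12-member-per-dimension exploration over 120 generations,
  three refinement starts) were chosen so the experiment completes in
  under ten minutes on a single core while leaving the criteria clear
  margins; the residual error is dominated by incomplete convergence on
  the hardest noise draws, not by bias.

## Known limitations

* Phototransduction adaptation, CBC ion-channel dynamics, and spatial
  structure are outside the model by design; the LN block is static.
* The 1-Hz peak-to-base ratio definition (plateau window, equal
  weighting) is one reasonable reading of an under-specified feature;
  both are configurable.
* Recovered parameters other than the adaptation summaries
  (A∞, τ_r over voltage) are not individually identifiable — several
  rate-law parameterisations produce indistinguishable features.
* The square-wave quantisation leaves period jitter at 333 Hz (cycles
  alternate between 2 and 4 ms); the effective frequency is correct on
  average and the jitter components lie far above the filter cutoff.
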