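# lnsynapse

Linear-Nonlinear-Synapse (LNS) modelling of retinal cone → bipolar-cell
channels: simulate the cascade, run frequency-tuning and paired-pulse
depression protocols, fit models to response features or release traces,
and infer synaptic depression recovery time constants — all validated on
synthetic data with known ground truth.

## The scientific problem

A single cone pedicle feeds several cone-bipolar-cell (CBC) subtypes,
and each contact forms a parallel processing channel with its own
temporal frequency tuning. Much of that tuning is set not by the cells
but by short-term depression at the ribbon synapse: vesicle pools
deplete during depolarisation and recover at hyperpolarised potentials,
and the recovery time constant differs across channels (fast cone–cb2
contacts versus slow cone–cb3a contacts, or acute-zone versus nasal UV
cones in the zebrafish retina). This package implements a circuit model
that makes the synapse explicit, so that synaptic depression can be
*inferred* from frequency-tuning measurements and, conversely, tuning
can be *predicted* from synaptic properties.

## The model

The cascade has three stages:

1. **Cell (LN) block.** Binary light x(t) ∈ {0, 1} is convolved with a
   40-ms exponential filter (unit DC gain) and passed through a fixed
   Hill-form nonlinearity, giving the cone membrane potential
   V_cone(t) ∈ [−70, −45] mV (dark rest −45 mV).
2. **Synaptic block.** A Boltzmann activation derived from the CaV1.4
   I–V curve maps voltage to a calcium drive
   u(V) = 0.078·(41 − V)·g(V) + 0.05. The drive controls a two-state
   kinetic system (active fraction A, inactive 1 − A) with transfer
   rates

       α(u) = (A_s·u^B_s + C_s)·(k_s^n_s + u^n_s)/k_s^n_s
       β(u) = (A_s·u^B_s + C_s)·(k_s^n_s + u^n_s)/u^n_s

   so the steady state A∞(u) = k_s^n_s/(k_s^n_s + u^n_s) falls with
   depolarisation and the relaxation time is τ_r = 1/(α + β). The
   block's output is the release rate r = α(u)·A·N. τ_r evaluated at
   −70 mV is the depression **recovery** time constant measured by
   paired-pulse protocols.
3. **Output stage.** For CBC membrane potential, a second sigmoid
   (reported relative to dark rest); for cone release imaged with a
   glutamate sensor, a 60-ms exponential kernel.

Simulation runs on a fixed 1-ms grid; the kinetics are advanced by
exponential Euler (exact per step for piecewise-constant drive).

The paired-pulse depression (PPD) protocol holds the synaptic block at
−70 mV, applies two 10-ms pulses to −30 mV separated by Δt, and fits
the peak ratio series with R(Δt) = flu·(1 − e^(−Δt/τ)) + base.

## Worked example

```python
import lnsynapse as L

fast = L.make_preset("cbc_fast")      # cone-cb2-like channel
slow = L.make_preset("cbc_slow")      # cone-cb3a-like channel

# analytic adaptation properties
for p in (fast, slow):
    a_inf, tau = L.adaptation_properties(-70.0, p.model)
    print(f"{p.name}: A_inf(-70) = {a_inf:.2f}, tau_r(-70) = {tau:.0f} ms")

# paired-pulse depression recovers the same constant operationally
ppd = L.run_ppd(fast.model)
print(f"PPD-fitted recovery tau: {ppd.fit.tau_ms:.1f} ms")

# frequency tuning of both channels
curve = L.tuning_curve(fast.model, (1, 2, 4, 8, 16))
print("fast peaks:", curve.peaks.round(2))
```

This prints:

```
cbc_fast: A_inf(-70) = 0.54, tau_r(-70) = 100 ms
cbc_slow: A_inf(-70) = 0.60, tau_r(-70) = 600 ms
PPD-fitted recovery tau: 99.5 ms
fast peaks: [3.77 3.38 2.4  1.47 0.08]
```

The fast channel keeps ~64% of its 1-Hz peak at 4 Hz and loses the
transient by 16 Hz; the slow channel's curve sits below it at every
frequency above baseline — the synaptic account of channel-specific
temporal tuning.

A `lns` command-line tool exposes the same pipeline
(`lns simulate | tune | ppd | synth | fit | report`); each run writes
its artifacts plus a `config.json` so results can be reproduced
exactly.

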