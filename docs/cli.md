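# Command-line interface

The `lns` entry point wraps the library pipeline. Every command writes
its artifacts into `--out` together with a `config.json` describing the
run, so any result can be reproduced from the output directory alone.
All commands are pure functions of (configuration, input files, seed);
running the same configuration twice produces byte-identical output.
Logging goes to stderr (`-v` for debug level).

## Commands

```
lns simulate --preset cbc_fast --freq 4 --out runs/sim
```
Simulates the cascade under a square-wave stimulus and writes one CSV
per inner variable: `stimulus`, `v_cone` (cone membrane potential),
`drive` (calcium drive), `A` (active fraction), `r` (release rate),
`output`.

```
lns tune --preset cbc_slow --freqs 1,2,4,8,16 --out runs/tune
```
Runs the frequency-tuning protocol: `tuning_curve.csv`
(`freq_hz,peak`) and `tuning_range.json` with the band edges and
open-bound flags. `--keep-frac`/`--gone-frac` set the "no decrement"
and "disappeared" thresholds (defaults 0.95 / 0.05 of the 1-Hz peak).

```
lns ppd --preset cbc_fast --out runs/ppd
```
Paired-pulse depression on the synaptic block: `ppd_ratios.csv`
(`interval_ms,ratio`) and `recovery_fit.json` (flu, base, tau_ms,
identifiable). `--intervals` overrides the default 12 log-spaced
intervals in [10 ms, 20 s].

```
lns synth --preset cbc_fast --kind cbc_features --noise-sd 0.08 --seed 1 --out data/fast1
```
Generates a synthetic dataset (`cbc_features`, `cone_trace` or
`ppd_ratios`) with a `manifest.json` recording preset, noise and seed.

```
lns fit --data data/fast1 --seed 1 --out runs/fit1
```
Fits an LNS model to a dataset directory (reads the manifest), writing
`fit_result.json` with the best parameters, objective, per-start
summaries and the derived adaptation report (A_inf and tau_r across
the working voltage grid). `--starts`, `--maxiter`, `--de-popsize`,
`--de-maxiter` control the optimiser budget.

```
lns report --run runs/fit1
```
Prints a human-readable summary of any run directory.

## config.json fields

| field | meaning |
|---|---|
| `command` | which subcommand produced the run |
| `seed` | seed for all randomness in the run |
| `preset` / `model_file` | model source |
| `freq_hz`, `freqs` | stimulus frequency / frequency grid (Hz) |
| `keep_frac`, `gone_frac` | tuning-range thresholds |
| `intervals` | paired-pulse intervals (ms) |
| `noise_sd` | generator noise level |
| `kind` | dataset kind for synth/fit |
| `out` | output directory |

The file is validated (types and ranges) before execution; a malformed
configuration or input file aborts with a nonzero exit status and a
message naming the offending file and rule.
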