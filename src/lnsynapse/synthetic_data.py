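"""Ground-truth presets and noisy synthetic datasets.

No machine-readable recordings accompany the modelled experiments, so
every pipeline stage is exercised against synthetic data generated from
fully specified LNS models.  Presets are constructed *backwards* from
declared adaptation targets: given the desired depression-recovery
constant ``tau_r(-70 mV)`` and steady active fraction ``A_inf(-70 mV)``,
:func:`design_rab` solves the RAB rate-law constants exactly, so each
preset's derived kinetics hit its targets by construction.

Presets
-------
``cbc_fast``  cone->cb2-like channel, tau_r(-70) = 100 ms
``cbc_slow``  cone->cb3a-like channel, tau_r(-70) = 600 ms
``cone_az``   acute-zone UV cone, large vesicle pool at -70 mV and
              fast recovery (retains responses at high frequency)
``cone_dorsal`` dorsal UV cone, recovery similar to the acute zone but
              a smaller pool
``cone_nasal`` nasal UV cone, small pool and slow recovery

The noise model is additive Gaussian (a stand-in for experimental
noise, whose structure the recordings do not constrain), truncated to
the valid range of each quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .model_core import (
    LNSModel,
    RABParams,
    SigmoidParams,
    adaptation_properties,
    cav_drive,
    resting_state,
    simulate_lns,
)
from .protocols import (
    DEFAULT_FREQS_HZ,
    DEFAULT_PPD_INTERVALS_MS,
    TuningCurve,
    peak_to_base_ratio,
    run_ppd,
    square_wave_stimulus,
    tuning_curve,
)
from .trace import Trace

__all__ = [
    "PRESET_NAMES",
    "Preset",
    "SyntheticDataset",
    "CBCFeatures",
    "ConeTraceData",
    "design_rab",
    "make_preset",
    "gen_cbc_features",
    "gen_cone_trace",
    "gen_ppd_ratios",
]

PRESET_NAMES = ("cbc_fast", "cbc_slow", "cone_az", "cone_dorsal", "cone_nasal")

#: Output sigmoid shared by the CBC presets (mV span / release units).
_CBC_OUTPUT_NL = dict(m=20.0, half=2.0, slope=0.5)

#: Resting release rate the output scale N is normalised to, so the
#: output sigmoid sees a comparable operating range across presets.
_R_REST_TARGET = 1.5


@dataclass
class CBCFeatures:
    """Feature table for a CBC channel: the tuning curve plus the 1-Hz
    peak-to-base ratio that pins the overall amplitude."""

    curve: TuningCurve
    ratio_at_1hz: float


@dataclass
class ConeTraceData:
    """A cone-release recording: the light stimulus and the
    sensor-convolved release trace."""

    stimulus: Trace
    trace: Trace


@dataclass
class Preset:
    """A fully specified ground-truth model with declared adaptation targets."""

    name: str
    model: LNSModel
    tau_r_70_ms: float
    a_inf_70: float


@dataclass
class SyntheticDataset:
    """A noisy dataset plus full provenance (truth, noise level, seed)."""

    kind: str  # cbc_features | cone_trace | ppd_ratios
    payload: object
    truth: Preset
    noise_sd: float
    seed: int

    def save(self, outdir) -> None:
        """Write payload files plus a ``manifest.json`` with provenance."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = []
        if self.kind == "cbc_features":
            self.payload.curve.to_csv(outdir / "features.csv")
            with open(outdir / "ratio.json", "w") as fh:
                json.dump({"ratio_at_1hz": self.payload.ratio_at_1hz}, fh)
            files = ["features.csv", "ratio.json"]
        elif self.kind == "cone_trace":
            self.payload.stimulus.to_csv(outdir / "stimulus.csv")
            self.payload.trace.to_csv(outdir / "trace.csv")
            files = ["stimulus.csv", "trace.csv"]
        elif self.kind == "ppd_ratios":
            intervals, ratios = self.payload
            import pandas as pd

            pd.DataFrame({"interval_ms": intervals, "ratio": ratios}).to_csv(
                outdir / "ppd.csv", index=False
            )
            files = ["ppd.csv"]
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                {
                    "kind": self.kind,
                    "preset": self.truth.name,
                    "noise_sd": self.noise_sd,
                    "seed": self.seed,
                    "files": files,
                },
                fh,
                indent=2,
            )


def design_rab(
    tau_r_70_ms: float,
    a_inf_70: float,
    n_s: float,
    B_s: float = 1.0,
    c_frac: float = 0.8,
    r_rest: float = _R_REST_TARGET,
) -> RABParams:
    """Solve RAB constants for declared adaptation targets at -70 mV.

    With ``u70 = cav_drive(-70)``, the steady state fixes
    ``k_s = u70 * (a/(1-a))**(1/n_s)`` and the recovery constant fixes
    the common rate factor ``A_s u70^B_s + C_s = a (1-a) / tau``, split
    between a drive-independent part (fraction ``c_frac``) and a
    drive-dependent part.  ``N`` is set so the dark resting release rate
    equals ``r_rest``.
    """
    if not (0.0 < a_inf_70 < 1.0):
        raise ValueError("a_inf_70 must lie strictly inside (0, 1)")
    if not (0.0 <= c_frac <= 1.0):
        raise ValueError("c_frac must lie in [0, 1]")
    u70 = cav_drive(-70.0)
    k_s = u70 * (a_inf_70 / (1.0 - a_inf_70)) ** (1.0 / n_s)
    base70 = a_inf_70 * (1.0 - a_inf_70) / tau_r_70_ms
    C_s = c_frac * base70
    A_s = (1.0 - c_frac) * base70 / u70**B_s
    params = RABParams(A_s=A_s, B_s=B_s, C_s=C_s, k_s=k_s, n_s=n_s, N=1.0)
    # dark resting release fixes the output scale
    u_dark = cav_drive(-45.0)
    base_dark = A_s * u_dark**B_s + C_s  # alpha * A_inf reduces to the base factor
    return RABParams(A_s=A_s, B_s=B_s, C_s=C_s, k_s=k_s, n_s=n_s, N=r_rest / base_dark)


_PRESET_SPECS = {
    # name: (tau_r(-70) ms, A_inf(-70), n_s, B_s, c_frac, variant)
    "cbc_fast": (100.0, 0.54, 0.4, 1.0, 0.8, "cbc"),
    "cbc_slow": (600.0, 0.60, 0.5, 1.2, 0.6, "cbc"),
    "cone_az": (90.0, 0.90, 1.0, 1.0, 1.0, "cone_release"),
    "cone_dorsal": (110.0, 0.55, 1.0, 1.0, 0.95, "cone_release"),
    "cone_nasal": (400.0, 0.45, 1.0, 1.0, 0.95, "cone_release"),
}


def make_preset(name: str) -> Preset:
    """Construct a named preset; derived kinetics are checked against the
    declared targets (within 5%) before returning."""
    if name not in _PRESET_SPECS:
        raise KeyError(f"unknown preset {name!r}; options: {PRESET_NAMES}")
    tau70, a70, n_s, B_s, c_frac, variant = _PRESET_SPECS[name]
    rab = design_rab(tau70, a70, n_s=n_s, B_s=B_s, c_frac=c_frac)
    if variant == "cbc":
        model = LNSModel(variant="cbc", rab=rab, output_nl=SigmoidParams(**_CBC_OUTPUT_NL))
    else:
        model = LNSModel(variant="cone_release", rab=rab)
    a_inf, tau = adaptation_properties(-70.0, model)
    if abs(tau - tau70) > 0.05 * tau70 or abs(a_inf - a70) > 0.05 * a70:
        raise AssertionError(
            f"preset {name}: derived adaptation ({a_inf:.3f}, {tau:.1f} ms) "
            f"misses declared targets ({a70}, {tau70} ms)"
        )
    return Preset(name=name, model=model, tau_r_70_ms=tau70, a_inf_70=a70)


# ---------------------------------------------------------------------------
# dataset generators
# ---------------------------------------------------------------------------


def gen_cbc_features(
    preset: Preset,
    freqs: Sequence[float] = DEFAULT_FREQS_HZ,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Noisy peak-response feature table from a CBC preset.

    Gaussian noise of standard deviation ``noise_sd`` (same units as the
    peaks) is added to each peak and, scaled into ratio units, to the
    1-Hz peak-to-base ratio.  Noisy peaks are truncated at 0 only where
    the noiseless peak is itself non-negative: transient amplitudes stay
    amplitudes, while plateau-dominated entries (negative signed peaks
    at high frequency) keep their value and the noise stays unbiased.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    curve = tuning_curve(preset.model, freqs)
    out_1hz = simulate_lns(preset.model, square_wave_stimulus(1.0))["output"]
    ratio = peak_to_base_ratio(out_1hz, 1000.0)
    peaks = curve.peaks.copy()
    if noise_sd > 0:
        noisy = peaks + rng.normal(0.0, noise_sd, peaks.size)
        peaks = np.where(peaks >= 0.0, np.maximum(noisy, 0.0), noisy)
        ratio += rng.normal(0.0, noise_sd * ratio / max(curve.baseline_peak, 1e-12))
    payload = CBCFeatures(
        curve=TuningCurve(curve.frequencies, peaks), ratio_at_1hz=float(ratio)
    )
    return SyntheticDataset("cbc_features", payload, preset, noise_sd, seed)


def gen_cone_trace(
    preset: Preset,
    stimulus: Trace,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Sensor-convolved release trace plus white Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    out = simulate_lns(preset.model, stimulus)["output"]
    values = out.values.copy()
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.size)
    payload = ConeTraceData(
        stimulus=stimulus, trace=out.with_values(values)
    )
    return SyntheticDataset("cone_trace", payload, preset, noise_sd, seed)


def gen_ppd_ratios(
    preset: Preset,
    intervals: Sequence[float] = DEFAULT_PPD_INTERVALS_MS,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Paired-pulse ratio series plus noise, truncated at 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    result = run_ppd(preset.model, intervals)
    ratios = result.ratios.copy()
    if noise_sd > 0:
        ratios = np.maximum(ratios + rng.normal(0.0, noise_sd, ratios.size), 0.0)
    return SyntheticDataset(
        "ppd_ratios", (result.intervals, ratios), preset, noise_sd, seed
    )
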