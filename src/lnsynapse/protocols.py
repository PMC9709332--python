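"""Experimental protocols: temporal frequency tuning and paired-pulse depression.

Frequency tuning drives a model with binary square-wave light (50% duty
cycle, 1-333 Hz), extracts the peak response of the last stimulus repeat
per frequency, and summarises the curve by a *tuning range* -- from the
highest frequency whose peak shows no decrement to the lowest frequency
at which the transient response has disappeared.

Paired-pulse depression (PPD) holds the cone at -70 mV, applies two
10-ms pulses to -30 mV separated by an interval ``dt`` (10 ms - 20 s),
and measures the ratio ``R`` of the second to the first pulse peak.  The
recovery time course is obtained by fitting
``R(dt) = flu * (1 - exp(-dt/tau)) + base``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model_core import LNModel, LNSModel, TAU_MIN_MS, resting_state, simulate_ln, simulate_lns, synaptic_block_only
from .trace import DT_MS, Trace, TraceError

__all__ = [
    "DEFAULT_FREQS_HZ",
    "DEFAULT_PPD_INTERVALS_MS",
    "TuningCurve",
    "TuningRange",
    "RecoveryFit",
    "PPDResult",
    "square_wave_stimulus",
    "peak_response_cbc",
    "peak_response_cone",
    "peak_to_base_ratio",
    "tuning_curve",
    "tuning_range",
    "ppd_command_trace",
    "run_ppd",
    "fit_recovery",
]

#: Octave-spaced test grid spanning the 1-333 Hz protocol range.
DEFAULT_FREQS_HZ = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 333.0)

#: Twelve log-spaced paired-pulse intervals from 10 ms to 20 s.
DEFAULT_PPD_INTERVALS_MS = tuple(
    float(v) for v in np.geomspace(10.0, 20000.0, 12).round(1)
)


class ProtocolError(ValueError):
    """Raised for malformed protocol inputs."""


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


def square_wave_stimulus(freq_hz: float, duration_ms: float | None = None) -> Trace:
    """Binary square-wave light at 50% duty cycle.

    Each period is a light half-cycle followed by a dark half-cycle (the
    dark resting state precedes the trace and is supplied by the model's
    initialisation).  Non-integer half-cycles are quantised to the 1-ms
    grid with an error accumulator, keeping every cycle at exactly 50%
    duty and preserving total duration to within a sample; the residual
    period jitter sits at or above the stimulus frequency, so no
    spurious low-frequency component is introduced.  The default
    duration is ``max(4000 ms, 8 periods)`` rounded up to whole periods,
    so the last repeat is near cyclo-stationary.
    """
    if freq_hz <= 0:
        raise ProtocolError("frequency must be positive")
    if not (1.0 <= freq_hz <= 333.0):
        warnings.warn(
            f"frequency {freq_hz} Hz lies outside the 1-333 Hz protocol range",
            stacklevel=2,
        )
    period = 1000.0 / freq_hz
    if duration_ms is None:
        duration_ms = max(4000.0, 8.0 * period)
    n_periods = int(np.ceil(duration_ms / period))
    half = period / 2.0
    chunks = []
    err = 0.0
    for _ in range(n_periods):
        d = int(round(half + err))
        err += half - d
        if d < 1:
            d, err = 1, err - 1.0  # never drop a half-cycle entirely
        chunk = np.zeros(2 * d)
        chunk[:d] = 1.0  # light half first, then dark
        chunks.append(chunk)
    return Trace(values=np.concatenate(chunks), kind="luminance")


def ppd_command_trace(
    interval_ms: float,
    baseline_mv: float = -70.0,
    pulse_mv: float = -30.0,
    pulse_ms: float = 10.0,
    lead_ms: float = 100.0,
    tail_ms: float = 50.0,
) -> Trace:
    """Voltage-clamp command for one paired-pulse trial.

    Baseline at -70 mV, two ``pulse_ms`` pulses to -30 mV separated by
    ``interval_ms`` measured from the offset of the first pulse to the
    onset of the second.
    """
    if interval_ms < DT_MS:
        raise ProtocolError(f"interval must be at least {DT_MS} ms")
    lead = int(round(lead_ms))
    pulse = int(round(pulse_ms))
    gap = int(round(interval_ms))
    tail = int(round(tail_ms))
    v = np.full(lead + 2 * pulse + gap + tail, baseline_mv)
    v[lead : lead + pulse] = pulse_mv
    v[lead + pulse + gap : lead + 2 * pulse + gap] = pulse_mv
    return Trace(values=v, kind="voltage_mV")


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def peak_response_cbc(output: Trace, period_ms: float) -> float:
    """Maximum of the baseline-corrected output over the last full period."""
    p = int(round(period_ms))
    if len(output) < p or p < 1:
        raise ProtocolError("output trace shorter than one stimulus period")
    return float(np.max(output.values[-p:]))


def peak_response_cone(output: Trace, rest_value: float) -> float:
    """Gap between the maximum response in the last second and the
    resting response before stimulation (may be negative when the
    response is suppressed below rest)."""
    if len(output) < 1000:
        raise ProtocolError("output trace shorter than 1000 ms")
    return float(np.max(output.values[-1000:]) - rest_value)


def peak_to_base_ratio(
    output: Trace, period_ms: float = 1000.0, plateau_ms: int = 50
) -> float:
    """Peak amplitude over the magnitude of the light-phase plateau.

    The plateau is the mean output over the final ``plateau_ms`` of the
    light half-cycle in the last period; at 1 Hz this term pins the
    overall amplitude of the tuning curve during fitting.
    """
    p = int(round(period_ms))
    if len(output) < p:
        raise ProtocolError("output trace shorter than one stimulus period")
    peak = float(np.max(output.values[-p:]))
    half = p // 2
    plateau = output.values[-p + half - plateau_ms : -p + half]
    base = float(abs(np.mean(plateau)))
    if base < 1e-12:
        raise ProtocolError("light-phase plateau is zero; ratio undefined")
    return peak / base


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------


@dataclass
class TuningCurve:
    """Peak response versus stimulus frequency; must include the 1-Hz
    baseline frequency."""

    frequencies: np.ndarray
    peaks: np.ndarray
    baseline_freq: float = 1.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.peaks = np.asarray(self.peaks, float)
        order = np.argsort(self.frequencies)
        self.frequencies = self.frequencies[order]
        self.peaks = self.peaks[order]
        if self.frequencies.size != self.peaks.size:
            raise ProtocolError("frequencies and peaks must align")
        if not np.any(np.isclose(self.frequencies, self.baseline_freq)):
            raise ProtocolError("tuning curve must include the baseline frequency")

    @property
    def baseline_peak(self) -> float:
        i = int(np.argmin(np.abs(self.frequencies - self.baseline_freq)))
        return float(self.peaks[i])

    def to_csv(self, path) -> None:
        pd.DataFrame({"freq_hz": self.frequencies, "peak": self.peaks}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "TuningCurve":
        df = pd.read_csv(path)
        for col in ("freq_hz", "peak"):
            if col not in df.columns:
                raise ProtocolError(f"{path}: missing required column {col!r}")
        return cls(df["freq_hz"].to_numpy(float), df["peak"].to_numpy(float))


@dataclass
class TuningRange:
    """Frequency band of a channel: ``f_start`` is the highest tested
    frequency without response decrement, ``f_end`` the lowest tested
    frequency at which the transient has disappeared.  Open bounds are
    flagged when no tested frequency meets a criterion."""

    f_start: Optional[float]
    f_end: Optional[float]
    start_open: bool = False
    end_open: bool = False


def tuning_curve(model, freqs: Sequence[float] = DEFAULT_FREQS_HZ) -> TuningCurve:
    """Peak response at each frequency, model re-initialised at rest per run."""
    freqs = sorted(float(f) for f in freqs)
    peaks = []
    is_cone = isinstance(model, LNSModel) and model.variant == "cone_release"
    for f in freqs:
        stim = square_wave_stimulus(f)
        if isinstance(model, LNModel):
            out = simulate_ln(model, stim)
        else:
            out = simulate_lns(model, stim)["output"]
        if is_cone:
            peaks.append(peak_response_cone(out, resting_state(model).output))
        else:
            peaks.append(peak_response_cbc(out, 1000.0 / f))
    return TuningCurve(np.array(freqs), np.array(peaks))


def tuning_range(
    curve: TuningCurve, keep_frac: float = 0.95, gone_frac: float = 0.05
) -> TuningRange:
    """Tuning range from the curve relative to its 1-Hz baseline peak.

    ``f_start``: highest tested frequency with peak >= ``keep_frac`` of
    the baseline peak; ``f_end``: lowest tested frequency with peak <=
    ``gone_frac`` of it.  The thresholds quantify "without decreasement"
    and "disappeared" and are configurable.
    """
    ref = curve.baseline_peak
    keep = curve.frequencies[curve.peaks >= keep_frac * ref]
    gone = curve.frequencies[curve.peaks <= gone_frac * ref]
    f_start = float(keep.max()) if keep.size else None
    f_end = float(gone.min()) if gone.size else None
    return TuningRange(
        f_start=f_start,
        f_end=f_end,
        start_open=not keep.size,
        end_open=not gone.size,
    )


# ---------------------------------------------------------------------------
# paired-pulse depression
# ---------------------------------------------------------------------------


@dataclass
class RecoveryFit:
    """Parameters of ``R(dt) = flu (1 - exp(-dt/tau)) + base``;
    ``identifiable`` is False when the ratios carry no usable curvature
    (e.g. constant R), in which case ``tau_ms`` is NaN."""

    flu: float
    base: float
    tau_ms: float
    identifiable: bool = True


@dataclass
class PPDResult:
    """Paired-pulse recovery series and its exponential fit."""

    intervals: np.ndarray
    ratios: np.ndarray
    fit: RecoveryFit

    def to_csv(self, path) -> None:
        pd.DataFrame({"interval_ms": self.intervals, "ratio": self.ratios}).to_csv(
            path, index=False
        )

    def fit_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "flu": self.fit.flu,
                    "base": self.fit.base,
                    "tau_ms": self.fit.tau_ms,
                    "identifiable": self.fit.identifiable,
                },
                fh,
                indent=2,
            )


def _recovery_model(dt, flu, base, tau):
    return flu * (1.0 - np.exp(-dt / tau)) + base


def fit_recovery(intervals: Sequence[float], ratios: Sequence[float]) -> RecoveryFit:
    """Least-squares fit of the one-exponential recovery function.

    Requires at least three points; ``tau >= 1 ms`` is enforced through
    the fit bounds.  Constant ratio series are flagged non-identifiable.
    """
    dt = np.asarray(intervals, float)
    r = np.asarray(ratios, float)
    if dt.size < 3:
        raise ProtocolError("recovery fit needs at least 3 points")
    order = np.argsort(dt)
    dt, r = dt[order], r[order]
    if np.ptp(r) < 1e-9:
        return RecoveryFit(flu=0.0, base=float(r.mean()), tau_ms=float("nan"), identifiable=False)
    p0 = (max(r[-1] - r[0], 1e-3), r[0], max(float(np.median(dt)), TAU_MIN_MS))
    popt, _ = curve_fit(
        _recovery_model,
        dt,
        r,
        p0=p0,
        bounds=([-np.inf, -np.inf, TAU_MIN_MS], [np.inf, np.inf, 1e8]),
        maxfev=20000,
    )
    return RecoveryFit(flu=float(popt[0]), base=float(popt[1]), tau_ms=float(popt[2]))


def run_ppd(
    model: LNSModel,
    intervals: Sequence[float] = DEFAULT_PPD_INTERVALS_MS,
    pulse_mv: float = -30.0,
    baseline_mv: float = -70.0,
    pulse_ms: float = 10.0,
) -> PPDResult:
    """Paired-pulse depression protocol on the synaptic block.

    For each interval the command trace is fed directly to the synaptic
    block; each pulse's peak release above its pre-pulse baseline is
    measured and the ratio series fitted with :func:`fit_recovery`.
    """
    intervals = sorted(float(v) for v in intervals)
    ratios = []
    pulse = int(round(pulse_ms))
    lead = 100
    for dt_ms in intervals:
        trace = ppd_command_trace(
            dt_ms, baseline_mv=baseline_mv, pulse_mv=pulse_mv,
            pulse_ms=pulse_ms, lead_ms=lead,
        )
        r = synaptic_block_only(model, trace).values
        on1 = lead
        on2 = lead + pulse + int(round(dt_ms))
        p1 = np.max(r[on1 : on1 + pulse]) - r[on1 - 1]
        p2 = np.max(r[on2 : on2 + pulse]) - r[on2 - 1]
        if p1 <= 0:
            raise ProtocolError("first-pulse peak is zero; no depression to measure")
        ratios.append(p2 / p1)
    fit = fit_recovery(intervals, ratios)
    return PPDResult(np.asarray(intervals), np.asarray(ratios), fit)
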