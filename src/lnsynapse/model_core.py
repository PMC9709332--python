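"""Model blocks of the Linear-Nonlinear-Synapse (LNS) cascade.

The cascade maps a binary light stimulus onto the output of a retinal
cone -> bipolar-cell channel in three stages:

1.  a *cell* (LN) block -- a linear temporal filter followed by a static
    nonlinearity -- standing in for phototransduction and yielding the
    cone membrane potential ``V_cone`` (mV);
2.  a *synaptic* block -- a Boltzmann-activation calcium drive ``u``
    derived from the CaV1.4 I-V curve, feeding a two-state kinetic
    system (the RAB module) whose states are an Active fraction ``A``
    and its complement, the Inactive fraction ``1 - A``.  The block's
    output is the active->inactive transfer flux, the release rate
    ``r = alpha(u) * A * N``;
3.  an *output* stage that differs by experiment: a second sigmoid for
    bipolar-cell membrane potential (``cbc`` variant), or a 60-ms
    exponential sensor kernel mimicking iGluSnFR glutamate imaging
    (``cone_release`` variant).

All voltages are in mV, all times in ms, rates in 1/ms; the drive ``u``
is dimensionless.  Simulations run on the fixed 1-ms grid of
:class:`~lnsynapse.trace.Trace`, with the RAB ordinary differential
equation ``dA/dt = beta (1 - A) - alpha A`` advanced by exponential
Euler (exact per step for piecewise-constant drive).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import signal as _signal

from .trace import DT_MS, Trace, TraceError

__all__ = [
    "PhotoFilterParams",
    "SigmoidParams",
    "ConeLNParams",
    "CaVParams",
    "RABParams",
    "RABState",
    "LNModel",
    "LNSModel",
    "RestingState",
    "ParameterError",
    "photoreceptor_kernel",
    "exponential_kernel",
    "convolve_causal",
    "sigmoid_nl",
    "cone_nl",
    "cav_drive",
    "rab_rates",
    "adaptation_properties",
    "step_rab",
    "rab_integrate",
    "synapse_output",
    "resting_state",
    "simulate_ln",
    "simulate_lns",
    "synaptic_block_only",
    "save_model",
    "load_model",
    "VOLTAGE_GRID",
]

#: Working voltage grid (mV) spanned by the experimental protocols; used
#: for the tau >= 1 ms constraint and adaptation reports.
VOLTAGE_GRID = np.arange(-75.0, -29.0, 1.0)

#: Minimum admissible time constant (ms) anywhere in a model.
TAU_MIN_MS = 1.0


class ParameterError(ValueError):
    """Raised for parameter values outside their admissible domain."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class PhotoFilterParams:
    """Photoreceptor impulse-filter parameters (cell block of the LN model).

    Only ``gamma`` (a dimensionless time-scale factor) is free during
    optimisation; the remaining constants are fixed properties of the
    template kernel.  ``tau_phase`` acts as a radian phase offset of the
    cosine term.
    """

    gamma: float = 1.0
    tau_rise: float = 70.0
    tau_decay: float = 70.0
    tau_phase: float = 100.0
    phi: float = -math.pi / 5.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ParameterError(f"gamma must be positive, got {self.gamma}")


@dataclass
class SigmoidParams:
    """Static sigmoid nonlinearity ``m / (1 + exp(-(l - half)/slope))``."""

    m: float
    half: float
    slope: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ParameterError("sigmoid slope must be nonzero")


@dataclass
class ConeLNParams:
    """Fixed phototransduction stage of the LNS model.

    A 40-ms exponential low-pass followed by a Hill-form hyperpolarising
    nonlinearity; with a unit-DC filter, binary light maps the linear
    output into [0, 1] and the cone voltage spans -45 mV (dark) to about
    -70 mV (light).
    """

    tau_L: float = 40.0
    hill_amp: float = -26.4
    hill_exp: float = 4.92
    hill_half: float = 0.542
    offset: float = -45.0


@dataclass
class CaVParams:
    """Calcium-drive nonlinearity adapted from the CaV1.4 I-V curve.

    ``u = gain * (e_rev - V) * g(V) + u_resting`` with the Boltzmann
    activation ``g(V) = 1 / (1 + exp(-(V - v_half)/k_slope))``; the
    resting term represents the resting calcium concentration in the
    cone terminal.
    """

    gain: float = 0.078
    e_rev: float = 41.0
    v_half: float = -39.3
    k_slope: float = 4.88
    u_resting: float = 0.05


@dataclass
class RABParams:
    """Rate-law constants of the two-state RAB kinetics and output scale.

    The transfer rates share a common factor ``A_s * u**B_s + C_s``:

    * ``alpha(u) = (A_s u^B_s + C_s) (k_s^n_s + u^n_s) / k_s^n_s``
    * ``beta(u)  = (A_s u^B_s + C_s) (k_s^n_s + u^n_s) / u^n_s``

    so the steady state ``A_inf = beta/(alpha+beta)`` reduces to
    ``k_s^n_s / (k_s^n_s + u^n_s)`` and decreases with drive:
    depolarisation depletes the active pool.  ``N`` scales the release
    rate output.
    """

    A_s: float
    B_s: float
    C_s: float
    k_s: float
    n_s: float
    N: float = 1.0

    def __post_init__(self) -> None:
        if self.A_s < 0 or self.B_s < 0 or self.C_s < 0:
            raise ParameterError("A_s, B_s, C_s must be nonnegative")
        if not (self.k_s > 0 and self.n_s > 0):
            raise ParameterError("k_s and n_s must be positive")
        if not self.N > 0:
            raise ParameterError("output scale N must be positive")


@dataclass
class RABState:
    """Active fraction of the two-state system; the inactive fraction is
    ``1 - A`` by conservation and is never stored separately."""

    A: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.A <= 1.0):
            raise ParameterError(f"active fraction must lie in [0, 1], got {self.A}")


@dataclass
class LNModel:
    """Linear filter + static sigmoid; output reported relative to rest."""

    filter: PhotoFilterParams
    nl: SigmoidParams


@dataclass
class LNSModel:
    """Full cascade; ``variant`` selects the output stage.

    ``cbc``: output sigmoid produces bipolar-cell membrane potential
    relative to rest.  ``cone_release``: the release rate is convolved
    with an exponential sensor kernel (``sensor_tau`` ms).
    """

    variant: str
    rab: RABParams
    cone_ln: ConeLNParams = field(default_factory=ConeLNParams)
    cav: CaVParams = field(default_factory=CaVParams)
    output_nl: Optional[SigmoidParams] = None
    sensor_tau: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant not in ("cbc", "cone_release"):
            raise ParameterError(f"unknown LNS variant {self.variant!r}")
        if self.variant == "cbc":
            if self.output_nl is None or self.sensor_tau is not None:
                raise ParameterError("cbc variant requires output_nl and no sensor_tau")
        else:
            if self.sensor_tau is None:
                self.sensor_tau = 60.0
            if self.output_nl is not None:
                raise ParameterError("cone_release variant takes no output sigmoid")


# ---------------------------------------------------------------------------
# kernels and convolution
# ---------------------------------------------------------------------------


def photoreceptor_kernel(params: PhotoFilterParams, length_ms: int) -> Trace:
    """Biphasic photoreceptor impulse filter on [0, length_ms).

    ``k(t) = -((t/(g tr))^3 / (1 + t/(g tr))) exp(-(t/(g td))^2)
    cos(2 pi t / (g phi) + tau_phase)`` with ``g = gamma``, then
    normalised so its peak absolute value is 1 (any gain ambiguity is
    absorbed by the free nonlinearity parameters).
    """
    if not params.gamma > 0:
        raise ParameterError("gamma must be positive")
    if length_ms < 1:
        raise ParameterError("kernel length must be >= 1 ms")
    t = np.arange(int(length_ms), dtype=float)
    g = params.gamma
    rise = (t / (g * params.tau_rise)) ** 3 / (1.0 + t / (g * params.tau_rise))
    envelope = np.exp(-((t / (g * params.tau_decay)) ** 2))
    phase = np.cos(2.0 * np.pi * t / (g * params.phi) + params.tau_phase)
    k = -rise * envelope * phase
    peak = np.max(np.abs(k))
    if peak > 0:
        k = k / peak
    return Trace(values=k, kind="drive")


def exponential_kernel(tau_ms: float, length_ms: int | None = None) -> Trace:
    """Causal first-order kernel ``exp(-s/tau)``, normalised to unit sum.

    Unit DC gain keeps binary light inside [0, 1] after filtering.  The
    default truncation is 8 time constants, where the discarded tail
    carries less than ``exp(-8)`` of the mass.
    """
    if tau_ms < TAU_MIN_MS:
        raise ParameterError(f"filter time constant must be >= {TAU_MIN_MS} ms")
    if length_ms is None:
        length_ms = int(math.ceil(8.0 * tau_ms))
    if length_ms < 1:
        raise ParameterError("kernel length must be >= 1 ms")
    s = np.arange(int(length_ms), dtype=float)
    k = np.exp(-s / tau_ms)
    return Trace(values=k / k.sum(), kind="drive")


def convolve_causal(signal: Trace, kernel: Trace, pad_value: float = 0.0) -> Trace:
    """Discrete causal convolution; history before ``t0`` is the
    pre-stimulus baseline ``pad_value``.  Output matches the signal grid."""
    if signal.dt != kernel.dt:
        raise TraceError("signal and kernel must share dt")
    x = signal.values
    k = kernel.values
    nk = k.size
    padded = np.concatenate([np.full(nk - 1, float(pad_value)), x])
    if x.size * nk > 500_000:
        full = _signal.fftconvolve(padded, k)
    else:
        full = np.convolve(padded, k)
    out = full[nk - 1 : nk - 1 + x.size]
    # a filtered binary stimulus is no longer luminance; call it a drive
    kind = "drive" if signal.kind == "luminance" else signal.kind
    return Trace(values=out, kind=kind, t0=signal.t0)


# ---------------------------------------------------------------------------
# static nonlinearities
# ---------------------------------------------------------------------------


def sigmoid_nl(l, params: SigmoidParams):
    """``m / (1 + exp(-(l - half)/slope))``; saturates at 0 and ``m``."""
    if params.slope == 0:
        raise ParameterError("sigmoid slope must be nonzero")
    l = np.asarray(l, dtype=float)
    out = params.m / (1.0 + np.exp(-(l - params.half) / params.slope))
    return out if out.ndim else float(out)


def cone_nl(l, params: ConeLNParams = ConeLNParams()):
    """Hill-form cone voltage nonlinearity (mV); -45 mV in the dark."""
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ParameterError("cone nonlinearity input must be nonnegative")
    ln = l**params.hill_exp
    out = params.hill_amp * ln / (ln + params.hill_half**params.hill_exp) + params.offset
    return out if out.ndim else float(out)


def cav_drive(v, params: CaVParams = CaVParams()):
    """Calcium drive from cone voltage; strictly increasing on the
    working range, with floor ``u_resting`` at the reversal potential."""
    v = np.asarray(v, dtype=float)
    gate = 1.0 / (1.0 + np.exp(-(v - params.v_half) / params.k_slope))
    out = params.gain * (params.e_rev - v) * gate + params.u_resting
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# RAB kinetics
# ---------------------------------------------------------------------------


def rab_rates(u, params: RABParams):
    """Transfer rates ``(alpha, beta)`` in 1/ms at drive ``u > 0``."""
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ParameterError("drive must be positive (beta divides by u^n_s)")
    base = params.A_s * u**params.B_s + params.C_s
    kn = params.k_s**params.n_s
    un = u**params.n_s
    s = kn + un
    alpha = base * s / kn
    beta = base * s / un
    if alpha.ndim:
        return alpha, beta
    return float(alpha), float(beta)


def _steady_and_tau(u, params: RABParams):
    alpha, beta = rab_rates(u, params)
    total = np.asarray(alpha) + np.asarray(beta)
    a_inf = np.asarray(beta) / total
    tau = 1.0 / total
    return a_inf, tau


def adaptation_properties(v, model: "LNSModel"):
    """Steady state ``A_inf = beta/(alpha+beta)`` and relaxation time
    ``tau_r = 1/(alpha+beta)`` at membrane voltage ``v`` (mV).

    ``tau_r`` at -70 mV is the model's synaptic-depression recovery
    constant, the quantity the paired-pulse protocol measures.
    """
    u = cav_drive(v, model.cav)
    a_inf, tau = _steady_and_tau(u, model.rab)
    if np.asarray(v).ndim:
        return a_inf, tau
    return float(a_inf), float(tau)


def step_rab(state: RABState, u: float, dt: float, params: RABParams) -> RABState:
    """Advance the active fraction by ``dt`` at constant drive.

    Exponential-Euler update ``A' = A_inf + (A - A_inf) exp(-dt/tau)``,
    exact for constant ``u``; the result stays in [0, 1].
    """
    a_inf, tau = _steady_and_tau(u, params)
    a = float(a_inf + (state.A - a_inf) * math.exp(-dt / tau))
    return RABState(A=min(1.0, max(0.0, a)))


def _relax_python(a_inf, decay, a0):
    # sample n carries the state at time n: the initial state advanced
    # through drive samples u[0..n], each held over its 1-ms interval
    out = np.empty_like(a_inf)
    a = a0
    for i in range(a_inf.size):
        a = a_inf[i] + (a - a_inf[i]) * decay[i]
        out[i] = a
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _relax_compiled = njit(cache=True)(_relax_python)
except Exception:  # pragma: no cover
    _relax_compiled = _relax_python


def rab_integrate(u: np.ndarray, a0: float, params: RABParams, dt: float = DT_MS) -> np.ndarray:
    """Active-fraction trajectory ``A[n]`` for a drive sample path.

    The initial state ``a0`` sits one sample before the trace; each
    drive sample ``u[n]`` is held constant over its 1-ms interval, so
    the exponential-Euler recursion is exact per step, and ``A[n]`` is
    the state at the end of interval ``n``.
    """
    a_inf, tau = _steady_and_tau(np.asarray(u, float), params)
    decay = np.exp(-dt / tau)
    return _relax_compiled(np.asarray(a_inf, float), decay, float(a0))


def synapse_output(state, u, params: RABParams):
    """Release rate ``r = alpha(u) * A * N`` (active->inactive flux)."""
    alpha, _ = rab_rates(u, params)
    a = state.A if isinstance(state, RABState) else np.asarray(state, float)
    out = np.asarray(alpha) * a * params.N
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# resting state and simulation
# ---------------------------------------------------------------------------


@dataclass
class RestingState:
    """Dark-adapted stable state: filter histories at their x = 0 value,
    RAB active fraction at its dark steady state."""

    l: float
    v_cone: float
    u: float
    A: float
    r: float
    output: float


def resting_state(model):
    """Stable state in darkness (x = 0), used to initialise simulations."""
    if isinstance(model, LNModel):
        return RestingState(l=0.0, v_cone=0.0, u=0.0, A=0.0, r=0.0, output=0.0)
    v = cone_nl(0.0, model.cone_ln)
    u = cav_drive(v, model.cav)
    a_inf, _ = _steady_and_tau(u, model.rab)
    a_inf = float(a_inf)
    r = synapse_output(RABState(A=a_inf), u, model.rab)
    if model.variant == "cbc":
        out = 0.0  # output is reported relative to this resting value
    else:
        out = r  # sensor kernel has unit DC gain
    return RestingState(l=0.0, v_cone=v, u=u, A=a_inf, r=r, output=out)


def _check_luminance(stimulus: Trace) -> None:
    if stimulus.kind != "luminance":
        raise TraceError("stimulus must be a luminance trace")
    if not np.all(np.isin(stimulus.values, (0.0, 1.0))):
        raise TraceError("stimulus must be binary")


def release_from_drive(
    u: np.ndarray, rab: RABParams, u_rest: float, a_rest: float
) -> tuple[np.ndarray, np.ndarray]:
    """Active fraction and release rate for a smooth drive sample path.

    The kinetics step holds the interval-midpoint drive (the filtered
    drive ramps within each 1-ms interval); the release-rate output
    evaluates ``alpha`` at the sample times.  Shared by the simulator
    and the fitting objectives so both follow the same discretisation.
    """
    u = np.asarray(u, float)
    u_mid = 0.5 * (np.concatenate(([u_rest], u[:-1])) + u)
    a = rab_integrate(u_mid, a_rest, rab)
    alpha, _ = rab_rates(u, rab)
    return a, alpha * a * rab.N


def simulate_ln(model: LNModel, stimulus: Trace) -> Trace:
    """LN response: filtered stimulus through the sigmoid, relative to
    the dark resting output so that x = 0 maps to 0."""
    _check_luminance(stimulus)
    slowest = model.filter.gamma * max(model.filter.tau_rise, model.filter.tau_decay)
    length = max(1000, int(math.ceil(8.0 * slowest)))
    kernel = photoreceptor_kernel(model.filter, length)
    l = convolve_causal(stimulus, kernel, pad_value=0.0)
    v = sigmoid_nl(l.values, model.nl) - sigmoid_nl(0.0, model.nl)
    return Trace(values=v, kind="voltage_mV", t0=stimulus.t0)


def simulate_lns(model: LNSModel, stimulus: Trace) -> dict[str, Trace]:
    """Run the full cascade from a binary light stimulus.

    Returns the inner variables alongside the output: ``v_cone`` (mV),
    ``drive`` (dimensionless), ``A`` (active fraction), ``r`` (release
    rate) and ``output`` (variant-dependent).  The model starts from its
    dark resting state.
    """
    _check_luminance(stimulus)
    rest = resting_state(model)
    kernel = exponential_kernel(model.cone_ln.tau_L)
    l = convolve_causal(stimulus, kernel, pad_value=0.0)
    v = cone_nl(np.clip(l.values, 0.0, None), model.cone_ln)
    u = cav_drive(v, model.cav)
    a, r = release_from_drive(u, model.rab, rest.u, rest.A)
    t0 = stimulus.t0
    if model.variant == "cbc":
        out = sigmoid_nl(r, model.output_nl) - sigmoid_nl(rest.r, model.output_nl)
        out_kind = "voltage_mV"
    else:
        sensor = exponential_kernel(model.sensor_tau)
        # midpoint values again: the release rate varies within each interval
        r_mid = 0.5 * (np.concatenate(([rest.r], r[:-1])) + r)
        out = convolve_causal(
            Trace(values=r_mid, kind="release", t0=t0), sensor, pad_value=rest.r
        ).values
        out_kind = "fluorescence"
    return {
        "v_cone": Trace(values=v, kind="voltage_mV", t0=t0),
        "drive": Trace(values=u, kind="drive", t0=t0),
        "A": Trace(values=a, kind="drive", t0=t0),
        "r": Trace(values=r, kind="rate", t0=t0),
        "output": Trace(values=out, kind=out_kind, t0=t0),
    }


def synaptic_block_only(model: LNSModel, v_cone: Trace) -> Trace:
    """Drive the synaptic block directly with a voltage-clamp trace.

    Bypasses the cell block; the kinetics start at the steady state of
    the trace's first sample.  This mimics recording EPSC-like outputs
    while commanding the presynaptic voltage.
    """
    if v_cone.kind != "voltage_mV":
        raise TraceError("synaptic block input must be a voltage trace")
    u = cav_drive(v_cone.values, model.cav)
    a_inf0, _ = _steady_and_tau(u[0], model.rab)
    a = rab_integrate(u, float(a_inf0), model.rab)
    alpha, _ = rab_rates(u, model.rab)
    return Trace(values=alpha * a * model.rab.N, kind="rate", t0=v_cone.t0)


# ---------------------------------------------------------------------------
# JSON model files
# ---------------------------------------------------------------------------


def _model_to_dict(model) -> dict:
    if isinstance(model, LNModel):
        return {
            "variant": "ln",
            "fixed": {
                "filter": {
                    k: v for k, v in asdict(model.filter).items() if k != "gamma"
                }
            },
            "free": {"gamma": model.filter.gamma, "nl": asdict(model.nl)},
        }
    d = {
        "variant": model.variant,
        "fixed": {"cone_ln": asdict(model.cone_ln), "cav": asdict(model.cav)},
        "free": {"rab": asdict(model.rab)},
    }
    if model.variant == "cbc":
        d["free"]["output_nl"] = asdict(model.output_nl)
    else:
        d["fixed"]["sensor_tau"] = model.sensor_tau
    return d


def _model_from_dict(d: dict):
    variant = d["variant"]
    if variant == "ln":
        return LNModel(
            filter=PhotoFilterParams(gamma=d["free"]["gamma"], **d["fixed"]["filter"]),
            nl=SigmoidParams(**d["free"]["nl"]),
        )
    kwargs = dict(
        variant=variant,
        cone_ln=ConeLNParams(**d["fixed"]["cone_ln"]),
        cav=CaVParams(**d["fixed"]["cav"]),
        rab=RABParams(**d["free"]["rab"]),
    )
    if variant == "cbc":
        kwargs["output_nl"] = SigmoidParams(**d["free"]["output_nl"])
    else:
        kwargs["sensor_tau"] = d["fixed"].get("sensor_tau", 60.0)
    return LNSModel(**kwargs)


def save_model(model, path) -> None:
    """Write a model as JSON with explicit fixed/free parameter groups."""
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=2)


def load_model(path):
    """Read a model written by :func:`save_model` (lossless round trip)."""
    with open(path) as fh:
        return _model_from_dict(json.load(fh))
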