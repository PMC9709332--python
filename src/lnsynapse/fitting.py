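"""Model fitting: objectives, constraints, and multi-start Nelder-Mead.

Two objective kinds mirror the two experiment families:

``cbc_features``
    Sum of absolute differences between simulated and target features --
    the per-frequency peak responses plus the 1-Hz peak-to-base ratio
    (which pins the curve's overall amplitude), equally weighted.
``cone_trace``
    Sum of absolute differences between the simulated and the target
    sensor trace, each normalised (rest subtracted, divided by peak
    magnitude) so the comparison is scale-free.

Free parameters are positive and optimised in log space, which keeps
Nelder-Mead unconstrained; the biophysical requirement that every time
constant exceed 1 ms over the working voltage range enters as a smooth
penalty.  Multi-start initial points are drawn log-uniformly from broad
parameter ranges with a seeded generator, so fits are reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .model_core import (
    LNModel,
    LNSModel,
    _relax_compiled as _relax,
    PhotoFilterParams,
    RABParams,
    SigmoidParams,
    TAU_MIN_MS,
    VOLTAGE_GRID,
    adaptation_properties,
    cav_drive,
    cone_nl,
    convolve_causal,
    exponential_kernel,
    rab_integrate,
    rab_rates,
    release_from_drive,
    resting_state,
    sigmoid_nl,
    simulate_lns,
)
from .protocols import (
    peak_response_cbc,
    peak_response_cone,
    peak_to_base_ratio,
    square_wave_stimulus,
)
from .synthetic_data import CBCFeatures, ConeTraceData
from .trace import Trace

__all__ = [
    "FitSpec",
    "FitResult",
    "cbc_feature_error",
    "cone_trace_error",
    "constraint_penalty",
    "fit_model",
]

logger = logging.getLogger(__name__)

#: Log-uniform sampling ranges for multi-start initial points.
DEFAULT_RANGES = {
    "A_s": (1e-6, 1e-1),
    "B_s": (0.3, 3.0),
    "C_s": (1e-6, 1e-1),
    "k_s": (0.01, 2.0),
    "n_s": (0.2, 2.5),
    "N": (10.0, 5000.0),
    "m": (5.0, 60.0),
    "half": (0.2, 6.0),
    "slope": (0.05, 2.0),
    "gamma": (0.05, 10.0),
}

_FREE_PARAMS = {
    "ln": ("gamma", "m", "half", "slope"),
    "cbc": ("A_s", "B_s", "C_s", "k_s", "n_s", "N", "m", "half", "slope"),
    "cone_release": ("A_s", "B_s", "C_s", "k_s", "n_s", "N"),
}

_LOG_FLOOR = 1e-12


@dataclass
class FitSpec:
    """Optimisation problem definition.

    ``model`` is the template supplying the fixed blocks and the variant;
    its free parameters seed the first local start.  ``objective``
    selects the error kind.  The optimiser runs a seeded
    differential-evolution exploration over the log-parameter box, then
    Nelder-Mead refinement from the template and from the ``n_starts - 1``
    best distinct explorer candidates; the non-smooth L1 objective
    defeats purely local simplex descent from random starts.
    """

    model: object
    objective: str  # cbc_features | cone_trace
    n_starts: int = 4
    maxiter: int = 2000
    polish_maxiter: int = 2000
    de_popsize: int = 15
    de_maxiter: int = 200
    xatol: float = 1e-6
    fatol: float = 1e-9
    seed: int = 0
    ranges: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.objective not in ("cbc_features", "cone_trace"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.n_starts < 1:
            raise ValueError("need at least one start")


@dataclass
class FitResult:
    """Best model, its objective, per-start summaries, and the derived
    adaptation report (A_inf and tau_r over the working voltage grid)."""

    model: object
    objective: float
    starts: list
    adaptation_v: np.ndarray
    adaptation_a_inf: np.ndarray
    adaptation_tau_r: np.ndarray
    tau_r_70_ms: float
    a_inf_70: float

    def to_json(self, path) -> None:
        from .model_core import _model_to_dict

        with open(path, "w") as fh:
            json.dump(
                {
                    "model": _model_to_dict(self.model),
                    "objective": self.objective,
                    "tau_r_70_ms": self.tau_r_70_ms,
                    "a_inf_70": self.a_inf_70,
                    "starts": self.starts,
                    "adaptation": {
                        "v_mV": self.adaptation_v.tolist(),
                        "a_inf": self.adaptation_a_inf.tolist(),
                        "tau_r_ms": self.adaptation_tau_r.tolist(),
                    },
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------


class _CbcSimulator:
    """Per-frequency drive traces precomputed once per fit.

    The cell block of the LNS-cbc model is fully fixed, so the calcium
    drive under each stimulus does not depend on the free parameters;
    only the kinetics and the output sigmoid are re-evaluated per
    objective call.  Rate laws are evaluated as ``exp(p * log u)`` on
    precomputed log-drives, and the output sigmoid only on the feature
    windows (last period, 1-Hz plateau), which keeps a single objective
    call near a millisecond without changing the computed features.
    """

    def __init__(self, model: LNSModel, freqs: Sequence[float]):
        self.freqs = sorted(float(f) for f in freqs)
        self.cav = model.cav
        self.u_rest = cav_drive(cone_nl(0.0, model.cone_ln), model.cav)
        kernel = exponential_kernel(model.cone_ln.tau_L)
        self.drives = []
        for f in self.freqs:
            stim = square_wave_stimulus(f)
            l = convolve_causal(stim, kernel, pad_value=0.0)
            v = cone_nl(np.clip(l.values, 0.0, None), model.cone_ln)
            u = cav_drive(v, model.cav)
            u_mid = 0.5 * (np.concatenate(([self.u_rest], u[:-1])) + u)
            period = int(round(1000.0 / f))
            # feature windows: the whole last period for the peak, the
            # end of the light half-cycle for the 1-Hz plateau
            w0 = u.size - period
            self.drives.append(
                dict(
                    f=f,
                    log_u_mid=np.log(u_mid),
                    log_u_win=np.log(u[w0:]),
                    period=period,
                    w0=w0,
                )
            )

    def features(self, rab: RABParams, output_nl: SigmoidParams):
        n_s, B_s, kn = rab.n_s, rab.B_s, rab.k_s**rab.n_s
        base_rest = rab.A_s * self.u_rest**B_s + rab.C_s
        a_inf_rest = kn / (kn + self.u_rest**n_s)
        r_rest = base_rest * rab.N  # alpha * A_inf collapses to the base factor
        out_rest = sigmoid_nl(r_rest, output_nl)
        peaks = np.empty(len(self.drives))
        ratio = None
        for i, d in enumerate(self.drives):
            un = np.exp(n_s * d["log_u_mid"])
            s = kn + un
            base = rab.A_s * np.exp(B_s * d["log_u_mid"]) + rab.C_s
            a_inf = kn / s
            decay = np.exp(-base * s * s / (kn * un))  # exp(-(alpha+beta)*dt)
            a = _relax(a_inf, decay, a_inf_rest)[d["w0"] :]
            alpha_w = (
                (rab.A_s * np.exp(B_s * d["log_u_win"]) + rab.C_s)
                * (kn + np.exp(n_s * d["log_u_win"]))
                / kn
            )
            out = sigmoid_nl(alpha_w * a * rab.N, output_nl) - out_rest
            peaks[i] = float(np.max(out))
            if d["f"] == 1.0:
                half = d["period"] // 2
                base = abs(float(np.mean(out[half - 50 : half])))
                if base < 1e-12:
                    raise ValueError("light-phase plateau is zero; ratio undefined")
                ratio = peaks[i] / base
        return peaks, ratio


class _LnSimulator:
    """Cached stimuli for fitting an LN model to CBC feature tables.

    The photoreceptor kernel depends on the free ``gamma``, so the
    convolution is redone per call (FFT-based for the long traces).
    """

    def __init__(self, freqs: Sequence[float]):
        self.freqs = sorted(float(f) for f in freqs)
        self.stims = [square_wave_stimulus(f) for f in self.freqs]

    def features(self, model: LNModel):
        from .model_core import simulate_ln

        peaks = np.empty(len(self.freqs))
        ratio = None
        for i, (f, stim) in enumerate(zip(self.freqs, self.stims)):
            out = simulate_ln(model, stim)
            peaks[i] = peak_response_cbc(out, 1000.0 / f)
            if f == 1.0:
                ratio = peak_to_base_ratio(out, 1000.0)
        return peaks, ratio


def cbc_feature_error(model, target: CBCFeatures) -> float:
    """L1 feature mismatch against a CBC feature table.

    Accepts either an LNS-cbc model or an LN model (the baseline the
    synapse block is compared against).
    """
    freqs = target.curve.frequencies
    if not np.any(np.isclose(freqs, 1.0)):
        raise ValueError("target features must include the 1-Hz entry")
    if isinstance(model, LNModel):
        peaks, ratio = _LnSimulator(freqs).features(model)
    else:
        sim = _CbcSimulator(model, freqs)
        peaks, ratio = sim.features(model.rab, model.output_nl)
    return float(
        np.sum(np.abs(peaks - target.curve.peaks)) + abs(ratio - target.ratio_at_1hz)
    )


def _normalise(values: np.ndarray, rest: float) -> np.ndarray:
    shifted = values - rest
    peak = np.max(np.abs(shifted))
    if peak < 1e-12:
        raise ValueError("trace is constant after rest subtraction")
    return shifted / peak


def cone_trace_error(model: LNSModel, target: ConeTraceData) -> float:
    """L1 mismatch between normalised sensor traces.

    Both traces are shifted by their pre-stimulus rest and scaled by
    their peak magnitude, so the comparison is amplitude-free.
    """
    sim = simulate_lns(model, target.stimulus)["output"]
    if len(sim) != len(target.trace):
        raise ValueError("simulated and target traces must share length")
    sim_n = _normalise(sim.values, resting_state(model).output)
    tgt_n = _normalise(target.trace.values, float(target.trace.values[0]))
    return float(np.sum(np.abs(sim_n - tgt_n)))


def constraint_penalty(model, weight: float = 1e4) -> float:
    """Smooth penalty keeping every model time constant above 1 ms.

    Zero when ``tau_r(V) >= 1 ms`` across the working voltage grid and
    all filter time constants are admissible; grows linearly with the
    worst violation, so it is continuous at the boundary.
    """
    viol = 0.0
    if isinstance(model, LNModel):
        tau_filter = model.filter.gamma * min(model.filter.tau_rise, model.filter.tau_decay)
        viol += max(0.0, TAU_MIN_MS - tau_filter)
    else:
        _, tau = adaptation_properties(VOLTAGE_GRID, model)
        viol += max(0.0, TAU_MIN_MS - float(np.min(tau)))
        viol += max(0.0, TAU_MIN_MS - model.cone_ln.tau_L)
        if model.sensor_tau is not None:
            viol += max(0.0, TAU_MIN_MS - model.sensor_tau)
    return weight * viol


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------


def _kind_of(model) -> str:
    return "ln" if isinstance(model, LNModel) else model.variant


def _pack(model) -> np.ndarray:
    kind = _kind_of(model)
    vals = []
    for name in _FREE_PARAMS[kind]:
        if kind == "ln":
            src = {"gamma": model.filter.gamma, "m": model.nl.m,
                   "half": model.nl.half, "slope": model.nl.slope}[name]
        elif name in ("m", "half", "slope"):
            src = getattr(model.output_nl, name)
        else:
            src = getattr(model.rab, name)
        vals.append(math.log(max(float(src), _LOG_FLOOR)))
    return np.array(vals)


def _unpack(x: np.ndarray, template) -> object:
    kind = _kind_of(template)
    vals = dict(zip(_FREE_PARAMS[kind], np.exp(x)))
    if kind == "ln":
        return LNModel(
            filter=replace(template.filter, gamma=vals["gamma"]),
            nl=SigmoidParams(m=vals["m"], half=vals["half"], slope=vals["slope"]),
        )
    rab = RABParams(
        A_s=vals["A_s"], B_s=vals["B_s"], C_s=vals["C_s"],
        k_s=vals["k_s"], n_s=vals["n_s"], N=vals["N"],
    )
    if kind == "cbc":
        return replace(
            template,
            rab=rab,
            output_nl=SigmoidParams(m=vals["m"], half=vals["half"], slope=vals["slope"]),
        )
    return replace(template, rab=rab)


# ---------------------------------------------------------------------------
# the optimiser
# ---------------------------------------------------------------------------


def fit_model(spec: FitSpec, data) -> FitResult:
    """Global-then-local fit; deterministic for a given seed.

    A seeded differential-evolution stage explores the log-parameter
    box; Nelder-Mead then refines the template start and the best
    distinct explorer candidates, and the winner gets a final tighter
    Nelder-Mead polish.  Raises if no start produces a finite objective.
    """
    template = spec.model
    kind = _kind_of(template)
    if spec.objective == "cbc_features":
        if kind == "cone_release":
            raise ValueError("cbc_features objective requires a cbc or LN model")
        if kind == "ln":
            sim = _LnSimulator(data.curve.frequencies)
            sim_features = sim.features
        else:
            _sim = _CbcSimulator(template, data.curve.frequencies)

            def sim_features(model):
                return _sim.features(model.rab, model.output_nl)

        target_peaks = data.curve.peaks
        target_ratio = data.ratio_at_1hz

        def error(model):
            peaks, ratio = sim_features(model)
            return float(
                np.sum(np.abs(peaks - target_peaks)) + abs(ratio - target_ratio)
            )

    else:
        if kind == "ln":
            raise ValueError("cone_trace objective requires an LNS model")

        def error(model):
            return cone_trace_error(model, data)

    def objective(x):
        try:
            model = _unpack(x, template)
            return error(model) + constraint_penalty(model)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12

    names = _FREE_PARAMS[kind]
    ranges = {**DEFAULT_RANGES, **spec.ranges}
    bounds = [
        (math.log(ranges[n][0]), math.log(ranges[n][1])) for n in names
    ]

    records = []
    best_x, best_f = None, np.inf
    with np.errstate(all="ignore"):
        explorer = differential_evolution(
            objective,
            bounds=bounds,
            seed=spec.seed,
            maxiter=spec.de_maxiter,
            popsize=spec.de_popsize,
            mutation=(0.5, 1.2),
            recombination=0.8,
            tol=1e-10,
            init="sobol",
            updating="deferred",
            polish=False,
        )
        order = np.argsort(explorer.population_energies)
        candidates = [("template", _pack(template))]
        for j in order[: spec.n_starts - 1]:
            candidates.append((f"explorer[{j}]", explorer.population[j]))
        for i, (label, x0) in enumerate(candidates):
            res = minimize(
                objective, x0, method="Nelder-Mead",
                options=dict(maxiter=spec.maxiter, xatol=spec.xatol,
                             fatol=spec.fatol, adaptive=True),
            )
            logger.debug("start %s: f=%.6g nit=%d", label, res.fun, res.nit)
            records.append(
                {"start": label, "objective": float(res.fun), "iterations": int(res.nit)}
            )
            if res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
        if best_x is None or not np.isfinite(best_f):
            raise RuntimeError("all optimisation starts failed to produce a finite objective")
        polish = minimize(
            objective, best_x, method="Nelder-Mead",
            options=dict(maxiter=spec.polish_maxiter, xatol=spec.xatol / 10,
                         fatol=spec.fatol / 10, adaptive=True),
        )
        if polish.fun <= best_f:
            best_x, best_f = polish.x, float(polish.fun)

    best_model = _unpack(best_x, template)
    if isinstance(best_model, LNSModel):
        a_inf, tau = adaptation_properties(VOLTAGE_GRID, best_model)
        a70, tau70 = adaptation_properties(-70.0, best_model)
    else:
        a_inf = tau = np.full(VOLTAGE_GRID.size, np.nan)
        a70 = tau70 = float("nan")
    return FitResult(
        model=best_model,
        objective=best_f,
        starts=records,
        adaptation_v=VOLTAGE_GRID.copy(),
        adaptation_a_inf=np.asarray(a_inf),
        adaptation_tau_r=np.asarray(tau),
        tau_r_70_ms=float(tau70),
        a_inf_70=float(a70),
    )
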