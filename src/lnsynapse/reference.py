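"""Brute-force fine-timestep integrator for cross-checking simulations.

Independent of the 1-ms production path in :mod:`lnsynapse.model_core`:
the linear filters are advanced as first-order ODEs and the two-state
kinetics ``dA/dt = beta (1 - A) - alpha A`` by plain forward Euler at a
small substep (default 0.01 ms), with the drive re-evaluated every
substep.  Used to bound the discretisation error of the exponential-
Euler 1-ms scheme.
"""

from __future__ import annotations

import numpy as np

from .model_core import LNSModel, cav_drive, cone_nl, rab_rates, resting_state
from .trace import Trace


def _fine_loop_python(x_fine, dt, tau_L, hill_amp, hill_exp, hill_halfn, offset,
                      gain, e_rev, v_half, k_slope, u_rest,
                      A_s, B_s, C_s, kn, n_s, a0, l0):
    n = x_fine.size
    l_out = np.empty(n)
    a_out = np.empty(n)
    u_out = np.empty(n)
    l = l0
    a = a0
    decay_l = np.exp(-dt / tau_L)
    for i in range(n):
        # filter: exact for the piecewise-constant stimulus substep
        l = x_fine[i] + (l - x_fine[i]) * decay_l
        ln = l**hill_exp
        v = hill_amp * ln / (ln + hill_halfn) + offset
        u = gain * (e_rev - v) / (1.0 + np.exp(-(v - v_half) / k_slope)) + u_rest
        base = A_s * u**B_s + C_s
        un = u**n_s
        s = kn + un
        alpha = base * s / kn
        beta = base * s / un
        a = a + dt * (beta * (1.0 - a) - alpha * a)
        l_out[i] = l
        a_out[i] = a
        u_out[i] = u
    return l_out, a_out, u_out


try:  # pragma: no cover
    from numba import njit

    _fine_loop = njit(cache=True)(_fine_loop_python)
except Exception:  # pragma: no cover
    _fine_loop = _fine_loop_python


def simulate_lns_fine(model: LNSModel, stimulus: Trace, dt: float = 0.01) -> dict[str, np.ndarray]:
    """Integrate the full cascade at substep ``dt`` (ms).

    Returns arrays sampled back on the stimulus' 1-ms grid, keyed like
    the production simulator.  The stimulus sample ``x[n]`` is treated
    as constant on ``(n-1, n]``, matching the causal-convolution
    convention of the 1-ms path, and the run starts one full sample
    before ``t0`` from the dark resting state.
    """
    k = int(round(1.0 / dt))
    if abs(k * dt - 1.0) > 1e-9:
        raise ValueError("dt must divide 1 ms")
    x = stimulus.values
    rest = resting_state(model)
    # substep j covers time (-1 + j*dt, -1 + (j+1)*dt]; stimulus index floor(j/k)
    x_fine = np.repeat(x, k)
    p = model.cone_ln
    c = model.cav
    r = model.rab
    l_f, a_f, u_f = _fine_loop(
        x_fine, dt, p.tau_L, p.hill_amp, p.hill_exp, p.hill_half**p.hill_exp,
        p.offset, c.gain, c.e_rev, c.v_half, c.k_slope, c.u_resting,
        r.A_s, r.B_s, r.C_s, r.k_s**r.n_s, r.n_s, rest.A, rest.l,
    )
    # sample n of the 1-ms path sits at time n: substep index (n+1)*k - 1
    idx = (np.arange(x.size) + 1) * k - 1
    l = l_f[idx]
    a = a_f[idx]
    u = u_f[idx]
    v = cone_nl(np.clip(l, 0.0, None), p)
    alpha, _ = rab_rates(u, r)
    rel = alpha * a * r.N
    out = {"l": l, "v_cone": v, "drive": u, "A": a, "r": rel}
    if model.variant == "cone_release":
        # sensor low-pass integrated at the fine step as well
        rel_f = None
        alpha_f, _ = rab_rates(u_f, r)
        rel_f = alpha_f * a_f * r.N
        decay = np.exp(-dt / model.sensor_tau)
        s = np.empty_like(rel_f)
        acc = rest.r
        for i in range(rel_f.size):
            acc = rel_f[i] + (acc - rel_f[i]) * decay
            s[i] = acc
        out["output"] = s[idx]
    else:
        from .model_core import sigmoid_nl

        out["output"] = sigmoid_nl(rel, model.output_nl) - sigmoid_nl(
            rest.r, model.output_nl
        )
    return out
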