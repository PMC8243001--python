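"""The double two-state opsin model.

The photocurrent is ``i(t) = g * G(V) * O(t) * R(t) * (V - E)`` where ``O``
is the open fraction and ``R`` the dark-adaptation conductance factor.  Both
gates relax first-order toward irradiance-dependent steady states:

    dO/dt = (O_inf(I) - O) / tau_O(I, V)
    dR/dt = (R_inf(I) - R) / tau_R(I, V)

Under voltage clamp and a rectangular light pulse the solution is a product
of mono-exponentials and is evaluated in closed form; for arbitrary light
waveforms the pair of ODEs is integrated numerically.

All intensity dependencies are logistic functions of log10 irradiance; the
``I = 0`` values are defined by their limits (``tau_O(0) = p3``,
``tau_R(0) = p1``, ``O_inf(0) = 0``, ``R_inf(0) = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .params import GatingState, OpsinParams
from .protocols import ClampProtocol

__all__ = [
    "PhotocurrentTrace",
    "two_pulse_ratio_curve",
    "tau_O",
    "tau_R",
    "O_inf",
    "R_inf",
    "driving_force",
    "rectification",
    "state_derivatives",
    "current_closed_form",
    "simulate_clamp_ode",
    "check_decay_constraint",
]


@dataclass(frozen=True)
class PhotocurrentTrace:
    """Sampled photocurrent with stimulus metadata.

    ``current`` is in the units implied by the parameter set's conductance
    mode (uA/cm^2 for density, nA for absolute with mV driving force).
    ``O`` and ``R`` carry the gating trajectories when the trace was
    produced by this package's simulators.
    """

    t: np.ndarray
    current: np.ndarray
    protocol: ClampProtocol
    conductance_mode: str = "density"
    O: np.ndarray | None = None
    R: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if t.ndim != 1 or t.shape != i.shape:
            raise ValueError("t and current must be 1-D arrays of equal length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "current", i)


def _log10I(I):
    I = np.asarray(I, dtype=float)
    if np.any(~np.isfinite(I)) or np.any(I < 0):
        raise ValueError("irradiance must be finite and >= 0")
    with np.errstate(divide="ignore"):
        return np.where(I > 0, np.log10(np.maximum(I, 1e-300)), -np.inf)


def _check_V(V):
    V = np.asarray(V, dtype=float)
    if np.any(~np.isfinite(V)):
        raise ValueError("potential must be finite")
    return V


def _combine(tau_i, tau_v, scheme: str):
    if scheme == "product":
        return tau_i * tau_v
    # reciprocal sum; written to stay finite when one part dominates
    return tau_i * tau_v / (tau_i + tau_v)


def _tauO_I(I, p):
    p1, p2, p3 = p
    return p3 * expit(-(p1 + _log10I(I)) / p2)


def _tauR_I(I, p):
    p1, p2, p3, p4, p5, p6 = p
    x = _log10I(I)
    # L(a, b) -> 0 as I -> 0, -> 1 as I -> inf
    L1 = expit((x - p3) / p4)
    L2 = expit((x - p5) / p6)
    return p1 * (1.0 - p2 * L1 - (1.0 - p2) * L2)


def _tau_V(V, p):
    p1, p2, p3 = p
    return p1 * expit((_check_V(V) - p2) / p3)


def tau_O(I, V, params: OpsinParams):
    """Open-state time constant (s) at irradiance ``I`` and potential ``V``."""
    return _combine(_tauO_I(I, params.tauO_I), _tau_V(V, params.tauO_V), params.combine_O)


def tau_R(I, V, params: OpsinParams):
    """Adaptation time constant (s); seconds-scale in darkness, fast under light."""
    return _combine(_tauR_I(I, params.tauR_I), _tau_V(V, params.tauR_V), params.combine_R)


def O_inf(I, params: OpsinParams):
    """Open-state steady state in [0, 1]; 0 in darkness, rises with log10 I."""
    p1, p2 = params.Oinf
    return expit((_log10I(I) - p1) / p2)


def R_inf(I, params: OpsinParams):
    """Adaptation steady state in [1 - p3, 1]; 1 in darkness."""
    p1, p2, p3 = params.Rinf
    return 1.0 - p3 * expit((_log10I(I) - p1) / p2)


def driving_force(V, params: OpsinParams):
    """Rectified driving force ``D(V) = G(V) * (V - E)`` in mV.

    Evaluated in the algebraically cancelled form
    ``p1 * (1 - p2 * exp(-(V - E) / p3))`` so there is no 0/0 at ``V = E``.
    Without a rectification block this is simply ``V - E``.
    """
    V = _check_V(V)
    if params.Grect is None:
        return V - params.E
    p1, p2, p3 = params.Grect
    return p1 * (1.0 - p2 * np.exp(-(V - params.E) / p3))


def rectification(V, params: OpsinParams):
    """The bare rectification factor ``G(V)``; singular at ``V = E``.

    Only used for constraint checking on a voltage grid that excludes the
    reversal potential; the current itself always goes through
    :func:`driving_force`.
    """
    V = _check_V(V)
    if params.Grect is None:
        return np.ones_like(V, dtype=float)
    dv = V - params.E
    if np.any(dv == 0):
        raise ValueError("G(V) is singular at V = E; evaluate driving_force instead")
    return driving_force(V, params) / dv


def state_derivatives(state: GatingState, I, V, params: OpsinParams):
    """Time derivatives (dO/dt, dR/dt) in 1/s for the given stimulus."""
    dO = (O_inf(I, params) - state.O) / tau_O(I, V, params)
    dR = (R_inf(I, params) - state.R) / tau_R(I, V, params)
    return float(dO), float(dR)


def _gating_on(t_rel, I, V, params, O0, R0):
    """O and R during the light pulse, time measured from pulse onset."""
    Oi, Ri = O_inf(I, params), R_inf(I, params)
    # floor the taus: degenerate parameter draws can make them vanish, and
    # the instantaneous-equilibration limit is the correct continuation
    to = np.maximum(tau_O(I, V, params), 1e-12)
    tr = np.maximum(tau_R(I, V, params), 1e-12)
    O = Oi - (Oi - O0) * np.exp(-t_rel / to)
    R = Ri - (Ri - R0) * np.exp(-t_rel / tr)
    return O, R


def _gating_dark(t_rel, V, params, O0, R0):
    """Dark relaxation: O decays to 0, R recovers to 1."""
    to = np.maximum(tau_O(0.0, V, params), 1e-12)
    tr = np.maximum(tau_R(0.0, V, params), 1e-12)
    O = O0 * np.exp(-t_rel / to)
    R = 1.0 - (1.0 - R0) * np.exp(-t_rel / tr)
    return O, R


def current_closed_form(
    t: Sequence[float],
    protocol: ClampProtocol,
    params: OpsinParams,
    init: GatingState = GatingState(0.0, 1.0),
) -> PhotocurrentTrace:
    """Closed-form photocurrent under voltage clamp and a rectangular pulse.

    The on-interval is treated as closed at ``t_off`` (the plateau read-out
    is exactly the on-branch value at the pulse end); samples strictly after
    ``t_off`` follow the dark-decay branch.  Samples before ``t_on`` relax
    from ``init`` (given at ``t = 0``) under darkness, which for the default
    fully dark-adapted state is identically zero current.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or np.any(t < 0) or np.any(t > protocol.t_end + 1e-12):
        raise ValueError("time grid must be 1-D within [0, t_end]")
    V, I = protocol.V, protocol.I
    O = np.empty_like(t)
    R = np.empty_like(t)

    pre = t < protocol.t_on
    on = (t >= protocol.t_on) & (t <= protocol.t_off)
    post = t > protocol.t_off

    O[pre], R[pre] = _gating_dark(t[pre], V, params, init.O, init.R)
    O0, R0 = _gating_dark(protocol.t_on, V, params, init.O, init.R)
    O[on], R[on] = _gating_on(t[on] - protocol.t_on, I, V, params, O0, R0)
    Ooff, Roff = _gating_on(protocol.pulse_duration, I, V, params, O0, R0)
    O[post], R[post] = _gating_dark(t[post] - protocol.t_off, V, params, Ooff, Roff)

    i = params.g * driving_force(V, params) * O * R
    return PhotocurrentTrace(
        t=t, current=i, protocol=protocol,
        conductance_mode=params.conductance_mode, O=O, R=R,
    )


def simulate_clamp_ode(
    protocol: ClampProtocol,
    params: OpsinParams,
    t_eval: Sequence[float] | None = None,
    waveform: Callable[[float], float] | None = None,
    init: GatingState = GatingState(0.0, 1.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    max_step: float = np.inf,
) -> PhotocurrentTrace:
    """Integrate the gating ODEs under voltage clamp.

    With ``waveform=None`` the rectangular pulse of ``protocol`` is used and
    the integration is split at the pulse edges (the light level is
    discontinuous there).  ``waveform`` may be any piecewise-continuous
    nonnegative ``I(t)``; it then overrides the pulse and is integrated over
    ``[0, t_end]`` in one pass.
    """
    V = protocol.V
    if t_eval is None:
        t_eval = np.arange(0.0, protocol.t_end + 1e-12, 1.5e-4)
    t_eval = np.asarray(t_eval, dtype=float)

    if waveform is None:
        def I_of_t(t):
            return protocol.I if protocol.t_on <= t <= protocol.t_off else 0.0
        breakpoints = [0.0, protocol.t_on, protocol.t_off, protocol.t_end]
    else:
        I_of_t = waveform
        breakpoints = [0.0, protocol.t_end]

    def rhs(t, y):
        I = I_of_t(t)
        return [
            (O_inf(I, params) - y[0]) / tau_O(I, V, params),
            (R_inf(I, params) - y[1]) / tau_R(I, V, params),
        ]

    ts, Os, Rs = [], [], []
    y0 = [init.O, init.R]
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        if b <= a:
            continue
        seg_mask = (t_eval >= a) & (t_eval <= b)
        seg_t = np.unique(np.concatenate([[a], t_eval[seg_mask], [b]]))
        sol = solve_ivp(
            rhs, (a, b), y0, method=method, t_eval=seg_t,
            rtol=rtol, atol=atol, max_step=max_step,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed in [{a}, {b}] near t={sol.t[-1]:.6g}: {sol.message}"
            )
        y0 = sol.y[:, -1].tolist()
        keep = np.isin(sol.t, t_eval[seg_mask])
        ts.append(sol.t[keep])
        Os.append(sol.y[0][keep])
        Rs.append(sol.y[1][keep])

    t_all = np.concatenate(ts)
    O_all = np.concatenate(Os)
    R_all = np.concatenate(Rs)
    # pulse edges may be sampled twice (segment ends); keep first occurrence
    t_u, idx = np.unique(t_all, return_index=True)
    O_u, R_u = O_all[idx], R_all[idx]
    i = params.g * driving_force(V, params) * O_u * R_u
    return PhotocurrentTrace(
        t=t_u, current=i, protocol=protocol,
        conductance_mode=params.conductance_mode, O=O_u, R=R_u,
    )


def two_pulse_ratio_curve(
    params: OpsinParams,
    I: float,
    V: float,
    gaps: Sequence[float],
    pulse1_s: float = 0.5,
    pulse2_s: float = 0.5,
    dt: float = 1e-3,
) -> np.ndarray:
    """Probe/conditioning peak-current ratio versus dark-gap duration.

    Both pulses share irradiance and voltage; the probe starts from the
    gating state reached at the end of each dark gap.  Peaks are raw
    magnitudes read off a grid of step ``dt`` (matching how two-pulse
    recordings are sampled), so the ratio tends to the first pulse's
    steady-state/peak ratio as the gap shrinks and to 1 as it grows.
    """
    gaps = np.asarray(gaps, dtype=float)
    K = params.g * float(driving_force(V, params))
    t1 = np.arange(0.0, pulse1_s + 1e-12, dt)
    O1, R1 = _gating_on(t1, I, V, params, 0.0, 1.0)
    peak1 = np.max(np.abs(K * O1 * R1))
    O_end, R_end = _gating_on(pulse1_s, I, V, params, 0.0, 1.0)

    O0, R0 = _gating_dark(gaps, V, params, O_end, R_end)  # shape (n_gaps,)
    t2 = np.arange(0.0, pulse2_s + 1e-12, dt)
    Oi, Ri = O_inf(I, params), R_inf(I, params)
    to = np.maximum(tau_O(I, V, params), 1e-12)
    tr = np.maximum(tau_R(I, V, params), 1e-12)
    eO = np.exp(-t2 / to)[None, :]
    eR = np.exp(-t2 / tr)[None, :]
    O2 = Oi - (Oi - O0[:, None]) * eO
    R2 = Ri - (Ri - R0[:, None]) * eR
    peak2 = np.max(np.abs(K * O2 * R2), axis=1)
    return peak2 / peak1


def check_decay_constraint(params: OpsinParams, V, I_grid) -> tuple[bool, float]:
    """Check that the current decays back to baseline after the pulse.

    The off-phase current shrinks monotonically whenever
    ``R_inf(I) > 1 - tau_R(0,V) / (tau_R(0,V) + tau_O(0,V))`` at every
    stimulus on the grid.  Returns ``(passed, worst_margin)`` where the
    margin is ``min R_inf - bound`` (strictly positive means pass).
    """
    V = np.atleast_1d(_check_V(V))
    I_grid = np.atleast_1d(np.asarray(I_grid, dtype=float))
    tr0 = tau_R(0.0, V, params)
    to0 = tau_O(0.0, V, params)
    bound = 1.0 - tr0 / (tr0 + to0)          # shape (nV,)
    rinf = R_inf(I_grid, params)             # shape (nI,)
    margins = rinf[:, None] - bound[None, :]
    worst = float(margins.min())
    return worst > 0.0, worst
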