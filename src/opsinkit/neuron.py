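"""Conductance-based regular-spiking cortical neuron with an opsin current.

Single-compartment model with leak, transient Na+, delayed-rectifier K+ and
slow non-inactivating (M-type) K+ conductances, Traub-style kinetics shifted
by a spike-threshold parameter ``VT``, and spike-frequency adaptation set by
the M-current time scale ``tau_max``.  The published regular-spiking
parameter set ships as ``fixtures/rs_neuron.json``.

The opsin (density mode, mS/cm^2) couples into the membrane equation with
its signed current -- inward (negative) photocurrents depolarize -- and its
two gating ODEs are integrated together with the five neuron states.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import model
from .params import OpsinParams
from .protocols import PulseTrainProtocol

__all__ = [
    "NeuronConfig",
    "NeuronSimResult",
    "load_neuron",
    "rs_neuron",
    "resting_state",
    "single_pulse_protocol",
    "simulate_rs_neuron",
    "detect_spikes",
    "firing_rate",
]


@dataclass(frozen=True)
class NeuronConfig:
    """Membrane parameters: conductances mS/cm^2, potentials mV, Cm uF/cm^2."""

    cm: float = 1.0
    g_leak: float = 0.0205
    e_leak: float = -70.3
    g_na: float = 56.0
    e_na: float = 50.0
    g_kd: float = 6.0
    e_k: float = -90.0
    g_m: float = 0.075
    tau_max_ms: float = 608.0
    vt: float = -56.2

    def __post_init__(self):
        if min(self.g_leak, self.g_na, self.g_kd, self.g_m) < 0 or self.cm <= 0:
            raise ValueError("conductances must be >= 0 and cm > 0")


def load_neuron(path) -> NeuronConfig:
    with open(path) as fh:
        d = json.load(fh)
    return NeuronConfig(
        cm=d["cm_uF_cm2"], g_leak=d["g_leak_mS_cm2"], e_leak=d["e_leak_mV"],
        g_na=d["g_na_mS_cm2"], e_na=d["e_na_mV"], g_kd=d["g_kd_mS_cm2"],
        e_k=d["e_k_mV"], g_m=d["g_m_mS_cm2"], tau_max_ms=d["tau_max_ms"],
        vt=d["vt_mV"],
    )


def rs_neuron() -> NeuronConfig:
    """The bundled regular-spiking cortical parameter set."""
    text = resources.files("opsinkit.fixtures").joinpath("rs_neuron.json").read_text()
    d = json.loads(text)
    return NeuronConfig(
        cm=d["cm_uF_cm2"], g_leak=d["g_leak_mS_cm2"], e_leak=d["e_leak_mV"],
        g_na=d["g_na_mS_cm2"], e_na=d["e_na_mV"], g_kd=d["g_kd_mS_cm2"],
        e_k=d["e_k_mV"], g_m=d["g_m_mS_cm2"], tau_max_ms=d["tau_max_ms"],
        vt=d["vt_mV"],
    )


def _vtrap(x: float, y: float) -> float:
    """x / (exp(x / y) - 1) with the removable singularity filled in."""
    r = x / y
    if abs(r) < 1e-6:
        return y * (1.0 - r / 2.0)
    return x / (math.exp(r) - 1.0)


def _gate_rates(V: float, vt: float):
    """Traub-style alpha/beta pairs (1/ms) for m, h, n at potential V."""
    am = 0.32 * _vtrap(-(V - vt - 13.0), 4.0)
    bm = 0.28 * _vtrap(V - vt - 40.0, 5.0)
    ah = 0.128 * math.exp(-(V - vt - 17.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(V - vt - 40.0) / 5.0))
    an = 0.032 * _vtrap(-(V - vt - 15.0), 5.0)
    bn = 0.5 * math.exp(-(V - vt - 10.0) / 40.0)
    return am, bm, ah, bh, an, bn


def _m_gate(V: float, tau_max_ms: float):
    p_inf = 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))
    tau_p = tau_max_ms / (3.3 * math.exp((V + 35.0) / 20.0) + math.exp(-(V + 35.0) / 20.0))
    return p_inf, tau_p


def _membrane_current(V: float, m, h, n, p, cfg: NeuronConfig) -> float:
    """Total intrinsic ionic current (uA/cm^2, positive outward)."""
    return (cfg.g_na * m**3 * h * (V - cfg.e_na)
            + cfg.g_kd * n**4 * (V - cfg.e_k)
            + cfg.g_m * p * (V - cfg.e_k)
            + cfg.g_leak * (V - cfg.e_leak))


def resting_state(cfg: NeuronConfig) -> np.ndarray:
    """Stable rest: V where the steady-state current vanishes, gates at inf."""
    def i_ss(V):
        am, bm, ah, bh, an, bn = _gate_rates(V, cfg.vt)
        m = am / (am + bm)
        h = ah / (ah + bh)
        n = an / (an + bn)
        p, _ = _m_gate(V, cfg.tau_max_ms)
        return _membrane_current(V, m, h, n, p, cfg)

    # bracket the hyperpolarized stable fixed point (avoid the unstable
    # branch where the Na current takes over near threshold)
    grid = np.arange(-95.0, -49.9, 2.5)
    vals = [i_ss(v) for v in grid]
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            b, fb = a, fa
            break
        if fa * fb < 0:
            break
    else:
        raise ValueError("no stable resting potential in [-95, -50] mV")
    V0 = a if fa == 0.0 else brentq(i_ss, a, b)
    am, bm, ah, bh, an, bn = _gate_rates(V0, cfg.vt)
    p0, _ = _m_gate(V0, cfg.tau_max_ms)
    return np.array([V0, am / (am + bm), ah / (ah + bh), an / (an + bn), p0])


@dataclass(frozen=True)
class NeuronSimResult:
    """Membrane-potential and opsin-current trajectories plus spike times."""

    t: np.ndarray
    V: np.ndarray
    O: np.ndarray
    R: np.ndarray
    i_opsin: np.ndarray
    spikes: np.ndarray
    protocol: PulseTrainProtocol


def single_pulse_protocol(irradiance: float, pd_s: float, total_s: float) -> PulseTrainProtocol:
    """One rectangular light pulse of duration ``pd_s`` starting at t = 0."""
    if total_s < pd_s:
        raise ValueError("total_s must cover the pulse")
    return PulseTrainProtocol(irradiance=irradiance, prf_hz=1.0 / total_s,
                              duty=pd_s / total_s, stim_s=pd_s, total_s=total_s)


def _opsin_rhs_terms(params: OpsinParams, I: float):
    """Per-segment constants of the opsin ODEs (intensity parts)."""
    return (
        float(model._tauO_I(I, params.tauO_I)),
        float(model._tauR_I(I, params.tauR_I)),
        float(model.O_inf(I, params)),
        float(model.R_inf(I, params)),
    )


def simulate_rs_neuron(
    opsin: OpsinParams | None,
    protocol: PulseTrainProtocol,
    neuron: NeuronConfig | None = None,
    rtol: float = 1e-3,
    atol: float = 1e-6,
    max_step: float = 1e-4,
    sample_dt: float = 1e-4,
    method: str = "LSODA",
) -> NeuronSimResult:
    """Integrate the coupled neuron + opsin system under a light protocol.

    A variable-step, variable-order solver with a 100 us maximum step and
    relative/absolute tolerances 1e-3/1e-6 by default.  The integration is
    split at the light edges, where the irradiance is discontinuous.
    ``opsin=None`` (or zero-conductance opsin) simulates the bare neuron.
    """
    neuron = neuron or rs_neuron()
    if opsin is not None and opsin.conductance_mode != "density":
        raise ValueError("neuron coupling needs a density-mode (mS/cm^2) opsin")

    cm, vt, tmx = neuron.cm, neuron.vt, neuron.tau_max_ms
    y0 = np.concatenate([resting_state(neuron), [0.0, 1.0]])

    # segment edges: light on/off transitions inside [0, total_s]
    edges = {0.0, protocol.total_s}
    for a, b in protocol.on_windows():
        edges.add(a)
        edges.add(b)
    edges = sorted(e for e in edges if 0.0 <= e <= protocol.total_s)
    on_windows = protocol.on_windows()

    def light_at(t):
        return protocol.irradiance if any(a <= t < b for a, b in on_windows) else 0.0

    if opsin is not None:
        oE = opsin.E
        grect = opsin.Grect
        g_ops = opsin.g
        oV1, oV2, oV3 = opsin.tauO_V
        rV1, rV2, rV3 = opsin.tauR_V
        comb_O, comb_R = opsin.combine_O, opsin.combine_R

    def drive(V):
        if grect is None:
            return V - oE
        ex = -(V - oE) / grect[2]
        return grect[0] * (1.0 - grect[1] * math.exp(ex if ex < 60 else 60))

    def tau_v(V, p1, p2, p3):
        x = (V - p2) / p3
        if x > 60:
            return p1
        if x < -60:
            return p1 * 1e-26
        return p1 / (1.0 + math.exp(-x))

    def comb(ti, tv, scheme):
        return ti * tv if scheme == "product" else ti * tv / (ti + tv)

    ts, ys = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        I_seg = light_at(a)
        if opsin is not None:
            tOi, tRi, Oi, Ri = _opsin_rhs_terms(opsin, I_seg)

        def rhs(t, y):
            V, m, h, n, p, O, R = y
            am, bm, ah, bh, an, bn = _gate_rates(V, vt)
            p_inf, tau_p = _m_gate(V, tmx)
            if opsin is not None:
                i_ops = g_ops * drive(V) * O * R
                tO = comb(tOi, tau_v(V, oV1, oV2, oV3), comb_O)
                tR = comb(tRi, tau_v(V, rV1, rV2, rV3), comb_R)
                dO = (Oi - O) / max(tO, 1e-9)
                dR = (Ri - R) / max(tR, 1e-9)
            else:
                i_ops, dO, dR = 0.0, 0.0, 0.0
            i_ion = _membrane_current(V, m, h, n, p, neuron) + i_ops
            return [
                -1e3 * i_ion / cm,
                1e3 * (am * (1.0 - m) - bm * m),
                1e3 * (ah * (1.0 - h) - bh * h),
                1e3 * (an * (1.0 - n) - bn * n),
                1e3 * (p_inf - p) / tau_p,
                dO,
                dR,
            ]

        # arange with float steps can overshoot the stop; clip strictly to
        # [a, b) before closing the segment at b
        seg_t = np.arange(a, b, sample_dt)
        seg_t = seg_t[seg_t < b - 1e-12]
        seg_t = np.append(seg_t, b)
        sol = solve_ivp(rhs, (a, b), y0, method=method, t_eval=seg_t,
                        rtol=rtol, atol=atol, max_step=max_step)
        if not sol.success:
            raise RuntimeError(f"neuron solver failed near t={sol.t[-1]:.6g}: {sol.message}")
        y0 = sol.y[:, -1]
        ts.append(sol.t)
        ys.append(sol.y)

    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    t, idx = np.unique(t, return_index=True)
    Y = Y[:, idx]
    V, O, R = Y[0], Y[5], Y[6]
    if opsin is not None:
        D = model.driving_force(V, opsin)
        i_ops = opsin.g * D * O * R
    else:
        i_ops = np.zeros_like(V)
    return NeuronSimResult(
        t=t, V=V, O=O, R=R, i_opsin=i_ops,
        spikes=detect_spikes(t, V), protocol=protocol,
    )


def detect_spikes(t: Sequence[float], V: Sequence[float],
                  threshold: float = 0.0, refractory_s: float = 1e-3) -> np.ndarray:
    """Spike times: upward threshold crossings at least ``refractory_s`` apart."""
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    up = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold))
    times = t[up + 1]
    keep = []
    last = -np.inf
    for x in times:
        if x - last >= refractory_s:
            keep.append(x)
            last = x
    return np.asarray(keep)


def firing_rate(spikes: Sequence[float], protocol: PulseTrainProtocol,
                mode: str = "on") -> float:
    """Spike rate in Hz.

    ``mode="on"`` (default): spikes during light-on phases divided by the
    total on-time -- how stimulation-locked firing is usually reported.
    ``mode="window"``: all spikes divided by the total simulated time.
    """
    spikes = np.asarray(spikes, dtype=float)
    if mode == "window":
        return len(spikes) / protocol.total_s
    if mode != "on":
        raise ValueError("mode must be 'on' or 'window'")
    on_time = protocol.total_on_time
    if on_time <= 0:
        raise ValueError("protocol has zero light-on time")
    n = sum(int(np.sum((spikes >= a) & (spikes < b))) for a, b in protocol.on_windows())
    return n / on_time
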