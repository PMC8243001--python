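"""Synthetic voltage-clamp data from known model parameters.

Emulates the standard characterization experiments for an opsin: a grid of
single rectangular light pulses over irradiance and holding potential, and
two-pulse recovery series, with additive white Gaussian recording noise.
Because the generating parameters are known, the emitted ground-truth
feature table makes extraction and fitting testable end to end.

What this does *not* emulate: series-resistance and capacitive artifacts,
colored recording noise, liquid-junction offsets.  Passing tests on this
data therefore validates the numerics of extraction and fitting, not their
robustness to instrumentation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from . import model
from .features import FeatureSet
from .params import GatingState, OpsinParams
from .protocols import ClampProtocol, TwoPulseProtocol

__all__ = ["SynthConfig", "generate_clamp_traces", "generate_two_pulse_series", "exact_recovery_time"]


def _default_irradiances():
    return tuple(np.logspace(2, 4, 5))


def _default_voltages():
    return tuple(np.arange(-80.0, 41.0, 20.0))


def _default_intervals():
    return tuple(np.geomspace(0.3, 25.0, 12))


@dataclass(frozen=True)
class SynthConfig:
    """Study design of the synthetic experiments.

    Defaults mirror a typical opsin characterization: five log-spaced
    irradiances over 1e2..1e4 W/m^2, holding potentials -80..+40 mV in 20 mV
    steps, 0.5 s pulses sampled at 0.15 ms, and two-pulse recovery series at
    the three highest irradiances (1 ms sampling).  Noise is additive white
    Gaussian with standard deviation ``noise_sigma_rel`` times the largest
    peak on the grid.
    """

    params: OpsinParams | None = None     # default: RSRS-final fixture
    irradiances: tuple[float, ...] = field(default_factory=_default_irradiances)
    voltages: tuple[float, ...] = field(default_factory=_default_voltages)
    t_on: float = 0.05
    pulse_s: float = 0.5
    post_s: float = 0.4
    dt: float = 1.5e-4
    recovery_irradiances: tuple[float, ...] | None = None  # default: 3 highest
    recovery_voltages: tuple[float, ...] | None = None     # default: all
    intervals: tuple[float, ...] = field(default_factory=_default_intervals)
    dt_two_pulse: float = 1e-3
    pulse2_s: float = 0.5
    noise_sigma_rel: float = 0.01
    seed: int = 0

    def resolved_params(self) -> OpsinParams:
        if self.params is not None:
            return self.params
        from .params import fixture
        return fixture("rsrs_final")

    def resolved_recovery_grid(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        Is = self.recovery_irradiances or tuple(sorted(self.irradiances)[-3:])
        Vs = self.recovery_voltages or self.voltages
        return tuple(Is), tuple(Vs)


def exact_recovery_time(
    params: OpsinParams, I: float, V: float,
    pulse1_s: float = 0.5, pulse2_s: float = 0.5, dt: float = 1e-3,
    gap_bounds: tuple[float, float] = (1e-3, 200.0),
) -> float:
    """Dark gap at which the model's probe/conditioning peak ratio is 1 - 1/e.

    Solved by root finding on the closed-form two-pulse ratio curve; this is
    the generating model's own recovery time, free of interpolation error.
    """
    thr = 1.0 - np.exp(-1.0)

    def f(gap):
        return float(model.two_pulse_ratio_curve(
            params, I, V, [gap], pulse1_s, pulse2_s, dt)[0]) - thr

    lo, hi = gap_bounds
    if f(lo) > 0:
        raise ValueError("ratio already above threshold at the smallest gap")
    if f(hi) < 0:
        raise ValueError("no recovery within the gap search bounds")
    return float(brentq(f, lo, hi, xtol=1e-6))


def _ground_truth_features(cfg: SynthConfig) -> FeatureSet:
    p = cfg.resolved_params()
    fs = FeatureSet()
    t_grid = np.arange(0.0, cfg.pulse_s + 1e-12, cfg.dt)
    for V in cfg.voltages:
        D = float(model.driving_force(V, p))
        if abs(D) < 1e-9:      # at the reversal potential nothing is measurable
            continue
        K = p.g * D
        for I in cfg.irradiances:
            O, R = model._gating_on(t_grid, I, V, p, 0.0, 1.0)
            i_on = np.abs(K * O * R)
            fs.add(I, V, "I_peak", float(i_on.max()))
            fs.add(I, V, "I_ss", float(i_on[-1]))
            fs.add(I, V, "I_ratio", float(i_on[-1] / i_on.max()))
            fs.add(I, V, "tau_on", float(model.tau_O(I, V, p)))
            fs.add(I, V, "tau_inact", float(model.tau_R(I, V, p)))
            fs.add(I, V, "tau_off", float(model.tau_O(0.0, V, p)))
    rec_I, rec_V = cfg.resolved_recovery_grid()
    for V in rec_V:
        if abs(float(model.driving_force(V, p))) < 1e-9:
            continue
        for I in rec_I:
            fs.add(I, V, "tau_recov", exact_recovery_time(
                p, I, V, cfg.pulse_s, cfg.pulse2_s, cfg.dt_two_pulse))
    return fs


def generate_clamp_traces(
    cfg: SynthConfig = SynthConfig(),
) -> tuple[dict[tuple[float, float], model.PhotocurrentTrace], FeatureSet]:
    """Single-pulse traces on the (irradiance, voltage) grid + ground truth.

    Returns ``(traces, truth)`` where ``traces[(I, V)]`` is a
    :class:`PhotocurrentTrace` (noisy if ``noise_sigma_rel > 0``) and
    ``truth`` holds the generating model's feature values.  Conditions at
    the reversal potential produce (noisy) zero traces and carry no truth
    rows.
    """
    p = cfg.resolved_params()
    rng = np.random.default_rng(cfg.seed)
    t_end = cfg.t_on + cfg.pulse_s + cfg.post_s
    t = np.arange(0.0, t_end + 1e-12, cfg.dt)

    clean = {}
    peak_max = 0.0
    for I in cfg.irradiances:
        for V in cfg.voltages:
            prot = ClampProtocol(V=V, I=I, t_on=cfg.t_on,
                                 t_off=cfg.t_on + cfg.pulse_s, t_end=t_end)
            tr = model.current_closed_form(t, prot, p)
            clean[(I, V)] = tr
            peak_max = max(peak_max, float(np.abs(tr.current).max()))

    sigma = cfg.noise_sigma_rel * peak_max
    traces = {}
    for key, tr in clean.items():
        cur = tr.current
        if sigma > 0:
            cur = cur + rng.normal(0.0, sigma, size=cur.shape)
        traces[key] = model.PhotocurrentTrace(
            t=tr.t, current=cur, protocol=tr.protocol,
            conductance_mode=tr.conductance_mode, O=tr.O, R=tr.R)
    return traces, _ground_truth_features(cfg)


def generate_two_pulse_series(
    cfg: SynthConfig = SynthConfig(),
) -> dict[tuple[float, float], tuple[np.ndarray, np.ndarray]]:
    """Two-pulse recovery series: ``{(I, V): (intervals, peak_ratios)}``.

    The probe pulse starts from the exact gating state at the end of each
    dark gap.  With noise enabled, both peaks are read from noisy sampled
    segments, propagating recording noise into the ratios.  Emits a warning
    via ``RuntimeWarning`` when the interval grid does not span recovery.
    """
    import warnings

    p = cfg.resolved_params()
    rng = np.random.default_rng(cfg.seed + 1)
    rec_I, rec_V = cfg.resolved_recovery_grid()
    gaps = np.asarray(cfg.intervals, dtype=float)

    # reuse the single-pulse grid maximum for the noise scale
    sigma = 0.0
    if cfg.noise_sigma_rel > 0:
        _, truth = generate_clamp_traces(
            SynthConfig(**{**cfg.__dict__, "noise_sigma_rel": 0.0}))
        peaks = truth.df[truth.df.feature == "I_peak"].value
        sigma = cfg.noise_sigma_rel * float(peaks.max())

    out = {}
    thr = 1.0 - np.exp(-1.0)
    for V in rec_V:
        if abs(float(model.driving_force(V, p))) < 1e-9:
            continue
        for I in rec_I:
            ratios = model.two_pulse_ratio_curve(
                p, I, V, gaps, cfg.pulse_s, cfg.pulse2_s, cfg.dt_two_pulse)
            if sigma > 0:
                t1 = np.arange(0.0, cfg.pulse_s + 1e-12, cfg.dt_two_pulse)
                O1, R1 = model._gating_on(t1, I, V, p, 0.0, 1.0)
                K = p.g * float(model.driving_force(V, p))
                base = np.abs(K * O1 * R1)
                p1 = np.max(base + rng.normal(0, sigma, base.shape))
                ratios = np.maximum(
                    (ratios * p1 + rng.normal(0, sigma, ratios.shape)) / p1, 1e-6)
            if ratios.min() > thr or ratios.max() < thr:
                warnings.warn(
                    f"two-pulse grid does not span recovery at (I={I:g}, V={V:g})",
                    RuntimeWarning)
            out[(I, V)] = (gaps.copy(), np.asarray(ratios))
    return out
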