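"""Voltage-clamp feature extraction.

Seven features characterize a photocurrent recording: the transient peak
``I_peak``, the plateau ``I_ss``, their ratio ``I_ratio``, three
mono-exponential time constants (activation ``tau_on``, inactivation
``tau_inact``, deactivation ``tau_off``) and the dark-recovery constant
``tau_recov`` measured with two-pulse protocols.  These are the targets of
the fitting procedure and the quantities the goodness-of-fit metrics score.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, least_squares

from .model import PhotocurrentTrace
from .protocols import ClampProtocol

__all__ = [
    "FEATURE_NAMES",
    "RECOVERY_THRESHOLD",
    "FeatureSet",
    "ExtractConfig",
    "DegenerateTraceError",
    "MonoExpFitError",
    "RecoveryRangeError",
    "fit_monoexp",
    "extract_features",
    "recovery_time",
]

FEATURE_NAMES = ("I_peak", "I_ss", "I_ratio", "tau_on", "tau_inact", "tau_off", "tau_recov")

#: a probe peak recovered to 1 - 1/e of the conditioning peak defines tau_recov
RECOVERY_THRESHOLD = 1.0 - np.exp(-1.0)


class DegenerateTraceError(ValueError):
    """Trace carries no usable pulse response (flat, constant, or no pulse)."""


class MonoExpFitError(RuntimeError):
    """No multistart of the mono-exponential fit converged."""


class RecoveryRangeError(ValueError):
    """The two-pulse interval grid does not bracket the recovery threshold."""


@dataclass(frozen=True)
class ExtractConfig:
    """Tunables of the extraction step.

    ``guard_samples`` drops that many samples after each pulse edge before
    the exponential fits (edge samples sit on the discontinuity).
    ``plateau_frac`` is the fraction of the on-phase averaged for the
    plateau estimate; on noiseless data it coincides with the end sample.
    """

    guard_samples: int = 1
    plateau_frac: float = 0.05
    n_starts: int = 10
    seed: int = 0
    min_samples: int = 4
    tol: float = 1e-12


class FeatureSet:
    """Long-form table of features keyed by (irradiance, voltage).

    Stored as a DataFrame with columns ``irradiance_W_m2, voltage_mV,
    feature, value, sigma`` (sigma may be NaN).  Current-like features are
    stored as magnitudes; time constants in seconds.
    """

    COLUMNS = ("irradiance_W_m2", "voltage_mV", "feature", "value", "sigma")

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=list(self.COLUMNS))
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        self.df = df.reset_index(drop=True)[list(self.COLUMNS)]

    def add(self, I: float, V: float, feature: str, value: float, sigma: float = np.nan):
        if feature not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {feature!r}")
        row = pd.DataFrame(
            [[float(I), float(V), feature, float(value), float(sigma)]],
            columns=list(self.COLUMNS),
        )
        self.df = row if self.df.empty else pd.concat([self.df, row], ignore_index=True)

    def get(self, I: float, V: float, feature: str) -> float:
        sel = self.df[
            np.isclose(self.df.irradiance_W_m2, I)
            & np.isclose(self.df.voltage_mV, V)
            & (self.df.feature == feature)
        ]
        if len(sel) == 0:
            raise KeyError(f"no {feature} at (I={I}, V={V})")
        return float(sel.value.iloc[0])

    def has(self, I: float, V: float, feature: str) -> bool:
        try:
            self.get(I, V, feature)
            return True
        except KeyError:
            return False

    def conditions(self, feature: str | None = None) -> list[tuple[float, float]]:
        df = self.df if feature is None else self.df[self.df.feature == feature]
        pairs = df[["irradiance_W_m2", "voltage_mV"]].drop_duplicates()
        return [tuple(r) for r in pairs.to_numpy()]

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureSet":
        return cls(pd.read_csv(path))

    def copy(self) -> "FeatureSet":
        return FeatureSet(self.df.copy())


def _smart_tau_guesses(t, y, n_random, rng):
    """Initial tau guesses: log-linear regression plus a geometric sweep."""
    span = t[-1] - t[0]
    guesses = []
    resid = y - y[-1]
    s = np.sign(resid[0]) if resid[0] != 0 else 1.0
    pos = s * resid
    mask = pos > max(1e-3 * pos.max(initial=0.0), 0.0)
    if mask.sum() >= 3:
        slope = np.polyfit(t[mask], np.log(pos[mask]), 1)[0]
        if slope < 0:
            guesses.append(-1.0 / slope)
    guesses += list(span * np.geomspace(0.02, 2.0, 4))
    if n_random > 0:
        guesses += list(span * 10 ** rng.uniform(-2.3, 0.5, size=n_random))
    return guesses


def fit_monoexp(
    t: Sequence[float],
    y: Sequence[float],
    config: ExtractConfig = ExtractConfig(),
) -> tuple[float, float, float]:
    """Least-squares fit of ``y = A exp(-(t - t[0]) / tau) + C`` with tau > 0.

    A multistart trust-region-reflective fit (variable and function
    tolerances 1e-12); the best start by residual norm wins.  Raises
    :class:`DegenerateTraceError` for constant input and
    :class:`MonoExpFitError` if no start converges.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or len(t) < config.min_samples:
        raise ValueError(f"need >= {config.min_samples} samples of matching shape")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    spread = y.max() - y.min()
    if spread <= config.tol * max(1.0, np.abs(y).max()):
        raise DegenerateTraceError("constant trace: mono-exponential fit is undefined")

    t0 = t[0]

    def resid(theta):
        A, tau, C = theta
        return A * np.exp(-(t - t0) / tau) + C - y

    rng = np.random.default_rng(config.seed)
    n_random = max(0, config.n_starts - 5)
    best = None
    A0, C0 = y[0] - y[-1], y[-1]
    for tau0 in _smart_tau_guesses(t, y, n_random, rng)[: config.n_starts]:
        try:
            sol = least_squares(
                resid,
                x0=[A0, tau0, C0],
                bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=200,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15 or (
            abs(sol.cost - best.cost) <= 1e-15 and tuple(sol.x) < tuple(best.x)
        ):
            best = sol
    if best is None:
        raise MonoExpFitError("no mono-exponential multistart converged")
    A, tau, C = best.x
    return float(A), float(tau), float(C)


def extract_features(
    trace: PhotocurrentTrace,
    protocol: ClampProtocol | None = None,
    config: ExtractConfig = ExtractConfig(),
) -> dict[str, float | None]:
    """Single-pulse feature extraction.

    Baseline is the pre-pulse mean; ``I_peak`` the maximal absolute
    deflection during the pulse; ``I_ss`` the plateau estimate at pulse end;
    the three time constants come from mono-exponential fits on
    [t_on, t_peak], [t_peak, t_off] and [t_off, end].  A feature that cannot
    be measured (e.g. the peak sits on a pulse edge) is returned as ``None``.
    Raises :class:`DegenerateTraceError` when there is no pulse response.
    """
    if protocol is None:
        protocol = trace.protocol
    t, y = trace.t, trace.current
    on = (t >= protocol.t_on) & (t <= protocol.t_off)
    post = t > protocol.t_off
    if on.sum() < config.min_samples:
        raise DegenerateTraceError("trace does not cover the light pulse")

    pre = t < protocol.t_on
    baseline = float(y[pre].mean()) if pre.any() else 0.0
    dev = y - baseline

    t_on_seg, dev_on = t[on], dev[on]
    k_peak = int(np.argmax(np.abs(dev_on)))
    i_peak = float(np.abs(dev_on[k_peak]))
    if i_peak <= config.tol * max(1.0, np.abs(y).max()):
        raise DegenerateTraceError("no deflection from baseline during the pulse")

    n_pl = max(1, int(np.ceil(config.plateau_frac * on.sum())))
    i_ss = float(np.abs(dev_on[-n_pl:].mean()))
    out: dict[str, float | None] = {
        "I_peak": i_peak,
        "I_ss": i_ss,
        "I_ratio": i_ss / i_peak,
        "tau_on": None,
        "tau_inact": None,
        "tau_off": None,
    }

    g = config.guard_samples
    rise = slice(g, k_peak + 1)
    if k_peak + 1 - g >= config.min_samples:
        try:
            out["tau_on"] = fit_monoexp(t_on_seg[rise], dev_on[rise], config)[1]
        except (DegenerateTraceError, MonoExpFitError):
            pass
    decay = slice(k_peak, len(dev_on))
    if len(dev_on) - k_peak >= config.min_samples:
        try:
            out["tau_inact"] = fit_monoexp(t_on_seg[decay], dev_on[decay], config)[1]
        except (DegenerateTraceError, MonoExpFitError):
            pass
    t_post, dev_post = t[post][g:], dev[post][g:]
    if len(t_post) >= config.min_samples:
        try:
            out["tau_off"] = fit_monoexp(t_post, dev_post, config)[1]
        except (DegenerateTraceError, MonoExpFitError):
            pass
    return out


def recovery_time(
    intervals: Sequence[float],
    peak_ratios: Sequence[float],
) -> float:
    """Interpolate the dark gap at which the probe peak reaches 63% (1 - 1/e).

    ``peak_ratios`` are raw second/first peak magnitudes against the
    matching dark ``intervals`` (seconds, strictly increasing).  A monotone
    piecewise-cubic interpolant locates the crossing.
    """
    x = np.asarray(intervals, dtype=float)
    r = np.asarray(peak_ratios, dtype=float)
    if len(x) < 2 or x.shape != r.shape:
        raise ValueError("need >= 2 matched (interval, ratio) points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("intervals must be strictly increasing")
    if np.any((r <= 0) | (r > 1.0 + 1e-9)):
        raise ValueError("peak ratios must lie in (0, 1]")
    thr = RECOVERY_THRESHOLD
    exact = np.isclose(r, thr, rtol=0, atol=1e-12)
    if exact.any():
        return float(x[exact][0])
    if r.min() > thr:
        raise RecoveryRangeError("recovery faster than the interval grid resolves")
    if r.max() < thr:
        raise RecoveryRangeError("not recovered within the interval grid")
    f = PchipInterpolator(x, r - thr)
    roots = f.roots()
    roots = roots[(roots >= x[0]) & (roots <= x[-1])]
    if len(roots) == 0:  # fall back to bracketed bisection on the interpolant
        k = int(np.argmax(r > thr))
        return float(brentq(f, x[max(k - 1, 0)], x[k]))
    return float(roots[0])
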