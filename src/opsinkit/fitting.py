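"""Autonomous parameter inference for the double two-state opsin model.

The procedure runs in four steps:

1. feature extraction from voltage-clamp traces (``opsinkit.features``);
2. the two time constants ``tau_O`` and ``tau_R`` are fit to time-constant
   targets derived from the features (activation/deactivation map onto
   ``tau_O`` under light/darkness, inactivation onto ``tau_R`` under light,
   and the recovery time, rescaled by ``1 - ln(1/(1 - I_ratio))``, onto
   ``tau_R`` in darkness);
3. the equilibria ``O_inf`` and ``R_inf`` and the rectification ``G(V)``
   are fit by minimizing a weighted RMS cost over the current features,
   computed from the closed-form pulse response with the step-2 time
   constants frozen, under nonlinear constraints (``O_inf`` saturation,
   ``G >= 0``, and decay back to baseline after the pulse);
4. a bounded global refinement over *all* parameters inside a reduced box
   (10% of the original space centered on the intermediate fit) with a
   particle-swarm optimizer whose cost extracts model features from
   simulated traces with the same operations used on the data, followed by
   an optional bounded local polish of the best particle.

Because the photocurrent depends on products of parameters (notably
``g * Grect.p1``), success is measured by feature recovery, not by
parameter identity.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import model
from .features import (
    ExtractConfig,
    FeatureSet,
    RECOVERY_THRESHOLD,
    DegenerateTraceError,
    RecoveryRangeError,
    extract_features,
    recovery_time,
)
from .params import GatingState, OpsinParams
from .protocols import ClampProtocol

__all__ = [
    "FitConfig",
    "OpsinFit",
    "FitStageError",
    "ConstraintInfeasibleError",
    "ScalingInvalidError",
    "recovery_scale",
    "approximate_time_constant_targets",
    "fit_time_constants",
    "fit_equilibria",
    "global_refine_pso",
    "fit_pipeline",
    "model_features",
]

_EPS = 1e-6  # effective lower bound for strictly positive parameters

# parameter-space table: (lower, upper, start) per block, published search box
_SPACE_CHR2 = {
    "tauO_I": ([-10, _EPS, _EPS], [10, 20, 1], [1, 1, 0.5]),
    "tauO_V": ([_EPS, -100, -1000], [100, 100, 1000], [1, -50, 10]),
    "tauR_I": ([_EPS, 0, -10, _EPS, -10, _EPS], [10, 1, 10, 20, 10, 20], [1, 0.5, 0, 0.125, 3, 0.5]),
    "tauR_V": ([_EPS, -100, -1000], [100, 100, 1000], [1, -50, 10]),
    "Oinf": ([-10, _EPS], [10, 20], [1, 1]),
    "Rinf": ([-10, _EPS, 0], [10, 20, 1], [1, 1, 0.1]),
    "Grect": ([_EPS, 1.1, _EPS], [100, 100, 500], [1, 10, 50]),
}
_SPACE_MM = dict(
    _SPACE_CHR2,
    Rinf=([-10, _EPS, 0.8], [10, 20, 1], [1, 1, 0.9]),
    g=([_EPS], [100], [30]),
    E=([-100], [100], [0]),
)

#: training weights that level all seven features to a common magnitude
DEFAULT_WEIGHTS = {
    "I_peak": 10.0, "I_ss": 20.0, "I_ratio": 50.0,
    "tau_on": 1000.0, "tau_inact": 1000.0, "tau_off": 1000.0, "tau_recov": 20.0,
}


class FitStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ConstraintInfeasibleError(FitStageError):
    pass


class ScalingInvalidError(ValueError):
    """I_ratio too large for the recovery-time rescaling to be defined."""


@dataclass(frozen=True)
class OinfConstraint:
    """Saturation constraint on the open steady state at a given irradiance."""

    irradiance: float
    bound: float
    sense: str = "ge"  # "ge": O_inf >= bound; "le": O_inf <= bound


@dataclass
class FitConfig:
    """Search box, weights, budgets and constraints of the fitting procedure.

    ``mode="published"`` uses the published budgets (10/2000/3000 multistarts,
    1000 particles, 24 h swarm); ``mode="test"`` scales them to desk size
    while keeping every other study condition identical.
    """

    rectified: bool = True           # ChR2-style density mode with G(V)
    combine_O: str = "reciprocal_sum"
    combine_R: str = "reciprocal_sum"
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    oinf_constraints: tuple[OinfConstraint, ...] = (OinfConstraint(5500.0, 0.6, "ge"),)
    step1_starts: int = 10
    step2_starts: int = 2000
    step3_starts: int = 3000
    pso_particles: int = 1000
    pso_budget_s: float = 24 * 3600.0
    pso_max_iters: int = 10_000
    pso_inertia: float = 0.7298
    pso_cognitive: float = 1.49618
    pso_social: float = 1.49618
    reduced_fraction: float = 0.10
    polish: bool = True
    polish_max_nfev: int = 12
    dt_single: float = 1.5e-4
    dt_two_pulse: float = 1e-3
    t_on: float = 0.05
    pulse_s: float = 0.5
    post_s: float = 0.4
    intervals: tuple[float, ...] = tuple(np.geomspace(0.3, 25.0, 12))
    feature_starts: int = 1          # mono-exp starts inside the swarm cost (smart init)
    constraint_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.reduced_fraction <= 1.0:
            raise ValueError("reduced_fraction must be in (0, 1]")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be > 0")
        for blk, (lb, ub, x0) in self.space().items():
            if not all(l <= x <= u for l, x, u in zip(lb, x0, ub)):
                raise ValueError(f"start outside bounds in block {blk}")

    @classmethod
    def published(cls, **kw) -> "FitConfig":
        return cls(**kw)

    @classmethod
    def test(cls, **kw) -> "FitConfig":
        kw.setdefault("step2_starts", 50)
        kw.setdefault("step3_starts", 100)
        kw.setdefault("pso_particles", 60)
        kw.setdefault("pso_budget_s", 120.0)
        return cls(**kw)

    def space(self) -> dict:
        return _SPACE_CHR2 if self.rectified else _SPACE_MM

    # --- flattened full-parameter vector (step 4) -------------------------
    def blocks(self) -> tuple[str, ...]:
        common = ("tauO_I", "tauO_V", "tauR_I", "tauR_V", "Oinf", "Rinf")
        return common + (("Grect",) if self.rectified else ("g", "E"))

    def full_bounds(self):
        sp = self.space()
        lb = np.concatenate([sp[b][0] for b in self.blocks()]).astype(float)
        ub = np.concatenate([sp[b][1] for b in self.blocks()]).astype(float)
        return lb, ub

    def vector_of(self, p: OpsinParams) -> np.ndarray:
        parts = [p.tauO_I, p.tauO_V, p.tauR_I, p.tauR_V, p.Oinf, p.Rinf]
        parts.append(p.Grect if self.rectified else (p.g, p.E))
        return np.concatenate([np.asarray(x, dtype=float) for x in parts])

    def params_of(self, theta: np.ndarray, name: str = "") -> OpsinParams:
        t = np.asarray(theta, dtype=float)
        o = dict(tauO_I=t[0:3], tauO_V=t[3:6], tauR_I=t[6:12], tauR_V=t[12:15],
                 Oinf=t[15:17], Rinf=t[17:20])
        if self.rectified:
            o.update(Grect=tuple(t[20:23]), g=1.0, E=0.0, conductance_mode="density")
        else:
            o.update(Grect=None, g=float(t[20]), E=float(t[21]), conductance_mode="absolute")
        return OpsinParams(combine_O=self.combine_O, combine_R=self.combine_R,
                           name=name, **o)


@dataclass
class OpsinFit:
    """Result of the pipeline: intermediate (post step 3) and final params."""

    intermediate: OpsinParams
    final: OpsinParams
    cost_intermediate: float
    cost_final: float
    cost_trace: list = field(default_factory=list)
    constraint_margin: float = np.nan
    residuals: pd.DataFrame | None = None
    budget_exhausted: bool = False


# --------------------------------------------------------------------------
# step 2: time-constant targets and fits
# --------------------------------------------------------------------------

def recovery_scale(I_ratio: float) -> float:
    """Factor mapping the measured recovery time onto ``tau_R(0, V)``.

    ``tau_R(0,V) = tau_recov / (1 - ln(1/(1 - I_ratio)))``; undefined once
    ``I_ratio >= 1 - 1/e`` (the probe would recover above threshold before
    any dark adaptation happens).
    """
    if not 0.0 < I_ratio < 1.0:
        raise ValueError(f"I_ratio must be in (0,1), got {I_ratio}")
    denom = 1.0 - np.log(1.0 / (1.0 - I_ratio))
    if denom <= 0.0:
        raise ScalingInvalidError(
            f"I_ratio={I_ratio:.3f} >= 1 - 1/e: recovery rescaling undefined")
    return 1.0 / denom


def _ratio_near(features: FeatureSet, I: float, V: float) -> float:
    """I_ratio at (I, V), or from the nearest condition that has one.

    Two-pulse series are often recorded at a holding potential without a
    matching single-pulse recording; the ratio varies slowly with voltage,
    so the closest condition (same irradiance preferred) stands in.
    """
    if features.has(I, V, "I_ratio"):
        return features.get(I, V, "I_ratio")
    sub = features.df[features.df.feature == "I_ratio"]
    if sub.empty:
        raise KeyError(f"no I_ratio anywhere to rescale tau_recov at (I={I}, V={V})")
    dist = (np.abs(np.log10(np.maximum(sub.irradiance_W_m2, 1e-12)) - np.log10(max(I, 1e-12))) * 1e3
            + np.abs(sub.voltage_mV - V))
    row = sub.loc[dist.idxmin()]
    warnings.warn(
        f"no I_ratio at (I={I:g}, V={V:g}); using the one at "
        f"(I={row.irradiance_W_m2:g}, V={row.voltage_mV:g}) for the recovery rescaling")
    return float(row.value)


def approximate_time_constant_targets(features: FeatureSet) -> pd.DataFrame:
    """Map extracted features onto (gate, I, V) -> tau targets.

    tau_O targets: tau_on at (I, V) and tau_off at (0, V); tau_R targets:
    tau_inact at (I, V) and the rescaled recovery time at (0, V).  Raises
    :class:`ScalingInvalidError` when a recovery condition's I_ratio makes
    the rescaling undefined.
    """
    rows = []
    for I, V in features.conditions():
        for feat, gate, dark in (("tau_on", "O", False), ("tau_off", "O", True),
                                 ("tau_inact", "R", False)):
            if features.has(I, V, feat):
                rows.append((gate, 0.0 if dark else I, V, features.get(I, V, feat)))
        if features.has(I, V, "tau_recov"):
            rows.append(("R", 0.0, V,
                         features.get(I, V, "tau_recov")
                         * recovery_scale(_ratio_near(features, I, V))))
    if not rows:
        raise FitStageError("targets", "feature set contains no time constants")
    return pd.DataFrame(rows, columns=["gate", "irradiance_W_m2", "voltage_mV", "tau"])


def _multistart_ls(resid, lb, ub, x0, n_starts, rng, refine_top: int = 0,
                   screen_nfev: int = 60, n_full: int = 0, **ls_kw):
    """Bounded multistart least squares; ties broken lexicographically.

    ``x0`` may be a single start or a list; random starts are drawn
    uniformly in the (clipped) box up to ``n_starts`` total.  With
    ``refine_top > 0`` the multistart runs in two phases: every start gets
    a cheap screening fit (``screen_nfev`` evaluations) and the best
    screened candidates are refined at full budget.  The first ``n_full``
    provided starts are always refined fully, regardless of screening.
    """
    x0 = np.asarray(x0, dtype=float)
    starts = [x0] if x0.ndim == 1 else [np.asarray(s) for s in x0]
    lo, hi = np.asarray(lb, dtype=float), np.asarray(ub, dtype=float)
    span = np.minimum(hi, 1e3) - np.maximum(lo, -1e3)
    base = np.maximum(lo, -1e3)
    for _ in range(max(0, n_starts - len(starts))):
        starts.append(base + span * rng.random(len(lo)))

    def run(s, nfev_cap):
        kw = dict(ls_kw)
        if nfev_cap is not None:
            kw["max_nfev"] = nfev_cap
        try:
            return least_squares(resid, s, bounds=(lo, hi), method="trf",
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12, **kw)
        except Exception:
            return None

    def better(a, b):
        return b is None or a.cost < b.cost - 1e-15 or (
            abs(a.cost - b.cost) <= 1e-15 and tuple(a.x) < tuple(b.x))

    best = None
    if refine_top > 0:
        for s in starts[:n_full]:
            sol = run(s, None)
            if sol is not None and better(sol, best):
                best = sol
        screened = [sol for sol in (run(s, screen_nfev) for s in starts[n_full:]) if sol]
        screened.sort(key=lambda sol: (sol.cost, tuple(sol.x)))
        for sol in screened[:refine_top]:
            ref = run(sol.x, None)
            for cand in (ref, sol):
                if cand is not None and better(cand, best):
                    best = cand
    else:
        for s in starts:
            sol = run(s, None)
            if sol is not None and better(sol, best):
                best = sol
    if best is None:
        raise FitStageError("least-squares", "no multistart converged")
    return best


def _tau_model(gate: str, theta, I, V, cfg: FitConfig):
    if gate == "O":
        ti = model._tauO_I(I, theta[0:3])
        tv = model._tau_V(V, theta[3:6])
        scheme = cfg.combine_O
    else:
        ti = model._tauR_I(I, theta[0:6])
        tv = model._tau_V(V, theta[6:9])
        scheme = cfg.combine_R
    return model._combine(ti, tv, scheme)


def fit_time_constants(targets: pd.DataFrame, config: FitConfig):
    """Fit the parametric tau surfaces to the step-2 target table.

    Residuals are relative (per-target normalized), so millisecond
    activation targets and seconds-scale dark-recovery targets carry equal
    weight.  Returns ``(tauO_I, tauO_V, tauR_I, tauR_V)`` tuples.
    """
    sp = config.space()
    rng = np.random.default_rng(config.seed + 2)
    out = {}
    for gate, blocks in (("O", ("tauO_I", "tauO_V")), ("R", ("tauR_I", "tauR_V"))):
        sub = targets[targets.gate == gate]
        if sub.empty:
            raise FitStageError("tau-fit", f"no targets for gate {gate}")
        I = sub.irradiance_W_m2.to_numpy()
        V = sub.voltage_mV.to_numpy()
        tau_t = sub.tau.to_numpy()
        n_cond = len(sub.drop_duplicates(["irradiance_W_m2", "voltage_mV"]))
        lb = np.concatenate([sp[b][0] for b in blocks]).astype(float)
        ub = np.concatenate([sp[b][1] for b in blocks]).astype(float)
        x0 = np.concatenate([sp[b][2] for b in blocks]).astype(float)
        if n_cond < len(lb):
            warnings.warn(
                f"gate {gate}: {n_cond} conditions for {len(lb)} parameters; "
                "fit proceeds with the search box as regularizer")

        def resid(theta, I=I, V=V, tau_t=tau_t, gate=gate):
            return (_tau_model(gate, theta, I, V, config) - tau_t) / tau_t

        best = _multistart_ls(resid, lb, ub, x0, config.step2_starts, rng, max_nfev=300)
        k = len(sp[blocks[0]][0])
        out[blocks[0]] = tuple(best.x[:k])
        out[blocks[1]] = tuple(best.x[k:])
    return out["tauO_I"], out["tauO_V"], out["tauR_I"], out["tauR_V"]


# --------------------------------------------------------------------------
# step 3: equilibria / rectification under constraints
# --------------------------------------------------------------------------

def _constraint_violations(p: OpsinParams, cfg: FitConfig, I_grid, V_grid) -> np.ndarray:
    """Nonnegative violation magnitudes for every configured constraint.

    Evaluated on the experimental grid plus the constraint threshold
    intensities; G(V) is checked away from the reversal potential (the
    rectification factor is singular there).
    """
    viol = []
    for c in cfg.oinf_constraints:
        v = model.O_inf(c.irradiance, p)
        viol.append(max(0.0, c.bound - v) if c.sense == "ge" else max(0.0, v - c.bound))
    if p.Grect is not None:
        Vg = np.asarray([v for v in V_grid if abs(v - p.E) > 1.0], dtype=float)
        if len(Vg):
            viol.extend(np.maximum(0.0, -model.rectification(Vg, p)))
    Is = np.unique(np.concatenate([np.asarray(I_grid, dtype=float),
                                   [c.irradiance for c in cfg.oinf_constraints]]))
    _, margin = model.check_decay_constraint(p, np.asarray(V_grid, dtype=float), Is)
    viol.append(max(0.0, -margin))
    return np.asarray(viol)


class _OnPhaseKernel:
    """Precomputed on-phase exponentials for fixed time constants.

    With the step-2 taus frozen, ``O(t) R(t) = Oi (Ri A + (1 - Ri) A B)``
    where ``A = 1 - exp(-t/tauO)`` and ``B = exp(-t/tauR)`` are constant
    matrices over (condition, time); each cost evaluation is then two
    vector-scaled additions instead of fresh exponentials.
    """

    def __init__(self, tauO_c, tauR_c, cfg: FitConfig):
        t = np.arange(0.0, cfg.pulse_s + 1e-12, cfg.dt_single)
        A = 1.0 - np.exp(-t[None, :] / np.asarray(tauO_c)[:, None])
        self.A = A
        self.AB = A * np.exp(-t[None, :] / np.asarray(tauR_c)[:, None])

    def current_features(self, theta_eq, I, V, cfg: FitConfig):
        """y_peak, y_ss, y_ratio (magnitudes) per condition."""
        o1, o2 = theta_eq[0:2]
        r1, r2, r3 = theta_eq[2:5]
        x = model._log10I(I)
        Oi = model.expit((x - o1) / o2)
        Ri = 1.0 - r3 * model.expit((x - r1) / r2)
        if cfg.rectified:
            g1, g2, g3 = theta_eq[5:8]
            K = g1 * (1.0 - g2 * np.exp(-V / g3))      # g = 1, E = 0
        else:
            g, E = theta_eq[5:7]
            K = g * (V - E)
        OR = Ri[:, None] * self.A + (1.0 - Ri)[:, None] * self.AB
        cur = np.abs((K * Oi)[:, None] * OR)
        y_peak = cur.max(axis=1)
        y_ss = cur[:, -1]
        return y_peak, y_ss, y_ss / np.maximum(y_peak, 1e-300)


def fit_equilibria(tau_params, features: FeatureSet, config: FitConfig) -> OpsinParams:
    """Step 3: fit O_inf, R_inf and G(V) (or g, E) to the current features.

    Multistart bounded least squares on the weighted current-feature
    residuals with the step-2 time constants frozen; constraints are folded
    in as exact penalties and the returned point must be feasible to
    ``constraint_tol``.
    """
    tauO_I_p, tauO_V_p, tauR_I_p, tauR_V_p = tau_params
    conds = [
        (I, V) for (I, V) in features.conditions("I_peak")
        if features.has(I, V, "I_ss") and features.has(I, V, "I_ratio")
    ]
    if not conds:
        raise FitStageError("equilibria", "no current-feature conditions")
    I = np.asarray([c[0] for c in conds])
    V = np.asarray([c[1] for c in conds])
    t_peak = np.asarray([features.get(i, v, "I_peak") for i, v in conds])
    t_ss = np.asarray([features.get(i, v, "I_ss") for i, v in conds])
    t_ratio = np.asarray([features.get(i, v, "I_ratio") for i, v in conds])
    w = config.weights
    scale = np.sqrt(len(conds))
    pen_scale = 1e4 * max(w["I_peak"] * t_peak.max(), 1.0)

    tauO_c = model._combine(model._tauO_I(I, tauO_I_p), model._tau_V(V, tauO_V_p), config.combine_O)
    tauR_c = model._combine(model._tauR_I(I, tauR_I_p), model._tau_V(V, tauR_V_p), config.combine_R)
    kernel = _OnPhaseKernel(tauO_c, tauR_c, config)

    sp = config.space()
    blocks = ("Oinf", "Rinf") + (("Grect",) if config.rectified else ("g", "E"))
    lb = np.concatenate([sp[b][0] for b in blocks]).astype(float)
    ub = np.concatenate([sp[b][1] for b in blocks]).astype(float)
    x0 = np.concatenate([sp[b][2] for b in blocks]).astype(float)

    def to_params(theta):
        full = np.concatenate([tauO_I_p, tauO_V_p, tauR_I_p, tauR_V_p, theta])
        return config.params_of(full)

    I_grid = np.unique(I[I > 0])
    V_grid = np.unique(V)

    def resid(theta):
        y_peak, y_ss, y_ratio = kernel.current_features(theta, I, V, config)
        r = np.concatenate([
            w["I_peak"] * (y_peak - t_peak),
            w["I_ss"] * (y_ss - t_ss),
            w["I_ratio"] * (y_ratio - t_ratio),
        ]) / scale
        viol = _constraint_violations(to_params(theta), config, I_grid, V_grid)
        return np.concatenate([r, pen_scale * viol])

    # Deterministic coarse-grid starts over the directions that shape the
    # basin structure most: the logistic midpoints (centered on the data's
    # log-irradiance range), the desensitization depth, the current scale,
    # and -- critically -- a rectification shape that satisfies G >= 0 on
    # the grid, so no start is born inside a penalty wall.
    x_mid = float(np.log10(I[I > 0]).mean())
    starts = []
    if config.rectified:
        scale0 = max(t_peak.max() / 4.0, 1.0)  # |1 - p2 e^{-V/p3}| = O(few) at -80 mV
        shapes = [(1.2, 45.0), (2.0, 100.0)]
        for depth in (0.5, 0.75, 0.95):
            for sc in (1.0, 2.0):
                for g2, g3 in shapes:
                    starts.append(np.array(
                        [x_mid, 1.0, x_mid, 1.0, depth,
                         np.clip(sc * scale0, lb[5], ub[5]), g2, g3]))
    else:
        scale0 = max(t_peak.max() / max(np.abs(V).max(), 1.0), _EPS)
        for depth in (0.5, 0.75, 0.95):
            for sc in (0.5, 1.0, 2.0):
                starts.append(np.array(
                    [x_mid, 1.0, x_mid, 1.0, depth,
                     np.clip(sc * scale0, lb[5], ub[5]), 0.0]))
    n_full = len(starts)
    starts.append(x0)

    rng = np.random.default_rng(config.seed + 3)
    best = _multistart_ls(resid, lb, ub, np.asarray(starts), config.step3_starts, rng,
                          n_full=n_full,
                          refine_top=max(10, config.step3_starts // 40),
                          max_nfev=800)
    p = to_params(best.x)
    viol = _constraint_violations(p, config, I_grid, V_grid)
    if viol.max(initial=0.0) > config.constraint_tol:
        raise ConstraintInfeasibleError(
            "equilibria",
            f"no feasible optimum; worst constraint violation {viol.max():.3g}")
    return p.with_(name="intermediate")


# --------------------------------------------------------------------------
# step 4: global refinement (PSO + polish) over the reduced box
# --------------------------------------------------------------------------

def model_features(
    params: OpsinParams,
    target: FeatureSet,
    config: FitConfig,
    extract_cfg: ExtractConfig | None = None,
) -> FeatureSet:
    """Extract the model's features with the same operations used on data.

    Single-pulse traces are simulated in closed form at ``dt_single`` and
    passed through :func:`extract_features`; recovery conditions are probed
    with the two-pulse ratio curve at ``dt_two_pulse`` and interpolated by
    :func:`recovery_time`.  Features the model cannot produce at a condition
    (degenerate trace, recovery outside the interval grid) are omitted.
    """
    ec = extract_cfg or ExtractConfig(n_starts=config.feature_starts, seed=config.seed)
    out = FeatureSet()
    t_end = config.t_on + config.pulse_s + config.post_s
    t = np.arange(0.0, t_end + 1e-12, config.dt_single)
    for I, V in target.conditions("I_peak"):
        prot = ClampProtocol(V=V, I=I, t_on=config.t_on,
                             t_off=config.t_on + config.pulse_s, t_end=t_end)
        try:
            f = extract_features(model.current_closed_form(t, prot, params), prot, ec)
        except DegenerateTraceError:
            continue
        for name, val in f.items():
            if val is not None:
                out.add(I, V, name, val)
    gaps = np.asarray(config.intervals)
    for I, V in target.conditions("tau_recov"):
        ratios = model.two_pulse_ratio_curve(
            params, I, V, gaps, config.pulse_s, config.pulse_s, config.dt_two_pulse)
        try:
            out.add(I, V, "tau_recov", recovery_time(gaps, ratios))
        except (RecoveryRangeError, ValueError):
            continue
    return out


def _feature_cost(mf: FeatureSet, target: FeatureSet, weights) -> tuple[float, pd.DataFrame]:
    """Extended weighted RMS cost: squared errors summed across features per
    condition, averaged over conditions, rooted.  A target feature missing
    from the model contributes ten target-magnitudes of error."""
    lut = {(r.irradiance_W_m2, r.voltage_mV, r.feature): r.value
           for r in mf.df.itertuples()}
    rows = []
    for r in target.df.itertuples():
        I, V, feat, tv = r.irradiance_W_m2, r.voltage_mV, r.feature, r.value
        wx = weights.get(feat, 1.0)
        yv = lut.get((I, V, feat), np.nan)
        err = (yv - tv) if np.isfinite(yv) else 10.0 * abs(tv)
        rows.append((I, V, feat, yv, tv, wx * err))
    df = pd.DataFrame(rows, columns=["irradiance_W_m2", "voltage_mV", "feature", "y", "t", "werr"])
    per_cond = df.assign(sq=df.werr**2).groupby(["irradiance_W_m2", "voltage_mV"]).sq.sum()
    return float(np.sqrt(per_cond.mean())), df


def global_refine_pso(
    intermediate: OpsinParams,
    features: FeatureSet,
    config: FitConfig,
) -> tuple[OpsinParams, dict]:
    """Step 4: bounded global-best PSO inside the reduced box, plus polish.

    The swarm includes the intermediate point, so the result is never worse
    than it on the step-4 cost.  Velocity updates use the standard
    constriction-style coefficients; particles reflect at the box walls.
    Stops on the wall-clock budget (sets ``budget_exhausted``) or when the
    iteration cap is reached.
    """
    lb0, ub0 = config.full_bounds()
    center = config.vector_of(intermediate)
    if np.any(center < lb0 - 1e-9) or np.any(center > ub0 + 1e-9):
        raise FitStageError("pso", "intermediate parameters outside the search box")
    half = 0.5 * config.reduced_fraction * (ub0 - lb0)
    lb = np.maximum(lb0, center - half)
    ub = np.minimum(ub0, center + half)

    I_grid = np.unique([c[0] for c in features.conditions() if c[0] > 0])
    V_grid = np.unique([c[1] for c in features.conditions()])
    pen_scale = 1e4 * max(
        config.weights["I_peak"]
        * features.df[features.df.feature == "I_peak"].value.max(),
        1.0,
    )

    def cost(theta) -> float:
        try:
            p = config.params_of(theta)
        except ValueError:
            return np.inf
        viol = _constraint_violations(p, config, I_grid, V_grid)
        c, _ = _feature_cost(model_features(p, features, config), features, config.weights)
        return c + pen_scale * float(viol.sum())

    rng = np.random.default_rng(config.seed + 4)
    n, dim = config.pso_particles, len(lb)
    X = lb + (ub - lb) * rng.random((n, dim))
    X[0] = center
    Vel = 0.1 * (ub - lb) * (2 * rng.random((n, dim)) - 1)

    t_start = time.monotonic()
    fvals = np.array([cost(x) for x in X])
    pbest, pcost = X.copy(), fvals.copy()
    g = int(np.argmin(pcost))
    gbest, gcost = pbest[g].copy(), float(pcost[g])
    trace = [gcost]
    exhausted = False

    for it in range(config.pso_max_iters):
        if time.monotonic() - t_start > config.pso_budget_s:
            exhausted = True
            break
        r1 = rng.random((n, dim))
        r2 = rng.random((n, dim))
        Vel = (config.pso_inertia * Vel
               + config.pso_cognitive * r1 * (pbest - X)
               + config.pso_social * r2 * (gbest[None, :] - X))
        X = X + Vel
        low, high = X < lb, X > ub
        X = np.where(low, 2 * lb - X, X)
        X = np.where(high, 2 * ub - X, X)
        X = np.clip(X, lb, ub)   # guard against double reflection overshoot
        Vel = np.where(low | high, -Vel, Vel)
        for i in range(n):
            f = cost(X[i])
            if f < pcost[i]:
                pcost[i], pbest[i] = f, X[i].copy()
                if f < gcost:
                    gcost, gbest = float(f), X[i].copy()
        trace.append(gcost)

    if config.polish:
        gbest, gcost, trace = _polish(gbest, gcost, trace, features, config, lb, ub, pen_scale)

    final = config.params_of(gbest, name="final")
    info = dict(cost=gcost, cost_trace=trace, budget_exhausted=exhausted,
                box=(lb, ub))
    return final, info


def _polish(gbest, gcost, trace, features, config, lb, ub, pen_scale):
    """Bounded local least-squares refinement of the swarm's best point.

    Residuals are normalized per target (fractional feature errors), which
    applies the cost's "level all features" principle condition-by-
    condition: a 5% activation-time error counts as much as a 5% peak
    error.  The polished point is kept only when it improves the step-4
    cost and stays feasible, so the swarm contract is preserved.
    """
    tI = features.df.irradiance_W_m2.to_numpy()
    tV = features.df.voltage_mV.to_numpy()
    tF = features.df.feature.to_numpy()
    tval = features.df.value.to_numpy()

    def resid(theta):
        p = config.params_of(theta)
        mf = model_features(p, features, config)
        lut = {(r.irradiance_W_m2, r.voltage_mV, r.feature): r.value
               for r in mf.df.itertuples()}
        rel = np.empty(len(tval))
        for k in range(len(tval)):
            y = lut.get((tI[k], tV[k], tF[k]), np.nan)
            rel[k] = (y - tval[k]) / tval[k] if np.isfinite(y) else 10.0
        viol = _constraint_violations(
            p, config, np.unique(tI[tI > 0]), np.unique(tV))
        return np.concatenate([rel, 1e4 * viol])

    try:
        lb0, ub0 = config.full_bounds()
        sol = least_squares(resid, gbest, bounds=(lb, ub), method="trf",
                            diff_step=1e-3, x_scale=np.minimum(ub0 - lb0, 100.0),
                            xtol=1e-8, ftol=1e-8,
                            max_nfev=config.polish_max_nfev)
        p = config.params_of(sol.x)
        c, _ = _feature_cost(model_features(p, features, config), features, config.weights)
        I_grid = np.unique([c0 for c0, _ in features.conditions() if c0 > 0])
        V_grid = np.unique([v for _, v in features.conditions()])
        viol = _constraint_violations(p, config, I_grid, V_grid)
        total = c + pen_scale * float(viol.sum())
        if total < gcost and viol.max(initial=0.0) <= config.constraint_tol:
            trace = trace + [total]
            return sol.x, total, trace
    except Exception as exc:      # polish is best-effort; keep the swarm result
        warnings.warn(f"polish step failed: {exc}")
    return gbest, gcost, trace


# --------------------------------------------------------------------------
# the full pipeline
# --------------------------------------------------------------------------

def fit_pipeline(
    traces: Mapping[tuple[float, float], model.PhotocurrentTrace] | None = None,
    two_pulse: Mapping[tuple[float, float], tuple] | None = None,
    features: FeatureSet | None = None,
    config: FitConfig | None = None,
) -> OpsinFit:
    """Run the four-step procedure from traces or precomputed features.

    Provide either ``features`` (step 1 skipped) or ``traces`` (+ optional
    ``two_pulse`` series ``{(I, V): (intervals, peak_ratios)}``).  Errors
    are re-raised labeled with the failing stage.
    """
    config = config or FitConfig()
    if features is None:
        if not traces:
            raise FitStageError("extract", "no traces and no features supplied")
        features = FeatureSet()
        ec = ExtractConfig(n_starts=config.step1_starts, seed=config.seed)
        for (I, V), tr in traces.items():
            try:
                f = extract_features(tr, tr.protocol, ec)
            except DegenerateTraceError as exc:
                warnings.warn(f"condition (I={I:g}, V={V:g}) skipped: {exc}")
                continue
            for name, val in f.items():
                if val is not None:
                    features.add(I, V, name, val)
        for (I, V), (ivals, ratios) in (two_pulse or {}).items():
            try:
                features.add(I, V, "tau_recov", recovery_time(ivals, ratios))
            except (RecoveryRangeError, ValueError) as exc:
                warnings.warn(f"recovery at (I={I:g}, V={V:g}) skipped: {exc}")
    if len(features) == 0:
        raise FitStageError("extract", "empty feature set")

    try:
        targets = approximate_time_constant_targets(features)
        tau_params = fit_time_constants(targets, config)
    except FitStageError:
        raise
    except Exception as exc:
        raise FitStageError("tau-fit", str(exc)) from exc

    intermediate = fit_equilibria(tau_params, features, config)
    cost_intermediate, _ = _feature_cost(
        model_features(intermediate, features, config), features, config.weights)

    final, info = global_refine_pso(intermediate, features, config)
    cost_final, resid = _feature_cost(
        model_features(final, features, config), features, config.weights)
    if cost_final > cost_intermediate:
        # contract: never return a point worse than the intermediate one
        final, cost_final = intermediate.with_(name="final"), cost_intermediate

    I_grid = np.unique([c[0] for c in features.conditions() if c[0] > 0])
    V_grid = np.unique([c[1] for c in features.conditions()])
    _, margin = model.check_decay_constraint(final, V_grid, I_grid)
    return OpsinFit(
        intermediate=intermediate,
        final=final,
        cost_intermediate=cost_intermediate,
        cost_final=cost_final,
        cost_trace=info["cost_trace"],
        constraint_margin=margin,
        residuals=resid,
        budget_exhausted=info["budget_exhausted"],
    )
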