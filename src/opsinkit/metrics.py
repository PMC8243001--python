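"""Goodness-of-fit metrics for feature tables.

Four root-mean-square error flavors differ only in their per-feature
weights: RMSE (w = 1), RMSNE (w = 1/target), RMSWE (configured training
weights) and RMSZE (w = 1/sigma of the target feature).  Each is reported
per feature and for grouped scopes -- ``all`` (every feature), ``tau_all``
(the four time constants) and ``I_all`` (the three current features) --
where squared errors are summed across the group's features per stimulation
condition before the mean over conditions and the root are taken.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureSet

__all__ = ["MetricTable", "goodness_of_fit", "TAU_FEATURES", "CURRENT_FEATURES"]

TAU_FEATURES = ("tau_on", "tau_inact", "tau_off", "tau_recov")
CURRENT_FEATURES = ("I_peak", "I_ss", "I_ratio")

METRICS = ("RMSE", "RMSNE", "RMSWE", "RMSZE")


class MetricTable:
    """Metric x scope table; ``NaN`` marks undefined entries.

    RMSZE is undefined wherever the target table carries no standard
    deviation (e.g. the recovery time constant in typical datasets).
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df

    def value(self, metric: str, scope: str) -> float:
        sel = self.df[(self.df.metric == metric) & (self.df.scope == scope)]
        if len(sel) == 0:
            raise KeyError(f"no entry for ({metric}, {scope})")
        return float(sel.value.iloc[0])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __repr__(self) -> str:
        return "MetricTable:\n" + self.df.pivot(index="scope", columns="metric", values="value").to_string()


def _collect(model: FeatureSet, target: FeatureSet):
    """Join model and target tables on (I, V, feature)."""
    m = model.df.rename(columns={"value": "y"})[["irradiance_W_m2", "voltage_mV", "feature", "y"]]
    t = target.df.rename(columns={"value": "t", "sigma": "sig"})
    joined = pd.merge(
        t, m, on=["irradiance_W_m2", "voltage_mV", "feature"], how="inner"
    )
    if joined.empty:
        raise ValueError("model and target feature sets share no conditions")
    return joined


def goodness_of_fit(
    model_features: FeatureSet,
    target_features: FeatureSet,
    weights: Mapping[str, float] | None = None,
) -> MetricTable:
    """Score model features against targets on their shared conditions.

    ``weights`` maps feature name -> training weight for RMSWE (missing
    features default to 1).  Sigmas for RMSZE come from the target table.
    Conditions with a zero target (RMSNE) or zero/missing sigma (RMSZE) are
    excluded from that metric with a warning.
    """
    weights = dict(weights or {})
    j = _collect(model_features, target_features)
    j["err"] = j.y - j.t

    rows = []

    def w_of(metric, sub):
        if metric == "RMSE":
            return np.ones(len(sub))
        if metric == "RMSNE":
            return 1.0 / sub.t.to_numpy()
        if metric == "RMSWE":
            return np.array([weights.get(f, 1.0) for f in sub.feature])
        return 1.0 / sub.sig.to_numpy()

    def valid(metric, sub):
        if metric == "RMSNE":
            bad = sub.t == 0
            if bad.any():
                warnings.warn(f"RMSNE: excluded {int(bad.sum())} zero-target conditions")
            return sub[~bad]
        if metric == "RMSZE":
            bad = ~np.isfinite(sub.sig) | (sub.sig <= 0)
            if bad.any() and not bad.all():
                warnings.warn(f"RMSZE: excluded {int(bad.sum())} conditions without sigma")
            return sub[~bad]
        return sub

    scopes: dict[str, tuple[str, ...]] = {f: (f,) for f in FEATURE_NAMES}
    scopes["all"] = FEATURE_NAMES
    scopes["tau_all"] = TAU_FEATURES
    scopes["I_all"] = CURRENT_FEATURES

    for metric in METRICS:
        for scope, members in scopes.items():
            sub = valid(metric, j[j.feature.isin(members)])
            if sub.empty:
                rows.append((metric, scope, np.nan, 0))
                continue
            w = w_of(metric, sub)
            sq = (w * sub.err.to_numpy()) ** 2
            # grouped scopes: sum across features first, then mean over conditions
            g = pd.DataFrame({
                "I": sub.irradiance_W_m2.to_numpy(),
                "V": sub.voltage_mV.to_numpy(),
                "sq": sq,
            }).groupby(["I", "V"]).sq.sum()
            rows.append((metric, scope, float(np.sqrt(g.mean())), len(g)))

    return MetricTable(pd.DataFrame(rows, columns=["metric", "scope", "value", "n_conditions"]))
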