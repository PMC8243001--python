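"""Readers and writers for traces, features and fit configurations.

A photocurrent trace is a two-column CSV (``time_s,current``) with a JSON
sidecar (same stem, ``.json``) carrying the stimulus metadata; parameter
sets are JSON (see :mod:`opsinkit.params`); feature tables are long-form
CSV (see :class:`opsinkit.features.FeatureSet`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureSet
from .fitting import FitConfig, OinfConstraint
from .model import PhotocurrentTrace
from .protocols import ClampProtocol

__all__ = ["save_trace", "load_trace", "sidecar_path", "load_fit_config"]


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def save_trace(trace: PhotocurrentTrace, csv_path) -> None:
    """Write ``time_s,current`` CSV plus the stimulus sidecar JSON."""
    pd.DataFrame({"time_s": trace.t, "current": trace.current}).to_csv(
        csv_path, index=False)
    meta = {
        "irradiance_W_m2": trace.protocol.I,
        "voltage_mV": trace.protocol.V,
        "t_on_s": trace.protocol.t_on,
        "t_off_s": trace.protocol.t_off,
        "t_end_s": trace.protocol.t_end,
        "conductance_units": trace.conductance_mode,
    }
    with open(sidecar_path(csv_path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_trace(csv_path) -> PhotocurrentTrace:
    df = pd.read_csv(csv_path)
    if not {"time_s", "current"} <= set(df.columns):
        raise ValueError(f"{csv_path}: expected columns time_s,current")
    side = sidecar_path(csv_path)
    if not side.exists():
        raise FileNotFoundError(f"missing stimulus sidecar {side}")
    with open(side) as fh:
        meta = json.load(fh)
    prot = ClampProtocol(
        V=meta["voltage_mV"], I=meta["irradiance_W_m2"],
        t_on=meta["t_on_s"], t_off=meta["t_off_s"],
        t_end=meta.get("t_end_s", float(df.time_s.iloc[-1])),
    )
    return PhotocurrentTrace(
        t=df.time_s.to_numpy(), current=df.current.to_numpy(),
        protocol=prot, conductance_mode=meta.get("conductance_units", "density"),
    )


def load_fit_config(path, **overrides) -> FitConfig:
    """Build a :class:`FitConfig` from a YAML/JSON mapping.

    Recognized keys are the FitConfig fields; ``oinf_constraints`` entries
    are mappings with ``irradiance``, ``bound`` and optional ``sense``.
    ``mode: test`` applies the desk-scale budget preset before overrides.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping")
    mode = raw.pop("mode", "published")
    cons = raw.pop("oinf_constraints", None)
    if cons is not None:
        raw["oinf_constraints"] = tuple(
            OinfConstraint(c["irradiance"], c["bound"], c.get("sense", "ge"))
            for c in cons
        )
    if "intervals" in raw:
        raw["intervals"] = tuple(float(x) for x in raw["intervals"])
    raw.update(overrides)
    factory = FitConfig.test if mode == "test" else FitConfig.published
    return factory(**raw)
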