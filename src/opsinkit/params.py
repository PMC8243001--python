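"""Opsin parameter container, validation, (de)serialization and bundled fixtures.

The model describes an opsin photocurrent with two independent two-state
gating pairs: an open/closed pair ``O`` and a dark/light-adaptation
conductance pair ``R``.  Every rate function is parameterized by a small
vector ``p`` whose meaning is documented on :class:`OpsinParams`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from importlib import resources
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "OpsinParams",
    "GatingState",
    "load_params",
    "save_params",
    "fixture",
    "fixture_names",
    "normalize_conductance",
]

CombineScheme = Literal["product", "reciprocal_sum"]

_FIXTURE_NAMES = (
    "rsrs_intermediate",
    "rsrs_final",
    "pp_intermediate",
    "pp_final",
    "mm_intermediate",
    "mm_final",
)

_ALLOWED_KEYS = {
    "schema_version", "name", "conductance_mode", "g", "E",
    "tauO_I", "tauO_V", "tauR_I", "tauR_V",
    "Oinf", "Rinf", "Grect", "combine_O", "combine_R",
}


@dataclass(frozen=True)
class GatingState:
    """Instantaneous gating state.

    ``O`` is the open fraction and ``R`` the dark-adaptation conductance
    factor; both live in [0, 1].  The fully dark-adapted resting state is
    ``O=0, R=1``.
    """

    O: float = 0.0
    R: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.O <= 1.0 and 0.0 <= self.R <= 1.0):
            raise ValueError(f"gating state outside [0,1]: O={self.O}, R={self.R}")


@dataclass(frozen=True)
class OpsinParams:
    """All parameters of the double two-state opsin model.

    Parameters
    ----------
    g : float
        Maximal dark-adapted conductance.  mS/cm^2 when
        ``conductance_mode == "density"`` (opsin expressed in a membrane
        patch), uS when ``"absolute"`` (whole-cell recordings).
    E : float
        Reversal potential in mV.
    tauO_I : (p1, p2, p3)
        Intensity dependence of the open-state time constant: a logistic in
        log10 irradiance, ``p3 / (1 + exp((p1 + log10 I) / p2))`` with dark
        limit ``p3`` seconds.
    tauO_V : (p1, p2, p3)
        Voltage dependence, ``p1 / (1 + exp(-(V - p2) / p3))`` with ``p1``
        in seconds, ``p2`` the mV midpoint and ``p3`` the mV slope.
    tauR_I : (p1, p2, p3, p4, p5, p6)
        Intensity dependence of the adaptation time constant: dark limit
        ``p1`` seconds shaped by a biphasic logistic decay, weight
        ``p2 in [0,1]`` between two (log10-midpoint, slope) pairs
        (p3, p4) and (p5, p6).
    tauR_V : (p1, p2, p3)
        As ``tauO_V``.
    Oinf : (p1, p2)
        Open-state steady state, a rising logistic of log10 irradiance with
        midpoint ``10**p1`` W/m^2 and log-slope ``p2``.
    Rinf : (p1, p2, p3)
        Adaptation steady state, ``1 - p3 * logistic``; ``p3 in [0,1]`` is
        the desensitization depth.
    Grect : (p1, p2, p3) or None
        Rectification of the open-channel current:
        ``G(V) = p1 (1 - p2 exp(-(V-E)/p3)) / (V - E)``.  ``None`` means no
        rectification (G == 1), as for the MerMAID sets.
    combine_O, combine_R : {"product", "reciprocal_sum"}
        How the intensity and voltage parts of each time constant combine.
    """

    g: float
    E: float
    tauO_I: tuple[float, float, float]
    tauO_V: tuple[float, float, float]
    tauR_I: tuple[float, float, float, float, float, float]
    tauR_V: tuple[float, float, float]
    Oinf: tuple[float, float]
    Rinf: tuple[float, float, float]
    Grect: tuple[float, float, float] | None = None
    combine_O: CombineScheme = "reciprocal_sum"
    combine_R: CombineScheme = "reciprocal_sum"
    conductance_mode: Literal["density", "absolute"] = "density"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "tauO_I", tuple(float(x) for x in self.tauO_I))
        object.__setattr__(self, "tauO_V", tuple(float(x) for x in self.tauO_V))
        object.__setattr__(self, "tauR_I", tuple(float(x) for x in self.tauR_I))
        object.__setattr__(self, "tauR_V", tuple(float(x) for x in self.tauR_V))
        object.__setattr__(self, "Oinf", tuple(float(x) for x in self.Oinf))
        object.__setattr__(self, "Rinf", tuple(float(x) for x in self.Rinf))
        if self.Grect is not None:
            object.__setattr__(self, "Grect", tuple(float(x) for x in self.Grect))
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        errs = []
        if not np.isfinite(self.g) or self.g <= 0:
            errs.append(f"g must be finite and > 0, got {self.g}")
        if len(self.tauO_I) != 3 or len(self.tauO_V) != 3:
            errs.append("tauO_I and tauO_V need 3 parameters each")
        if len(self.tauR_I) != 6 or len(self.tauR_V) != 3:
            errs.append("tauR_I needs 6 and tauR_V needs 3 parameters")
        if len(self.Oinf) != 2 or len(self.Rinf) != 3:
            errs.append("Oinf needs 2 and Rinf needs 3 parameters")
        if self.tauO_I[2] <= 0:
            errs.append(f"tauO_I p3 (dark limit, s) must be > 0, got {self.tauO_I[2]}")
        if self.tauR_I[0] <= 0:
            errs.append(f"tauR_I p1 (dark limit, s) must be > 0, got {self.tauR_I[0]}")
        if not 0.0 <= self.tauR_I[1] <= 1.0:
            errs.append(f"tauR_I p2 (weight) must be in [0,1], got {self.tauR_I[1]}")
        if not 0.0 <= self.Rinf[2] <= 1.0:
            errs.append(f"Rinf p3 (depth) must be in [0,1], got {self.Rinf[2]}")
        for blk, idx in (("tauO_I", 1), ("tauR_I", 3), ("tauR_I", 5), ("Oinf", 1), ("Rinf", 1)):
            if getattr(self, blk)[idx] <= 0:
                errs.append(f"{blk} slope p{idx + 1} must be > 0")
        if self.Grect is not None and self.Grect[2] == 0:
            errs.append("Grect p3 (mV decay constant) must be nonzero")
        for scheme in (self.combine_O, self.combine_R):
            if scheme not in ("product", "reciprocal_sum"):
                errs.append(f"unknown combination scheme {scheme!r}")
        if self.conductance_mode not in ("density", "absolute"):
            errs.append(f"unknown conductance mode {self.conductance_mode!r}")
        if errs:
            raise ValueError("invalid opsin parameters: " + "; ".join(errs))

    def with_(self, **kwargs) -> "OpsinParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = "1.0"
        return d


def _as_params(d: dict, source: str = "<dict>") -> OpsinParams:
    unknown = set(d) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"{source}: unknown keys {sorted(unknown)}")
    missing = {"g", "E", "tauO_I", "tauO_V", "tauR_I", "tauR_V", "Oinf", "Rinf"} - set(d)
    if missing:
        raise ValueError(f"{source}: missing keys {sorted(missing)}")
    try:
        return OpsinParams(
            g=float(d["g"]),
            E=float(d["E"]),
            tauO_I=d["tauO_I"],
            tauO_V=d["tauO_V"],
            tauR_I=d["tauR_I"],
            tauR_V=d["tauR_V"],
            Oinf=d["Oinf"],
            Rinf=d["Rinf"],
            Grect=d.get("Grect"),
            combine_O=d.get("combine_O", "reciprocal_sum"),
            combine_R=d.get("combine_R", "reciprocal_sum"),
            conductance_mode=d.get("conductance_mode", "density"),
            name=d.get("name", ""),
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{source}: {exc}") from exc


def load_params(path) -> OpsinParams:
    """Load an :class:`OpsinParams` JSON file, rejecting unknown keys."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    return _as_params(d, source=str(path))


def save_params(params: OpsinParams, path) -> None:
    """Write canonicalized JSON (sorted keys, 2-space indent)."""
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def fixture_names() -> tuple[str, ...]:
    return _FIXTURE_NAMES


def fixture(name: str) -> OpsinParams:
    """Return one of the bundled published parameter sets.

    Names: ``rsrs_intermediate``, ``rsrs_final`` (reciprocal-sum
    combination, ChR2(H134R)), ``pp_intermediate``, ``pp_final`` (product
    combination, ChR2(H134R)), ``mm_intermediate``, ``mm_final`` (MerMAID,
    no rectification, absolute conductance).
    """
    key = name.lower().replace("-", "_").replace("intm", "intermediate")
    if key not in _FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; known: {_FIXTURE_NAMES}")
    text = resources.files("opsinkit.fixtures").joinpath(key + ".json").read_text()
    return _as_params(json.loads(text), source=f"fixture:{key}")


def normalize_conductance(params: OpsinParams, g: float = 1.0) -> OpsinParams:
    """Move scale between ``g`` and the rectification gain ``Grect.p1``.

    The photocurrent depends on the product ``g * Grect.p1`` only, so the
    published tables quote interchangeable pairs like "9.91 (1)" / "1
    (9.91)".  Returns an equivalent parameter set with the requested ``g``.
    """
    if params.Grect is None:
        raise ValueError("normalize_conductance requires a rectification block")
    if g <= 0:
        raise ValueError("g must be > 0")
    scale = params.g / g
    p1, p2, p3 = params.Grect
    return params.with_(g=g, Grect=(p1 * scale, p2, p3))
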