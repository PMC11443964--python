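"""Model definitions for single-compartment conductance-based neurons.

A model is a list of Hodgkin-Huxley-type channels, each with a gating law

    g_ion(V, t) = gbar_ion * m^a * h^b,

steady-state activation/inactivation curves and voltage-dependent time
constants.  Kinetics are shipped as structured YAML files (one per model)
built from a small catalogue of rate-function forms, so the simulation and
sensitivity engines stay model-agnostic.

Units: mV, ms, mS/cm^2, uA/cm^2, uF/cm^2; intracellular calcium in uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "RateFunction",
    "ChannelSpec",
    "CalciumDynamics",
    "ModelSpec",
    "ConductanceVector",
    "build_model",
    "load_model_file",
]


# ---------------------------------------------------------------------------
# Rate-function catalogue
# ---------------------------------------------------------------------------
# Each form maps a voltage (and, for calcium-gated channels, the intracellular
# calcium concentration) to either a steady-state gate value in [0, 1] or a
# time constant in ms.  Integer ids are shared with the compiled engine.

_MAX_PARAMS = 8


def _const(V, Ca, p):
    return np.full_like(np.asarray(V, dtype=float), p[0])


def _boltz(V, Ca, p):
    # 1 / (1 + exp((V - Vh) / k)); k < 0 -> activation, k > 0 -> inactivation
    return 1.0 / (1.0 + np.exp((V - p[0]) / p[1]))


def _sigtau(V, Ca, p):
    return p[0] + p[1] / (1.0 + np.exp((V - p[2]) / p[3]))


def _biexptau(V, Ca, p):
    return p[0] + p[1] / (np.exp((V - p[2]) / p[3]) + np.exp((V - p[4]) / p[5]))


def _prodsig(V, Ca, p):
    return (p[0] / (1.0 + np.exp((V - p[1]) / p[2]))) * (
        p[3] + p[4] / (1.0 + np.exp((V - p[5]) / p[6]))
    )


def _caboltz(V, Ca, p):
    # calcium-controlled activation: (Ca/(Ca+K)) * Boltzmann(V)
    return (Ca / (Ca + p[0])) / (1.0 + np.exp((V - p[1]) / p[2]))


def _mgblock(V, Ca, p):
    # instantaneous magnesium block of NMDA-type channels
    return 1.0 / (1.0 + p[0] * np.exp(p[1] * V))


FORMS: dict[str, tuple[int, int, Callable]] = {
    "const": (0, 1, _const),
    "boltz": (1, 2, _boltz),
    "sigtau": (2, 4, _sigtau),
    "biexptau": (3, 6, _biexptau),
    "prodsig": (4, 7, _prodsig),
    "caboltz": (5, 3, _caboltz),
    "mgblock": (6, 2, _mgblock),
}

_CA_FORMS = {"caboltz"}


@dataclass(frozen=True)
class RateFunction:
    """One gating curve: a named parametric form plus its parameters."""

    form: str
    p: tuple[float, ...]

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown rate-function form {self.form!r}")
        _, nparams, _ = FORMS[self.form]
        if len(self.p) != nparams:
            raise ValueError(
                f"form {self.form!r} takes {nparams} parameters, got {len(self.p)}"
            )

    @property
    def form_id(self) -> int:
        return FORMS[self.form][0]

    @property
    def uses_calcium(self) -> bool:
        return self.form in _CA_FORMS

    def __call__(self, V, Ca=None):
        if self.uses_calcium and Ca is None:
            raise ValueError(f"form {self.form!r} requires a calcium value")
        V = np.asarray(V, dtype=float)
        out = FORMS[self.form][2](V, Ca, self.p)
        return out

    def packed(self) -> np.ndarray:
        out = np.zeros(_MAX_PARAMS)
        out[: len(self.p)] = self.p
        return out


CALCIUM_REVERSAL = "calcium"


@dataclass(frozen=True)
class ChannelSpec:
    """One voltage- (and possibly calcium-) gated ion channel."""

    name: str
    a: int
    b: int
    m_inf: RateFunction
    tau_m: RateFunction
    reversal: float | str  # mV, or "calcium" for a Nernst-style reversal
    h_inf: RateFunction | None = None
    tau_h: RateFunction | None = None
    calcium_source: bool = False  # current feeds the intracellular Ca pool
    depends_on_calcium: bool = False  # gating reads intracellular Ca

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("gating exponents must be non-negative")
        if self.b > 0 and (self.h_inf is None or self.tau_h is None):
            raise ValueError(f"channel {self.name}: b > 0 requires h kinetics")
        if self.b == 0 and self.h_inf is not None:
            raise ValueError(f"channel {self.name}: b = 0 forbids h kinetics")

    @property
    def has_h(self) -> bool:
        return self.b > 0

    @property
    def has_calcium_reversal(self) -> bool:
        return self.reversal == CALCIUM_REVERSAL


@dataclass(frozen=True)
class CalciumDynamics:
    """First-order intracellular calcium pool driven by calcium currents.

    tau_ca * dCa/dt = -f * sum(I_Ca) - Ca + ca_rest, with the calcium
    reversal computed from a Nernst-style law E_Ca = nernst_mV * ln(ca_out/Ca).
    """

    tau: float = 20.0  # ms
    f: float = 0.94  # uM per (uA/cm^2)
    ca_rest: float = 0.05  # uM
    ca_out: float = 3000.0  # uM
    nernst_mV: float = 12.199  # RT/2F at ~10 degC, in mV


@dataclass(frozen=True)
class ModelSpec:
    """Full kinetic description of one neuron model.

    ``channels`` is the fixed, ordered list of analysis channels; the
    conductance space of the model is these channels plus leak, in that
    order (leak last).  ``baseline_channels`` are simulated at a fixed
    conductance but excluded from the analysis dimension.
    """

    name: str
    channels: tuple[ChannelSpec, ...]
    C: float  # uF/cm^2
    E_leak: float  # mV
    calcium: CalciumDynamics | None = None
    baseline_channels: tuple[tuple[ChannelSpec, float], ...] = ()

    def __post_init__(self):
        names = [c.name for c in self.all_channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")
        if any(c.depends_on_calcium or c.has_calcium_reversal for c in self.all_channels):
            if self.calcium is None:
                raise ValueError(f"model {self.name}: calcium dynamics required")

    @property
    def all_channels(self) -> tuple[ChannelSpec, ...]:
        return self.channels + tuple(c for c, _ in self.baseline_channels)

    @property
    def channel_names(self) -> list[str]:
        """Analysis conductance names, leak last (the model's channel order)."""
        return [c.name for c in self.channels] + ["leak"]

    @property
    def N(self) -> int:
        """Dimension of the analysis conductance space (channels + leak)."""
        return len(self.channels) + 1

    def channel(self, name: str) -> ChannelSpec:
        for c in self.all_channels:
            if c.name == name:
                return c
        raise KeyError(f"model {self.name} has no channel {name!r}")

    def index(self, name: str) -> int:
        return self.channel_names.index(name)


@dataclass
class ConductanceVector:
    """One neuron's maximal conductances (mS/cm^2), leak included.

    ``values`` follows the model's channel order with leak last.
    """

    model: ModelSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.model.N,):
            raise ValueError(
                f"expected {self.model.N} conductances for model "
                f"{self.model.name}, got shape {self.values.shape}"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("maximal conductances must be finite and >= 0")

    @classmethod
    def from_dict(cls, model: ModelSpec, d: dict[str, float]) -> "ConductanceVector":
        missing = set(model.channel_names) - set(d)
        extra = set(d) - set(model.channel_names)
        if missing or extra:
            raise ValueError(
                f"conductance keys mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        return cls(model, np.array([d[n] for n in model.channel_names]))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.model.channel_names, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.model.index(name)])

    @property
    def gleak(self) -> float:
        return float(self.values[-1])

    def scaled(self, alpha: float) -> "ConductanceVector":
        """Homogeneous scaling: every conductance (leak included) times alpha."""
        return ConductanceVector(self.model, self.values * alpha)

    def replace(self, **updates: float) -> "ConductanceVector":
        vals = self.values.copy()
        for name, v in updates.items():
            vals[self.model.index(name)] = v
        return ConductanceVector(self.model, vals)


# ---------------------------------------------------------------------------
# YAML loading
# ---------------------------------------------------------------------------

_KNOWN_MODELS = {"STG": "stg.yaml", "DA": "da.yaml"}


def _parse_rate(d: dict) -> RateFunction:
    return RateFunction(form=d["form"], p=tuple(float(x) for x in d["p"]))


def _parse_channel(d: dict) -> ChannelSpec:
    b = int(d.get("b", 0))
    return ChannelSpec(
        name=str(d["name"]),
        a=int(d["a"]),
        b=b,
        m_inf=_parse_rate(d["m_inf"]),
        tau_m=_parse_rate(d["tau_m"]),
        h_inf=_parse_rate(d["h_inf"]) if b > 0 else None,
        tau_h=_parse_rate(d["tau_h"]) if b > 0 else None,
        reversal=(
            CALCIUM_REVERSAL
            if d["reversal"] == CALCIUM_REVERSAL
            else float(d["reversal"])
        ),
        calcium_source=bool(d.get("calcium_source", False)),
        depends_on_calcium=bool(d.get("depends_on_calcium", False)),
    )


def load_model_file(path: str | Path) -> ModelSpec:
    """Parse a model-definition YAML file into a :class:`ModelSpec`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        channels = tuple(_parse_channel(c) for c in raw["channels"])
        baseline = tuple(
            (_parse_channel(c), float(c["baseline_gbar"]))
            for c in raw.get("baseline_channels", [])
        )
        calcium = None
        if "calcium" in raw:
            calcium = CalciumDynamics(**{k: float(v) for k, v in raw["calcium"].items()})
        spec = ModelSpec(
            name=str(raw["name"]),
            channels=channels,
            C=float(raw["C"]),
            E_leak=float(raw["E_leak"]),
            calcium=calcium,
            baseline_channels=baseline,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed model definition {path}: {exc}") from exc
    declared = raw.get("N")
    if declared is not None and int(declared) != spec.N:
        raise ValueError(
            f"model {spec.name}: declared analysis dimension N={declared} "
            f"but definition has {spec.N}"
        )
    _validate_gating(spec)
    return spec


def _validate_gating(spec: ModelSpec, V_lo: float = -120.0, V_hi: float = 60.0):
    V = np.linspace(V_lo, V_hi, 181)
    ca = spec.calcium.ca_rest if spec.calcium else 1.0
    for c in spec.all_channels:
        pairs = [(c.m_inf, c.tau_m)] + ([(c.h_inf, c.tau_h)] if c.has_h else [])
        for inf, tau in pairs:
            x = inf(V, ca)
            if np.any(x < -1e-12) or np.any(x > 1.0 + 1e-12):
                raise ValueError(f"channel {c.name}: steady-state gate out of [0,1]")
            t = tau(V, ca)
            if np.any(t <= 0):
                raise ValueError(f"channel {c.name}: non-positive time constant")


def build_model(name: str, kinetics_source: str | Path | None = None) -> ModelSpec:
    """Build a model by name ("STG" or "DA"), or from an explicit kinetics file.

    The two shipped models are the crab stomatogastric-ganglion burster
    (seven gated channels + leak, N=8) and an adapted dopaminergic tonic
    spiker (five analysis channels + leak, N=6, NMDA simulated at a fixed
    baseline but excluded from the conductance space).
    """
    if kinetics_source is not None:
        spec = load_model_file(kinetics_source)
        if name != spec.name:
            raise ValueError(f"model file defines {spec.name!r}, not {name!r}")
        return spec
    if name not in _KNOWN_MODELS:
        raise ValueError(f"unknown model name {name!r}; known: {sorted(_KNOWN_MODELS)}")
    ref = resources.files("neurodegen.modeldefs") / _KNOWN_MODELS[name]
    with resources.as_file(ref) as path:
        return load_model_file(path)
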