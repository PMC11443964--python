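"""Simulation front end: voltage traces, steady states and input conductance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import pack_model, _run
from .modelspec import ConductanceVector, ModelSpec

__all__ = [
    "CurrentStep",
    "VoltageTrace",
    "SimulationError",
    "simulate",
    "steady_state_current",
    "calcium_steady_state",
    "calcium_steady_state_grad",
    "input_conductance",
]


class SimulationError(RuntimeError):
    """Raised when numerical integration produces a non-finite state."""


@dataclass(frozen=True)
class CurrentStep:
    """Applied-current protocol: a holding current plus one rectangular step."""

    base: float = 0.0  # uA/cm^2
    amplitude: float = 0.0
    t_on: float = 0.0  # ms
    t_off: float = 0.0

    def at(self, t: np.ndarray) -> np.ndarray:
        out = np.full_like(np.asarray(t, float), self.base)
        out[(t >= self.t_on) & (t < self.t_off)] += self.amplitude
        return out


@dataclass
class VoltageTrace:
    """A simulated membrane-potential trace (times in ms, V in mV)."""

    t: np.ndarray
    V: np.ndarray
    Iext: np.ndarray
    aux: dict = field(default_factory=dict)
    model_name: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")


def _steady_gate_values(model: ModelSpec, V: float, Ca: float):
    m = []
    h = []
    for c in model.all_channels:
        m.append(float(c.m_inf(V, Ca)))
        h.append(float(c.h_inf(V, Ca)) if c.has_h else 0.0)
    return np.array(m), np.array(h)


def _calcium_sources(model: ModelSpec, g: ConductanceVector):
    pm = pack_model(model)
    gbar = pm.full_gbar(g.values[:-1])
    return [
        (gbar[i], c)
        for i, c in enumerate(model.all_channels)
        if c.calcium_source
    ]


def calcium_steady_state_grad(
    model: ModelSpec, g: ConductanceVector, V, n_iter: int = 40
):
    """Steady-state intracellular calcium and its voltage derivative.

    Solves Ca = ca_rest - f * I_Ca(V, Ca) per voltage by Newton iteration
    (the Nernst reversal feeds Ca back into I_Ca), then differentiates the
    fixed point implicitly:  dCa/dV = -f dI/dV / (1 + f dI/dCa).
    Vectorised over V; returns (Ca, dCa_dV) as arrays matching V.
    """
    Vv = np.atleast_1d(np.asarray(V, dtype=float))
    ca = model.calcium
    if ca is None:
        return np.zeros_like(Vv), np.zeros_like(Vv)
    src = _calcium_sources(model, g)
    Ca = np.full_like(Vv, ca.ca_rest)

    def currents(Ca_arr):
        # returns I_Ca, dI/dCa, dI/dV at gates frozen at X_inf(V)
        E = ca.nernst_mV * np.log(ca.ca_out / Ca_arr)
        I = np.zeros_like(Vv)
        dIdCa = np.zeros_like(Vv)
        dIdV = np.zeros_like(Vv)
        dv = 1e-3
        for gb, c in src:
            if gb == 0.0:
                continue
            def gate(Vx):
                out = np.asarray(c.m_inf(Vx, Ca_arr)) ** c.a
                if c.has_h:
                    out = out * np.asarray(c.h_inf(Vx, Ca_arr)) ** c.b
                return out
            gt = gate(Vv)
            I += gb * gt * (Vv - E)
            dIdCa += gb * gt * (ca.nernst_mV / Ca_arr)
            dgdV = (gate(Vv + dv) - gate(Vv - dv)) / (2 * dv)
            dIdV += gb * (dgdV * (Vv - E) + gt)
        return I, dIdCa, dIdV

    for _ in range(n_iter):
        I, dIdCa, _ = currents(Ca)
        F = ca.ca_rest - ca.f * I - Ca
        dF = -ca.f * dIdCa - 1.0
        step = F / dF
        Ca = np.maximum(Ca - step, 1e-9)
        if np.max(np.abs(step)) < 1e-13 * max(1.0, float(np.max(Ca))):
            break
    I, dIdCa, dIdV = currents(Ca)
    dCadV = -ca.f * dIdV / (1.0 + ca.f * dIdCa)
    return Ca, dCadV


def calcium_steady_state(model: ModelSpec, g: ConductanceVector, V):
    """Fixed point of the intracellular-calcium pool with gates at X_inf(V).

    Accepts a scalar or an array of voltages.
    """
    scalar = np.asarray(V).ndim == 0
    Ca, _ = calcium_steady_state_grad(model, g, V)
    return float(Ca[0]) if scalar else Ca


def steady_state_current(
    model: ModelSpec,
    g: ConductanceVector,
    V,
    Iext: float = 0.0,
    frozen_ca: float | None = None,
):
    """Steady-state membrane current I_ss(V) (outward positive, uA/cm^2).

    All gates sit at their steady-state values for V; intracellular calcium
    sits at its own fixed point for V unless ``frozen_ca`` pins it.
    """
    V = np.asarray(V, dtype=float)
    scalar = V.ndim == 0
    Vv = np.atleast_1d(V)
    pm = pack_model(model)
    gbar = pm.full_gbar(g.values[:-1])
    out = np.empty_like(Vv)
    for k, v in enumerate(Vv):
        Ca = (
            frozen_ca
            if frozen_ca is not None
            else calcium_steady_state(model, g, float(v))
        )
        I = g.gleak * (v - model.E_leak)
        for i, c in enumerate(model.all_channels):
            minf = float(c.m_inf(v, Ca))
            gate = minf ** c.a
            if c.has_h:
                gate *= float(c.h_inf(v, Ca)) ** c.b
            E = (
                model.calcium.nernst_mV * np.log(model.calcium.ca_out / Ca)
                if c.has_calcium_reversal
                else c.reversal
            )
            I += gbar[i] * gate * (v - E)
        out[k] = I - Iext
    return float(out[0]) if scalar else out


def simulate(
    model: ModelSpec,
    g: ConductanceVector,
    Iext: float | CurrentStep = 0.0,
    duration: float = 10_000.0,
    transient: float = 2_000.0,
    dt: float = 0.05,
    record_dt: float = 0.1,
    V0: float = -65.0,
) -> VoltageTrace:
    """Integrate the model and return the trace on [transient, duration].

    Gating states and calcium are initialised at their steady-state values
    for V0, and the first ``transient`` ms are discarded, so metrics are not
    biased by initialisation.  Integration uses exponential Euler at fixed
    step ``dt`` (ms); halving ``dt`` is the accuracy control.
    """
    if not duration > transient >= 0:
        raise ValueError("need duration > transient >= 0")
    if g.model is not model:
        if g.model.name != model.name or g.model.channel_names != model.channel_names:
            raise ValueError("conductance vector does not match model")
    proto = Iext if isinstance(Iext, CurrentStep) else CurrentStep(base=float(Iext))
    pm = pack_model(model)
    Ca0 = calcium_steady_state(model, g, V0)
    m0, h0 = _steady_gate_values(model, V0, Ca0)
    nsteps = int(round(duration / dt))
    rec_every = max(int(round(record_dt / dt)), 1)
    trec, Vrec, Carec, ok = _run(
        pm.a, pm.b, pm.E, pm.is_carev, pm.is_caflux,
        pm.mf, pm.mp, pm.tmf, pm.tmp, pm.hf, pm.hp, pm.thf, pm.thp,
        pm.C, pm.E_leak, pm.has_ca, pm.ca_tau, pm.ca_f, pm.ca_rest,
        pm.ca_out, pm.ca_nernst,
        pm.full_gbar(g.values[:-1]), g.gleak, float(V0), float(Ca0),
        m0, h0, float(dt), nsteps, rec_every,
        proto.base, proto.amplitude, proto.t_on, proto.t_off,
    )
    if not ok or not np.all(np.isfinite(Vrec)):
        raise SimulationError(
            f"membrane potential diverged (model {model.name}, "
            f"t ~ {trec[-1]:.1f} ms)"
        )
    keep = trec >= transient
    aux = {"Ca": Carec[keep]} if pm.has_ca else {}
    t = trec[keep]
    return VoltageTrace(t=t, V=Vrec[keep], Iext=proto.at(t), aux=aux,
                        model_name=model.name)


def input_conductance(
    model: ModelSpec,
    g: ConductanceVector,
    V_ref: float = -70.0,
    dV: float = 0.01,
) -> float:
    """Slope conductance g_in(V_ref) = dI_ss/dV (mS/cm^2); R_in = 1/g_in.

    Positive for a stable subthreshold reference point.  Raises if the
    slope is non-positive (unstable point: pick a different V_ref).
    """
    I = steady_state_current(model, g, [V_ref - dV, V_ref + dV])
    gin = float((I[1] - I[0]) / (2.0 * dV))
    if gin <= 0:
        raise ValueError(
            f"g_in({V_ref} mV) = {gin:.4g} <= 0 (unstable point); "
            "choose a different V_ref"
        )
    return gin
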