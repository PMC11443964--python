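"""Dynamic input conductances (DICs) and the sensitivity machinery.

A conductance-based model's voltage dynamics can be summarised by three
voltage-dependent aggregate conductances acting on separate timescales --
fast g_f(V), slow g_s(V) and ultraslow g_u(V).  At each voltage they are
linear in the maximal-conductance vector:

    [g_f(V); g_s(V); g_u(V)] = S(V) . gbar,

where the 3 x N sensitivity matrix S(V) distributes each gating variable's
first-order effect on dV/dt over the three timescales according to the
logarithmic distance of its time constant from three reference timescales,
and is normalised by the leak conductance so the DICs are dimensionless.

Sign convention: positive DIC = net restorative (negative) feedback;
negative = regenerative (positive) feedback.  The threshold voltage V_th is
the subthreshold zero crossing of g_f (onset of net fast positive
feedback); the DIC values at V_th determine the firing pattern, which is
what the population generators and the neuromodulation rule exploit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .modelspec import ChannelSpec, ConductanceVector, ModelSpec
from .simulate import calcium_steady_state, calcium_steady_state_grad

__all__ = [
    "Gate",
    "TimescaleRefs",
    "TimescaleWeights",
    "SensitivityMatrix",
    "DICProfile",
    "DICTargets",
    "NoThresholdError",
    "gates",
    "timescale_weights",
    "sensitivity_matrix",
    "dic_at",
    "dic_curves",
    "threshold_voltage",
    "compensate",
    "zero_sensitivity_direction",
]

_DV = 1e-3  # mV step for d/dV of steady-state gating curves

FAST, SLOW, ULTRASLOW = 0, 1, 2


class NoThresholdError(ValueError):
    """The fast DIC has no subthreshold zero crossing for this neuron."""


@dataclass(frozen=True)
class Gate:
    """One gating variable of an analysis channel."""

    channel: ChannelSpec
    which: str  # "m" or "h"
    chan_index: int  # column in the conductance space

    @property
    def name(self) -> str:
        return f"{self.channel.name}:{self.which}"

    def inf(self, V, Ca):
        fn = self.channel.m_inf if self.which == "m" else self.channel.h_inf
        return fn(V, Ca)

    def tau(self, V, Ca):
        fn = self.channel.tau_m if self.which == "m" else self.channel.tau_h
        return fn(V, Ca)


def gates(model: ModelSpec) -> list[Gate]:
    """Gating variables of the analysis channels, in model order."""
    out = []
    for j, c in enumerate(model.channels):
        out.append(Gate(c, "m", j))
        if c.has_h:
            out.append(Gate(c, "h", j))
    return out


@dataclass(frozen=True)
class TimescaleRefs:
    """Reference time constants tau_f(V) < tau_s(V) < tau_u(V).

    Defaults: tau_f is the fast sodium activation time constant, tau_s the
    delayed-rectifier activation time constant, and tau_u the slowest
    gating time constant of the model, all as functions of V.
    """

    model: ModelSpec
    fast_gate: str = "Na:m"
    slow_gate: str = "Kd:m"

    def _gate(self, name: str) -> Gate:
        for g in gates(self.model):
            if g.name == name:
                return g
        raise KeyError(f"no gate named {name!r} in model {self.model.name}")

    def __call__(self, V, Ca):
        """Reference timescales at V (vectorised over voltage arrays)."""
        Vv = np.atleast_1d(np.asarray(V, dtype=float))
        Cav = np.broadcast_to(np.atleast_1d(np.asarray(Ca, float)), Vv.shape)
        tf = np.asarray(self._gate(self.fast_gate).tau(Vv, Cav), float)
        ts = np.asarray(self._gate(self.slow_gate).tau(Vv, Cav), float)
        tu = np.max(
            np.stack([np.broadcast_to(np.asarray(g.tau(Vv, Cav), float), Vv.shape)
                      for g in gates(self.model)]),
            axis=0,
        )
        if not (np.all(tf < ts) and np.all(ts < tu)):
            k = int(np.argmin((ts - tf) + (tu - ts)))
            raise ValueError(
                f"reference timescales not ordered at V={Vv[k]:.1f}: "
                f"tau_f={tf[k]:.3g}, tau_s={ts[k]:.3g}, tau_u={tu[k]:.3g}"
            )
        return tf, ts, tu


@dataclass
class TimescaleWeights:
    """Partition of unity over (fast, slow, ultraslow) per gating variable."""

    gate_names: list[str]
    tau: np.ndarray  # per-gate time constants at V
    w: np.ndarray  # 3 x n_gates, columns sum to 1
    refs: tuple[float, float, float]
    V: float


def _log_partition(tau, tf, ts, tu) -> np.ndarray:
    """Piecewise-linear partition of unity in log(tau) between the refs.

    Vectorised: all arguments broadcast; returns shape (..., 3).
    """
    lt, lf, ls, lu = np.log(tau), np.log(tf), np.log(ts), np.log(tu)
    lt, lf, ls, lu = np.broadcast_arrays(lt, lf, ls, lu)
    w = np.zeros(lt.shape + (3,))
    below = lt <= ls
    wf = np.clip((ls - lt) / (ls - lf), 0.0, 1.0)
    ws = np.clip((lu - lt) / (lu - ls), 0.0, 1.0)
    w[..., 0] = np.where(below, wf, 0.0)
    w[..., 1] = np.where(below, 1.0 - wf, ws)
    w[..., 2] = np.where(below, 0.0, 1.0 - ws)
    return w


def timescale_weights(
    model: ModelSpec, V: float, refs: TimescaleRefs | None = None, Ca: float | None = None
) -> TimescaleWeights:
    """Timescale weights for every gating variable at one voltage."""
    refs = refs or TimescaleRefs(model)
    if Ca is None:
        Ca = model.calcium.ca_rest if model.calcium else 0.0
    tf, ts, tu = (float(x[0]) for x in refs(V, Ca))
    gs = gates(model)
    tau = np.array([float(np.atleast_1d(g.tau(V, Ca))[0]) for g in gs])
    w = _log_partition(tau, tf, ts, tu).T  # 3 x n_gates
    return TimescaleWeights(
        gate_names=[g.name for g in gs], tau=tau, w=w, refs=(tf, ts, tu), V=V
    )


@dataclass
class SensitivityMatrix:
    """S(V): rows (fast, slow, ultraslow), columns = conductances, /gleak."""

    S: np.ndarray  # 3 x N
    V: float
    channel_names: list[str]
    frozen_ca: float | None = None

    def columns(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.channel_names.index(n) for n in names]
        return self.S[:, idx]


def _assemble_S(
    model: ModelSpec,
    g: ConductanceVector,
    Vv: np.ndarray,
    refs: TimescaleRefs | None,
    frozen_ca: float | None,
) -> np.ndarray:
    """S(V) stacked over a voltage grid: shape (len(V), 3, N).

    With ``frozen_ca`` set, intracellular calcium is pinned (exactly linear
    in gbar); otherwise calcium sits at its steady state for each V and is
    treated as a first-order variable of time constant tau_Ca, adding chain
    terms for calcium-gated channels and for Nernst-reversal drift.
    """
    if g.gleak <= 0:
        raise ValueError("sensitivity matrix undefined for gleak = 0")
    Vv = np.asarray(Vv, dtype=float)
    chain = frozen_ca is None and model.calcium is not None
    if frozen_ca is not None:
        Ca = np.full_like(Vv, float(frozen_ca))
    else:
        Ca, dCadV = calcium_steady_state_grad(model, g, Vv)
    refs = refs or TimescaleRefs(model)
    tf, ts, tu = refs(Vv, Ca)
    N = model.N
    S = np.zeros((Vv.size, 3, N))
    S[:, FAST, N - 1] = 1.0  # leak: purely passive, fast row
    for j, c in enumerate(model.channels):
        m = np.asarray(c.m_inf(Vv, Ca), float)
        h = np.asarray(c.h_inf(Vv, Ca), float) if c.has_h else np.ones_like(Vv)
        if c.has_calcium_reversal:
            E = model.calcium.nernst_mV * np.log(model.calcium.ca_out / Ca)
        else:
            E = float(c.reversal)
        drive = Vv - E
        S[:, FAST, j] += m**c.a * h**c.b  # instantaneous conductance
        for gate in (gg for gg in gates(model) if gg.chan_index == j):
            if gate.which == "m":
                dIdX = c.a * m ** (c.a - 1) * h**c.b * drive
            else:
                dIdX = c.b * m**c.a * h ** (c.b - 1) * drive
            tau = np.asarray(gate.tau(Vv, Ca), float)
            w = _log_partition(tau, tf, ts, tu)
            dinf = (
                np.asarray(gate.inf(Vv + _DV, Ca), float)
                - np.asarray(gate.inf(Vv - _DV, Ca), float)
            ) / (2 * _DV)
            S[:, :, j] += w * (dIdX * dinf)[..., None]
            if chain and c.depends_on_calcium:
                # gate tracks Ca_inf(V): chain with relaxation tau_gate+tau_Ca
                dCa = 1e-4 * np.maximum(Ca, 1.0)
                dinf_dCa = (
                    np.asarray(gate.inf(Vv, Ca + dCa), float)
                    - np.asarray(gate.inf(Vv, Ca - dCa), float)
                ) / (2 * dCa)
                wch = _log_partition(tau + model.calcium.tau, tf, ts, tu)
                S[:, :, j] += wch * (dIdX * dinf_dCa * dCadV)[..., None]
        if chain and c.has_calcium_reversal:
            # Nernst reversal drifts restoratively as Ca tracks Ca_inf(V)
            wch = _log_partition(model.calcium.tau, tf, ts, tu)
            S[:, :, j] += wch * (
                m**c.a * h**c.b * (model.calcium.nernst_mV / Ca) * dCadV
            )[..., None]
    S /= g.gleak
    return S


def sensitivity_matrix(
    model: ModelSpec,
    g: ConductanceVector,
    V: float,
    refs: TimescaleRefs | None = None,
    frozen_ca: float | None = None,
) -> SensitivityMatrix:
    """Build S(V) such that (g_f, g_s, g_u) at V equals S(V) . gbar."""
    S = _assemble_S(model, g, np.array([float(V)]), refs, frozen_ca)[0]
    ca = frozen_ca
    if ca is None and model.calcium is not None:
        ca = calcium_steady_state(model, g, float(V))
    return SensitivityMatrix(S=S, V=float(V), channel_names=model.channel_names,
                             frozen_ca=ca)


def dic_at(
    model: ModelSpec,
    g: ConductanceVector,
    V: float,
    refs: TimescaleRefs | None = None,
    frozen_ca: float | None = None,
) -> np.ndarray:
    """(g_f, g_s, g_u) at voltage V: the matrix-vector product S(V) . gbar."""
    S = _assemble_S(model, g, np.array([float(V)]), refs, frozen_ca)[0]
    return S @ g.values


@dataclass
class DICProfile:
    """DIC curves on a voltage grid plus their values at threshold."""

    V_grid: np.ndarray
    gf: np.ndarray
    gs: np.ndarray
    gu: np.ndarray
    V_th: float | None
    at_threshold: tuple[float, float, float] | None


def dic_curves(
    model: ModelSpec,
    g: ConductanceVector,
    V_grid: np.ndarray | None = None,
    refs: TimescaleRefs | None = None,
) -> DICProfile:
    if V_grid is None:
        V_grid = np.arange(-80.0, -19.9, 0.5)
    V_grid = np.asarray(V_grid, dtype=float)
    vals = _assemble_S(model, g, V_grid, refs, None) @ g.values
    try:
        vth = threshold_voltage(model, g, refs=refs)
        at = tuple(dic_at(model, g, vth, refs))
    except NoThresholdError:
        vth, at = None, None
    return DICProfile(V_grid=V_grid, gf=vals[:, 0], gs=vals[:, 1], gu=vals[:, 2],
                      V_th=vth, at_threshold=at)


def threshold_voltage(
    model: ModelSpec,
    g: ConductanceVector,
    bounds: tuple[float, float] = (-80.0, -20.0),
    refs: TimescaleRefs | None = None,
    xtol: float = 1e-3,
) -> float:
    """V_th: subthreshold zero crossing of the fast DIC (+ to - downward).

    Found by scanning a 0.5 mV grid for a sign change and bisecting to
    ``xtol`` mV.  Raises :class:`NoThresholdError` when g_f does not cross
    zero in ``bounds`` (e.g. a passive neuron with no fast positive
    feedback).
    """
    lo, hi, step = bounds[0], bounds[1], 0.5
    while True:
        grid = np.arange(lo, hi + 1e-12, step)
        gf = (_assemble_S(model, g, grid, refs, None) @ g.values)[:, FAST]
        crossing = np.flatnonzero((gf[:-1] > 0) & (gf[1:] <= 0))
        if crossing.size == 0:
            raise NoThresholdError(
                f"no threshold: fast DIC has no +/- zero crossing in {bounds}"
            )
        i = int(crossing[0])
        lo, hi = float(grid[i]), float(grid[i + 1])
        if step <= xtol:
            # linear interpolation inside the final bracket
            f0, f1 = float(gf[i]), float(gf[i + 1])
            return lo + (hi - lo) * f0 / (f0 - f1) if f0 != f1 else lo
        step = (hi - lo) / 8.0


@dataclass(frozen=True)
class DICTargets:
    """Target DIC values at a fixed threshold voltage.

    ``gf`` defaults to 0 because V_th is, by definition, the voltage where
    the fast DIC crosses zero: solving with gf(V_th)=0 pins the threshold
    of every generated neuron at ``V_th``.
    """

    V_th: float
    gs: float
    gu: float
    gf: float = 0.0

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.gf, self.gs, self.gu])


def compensate(
    model: ModelSpec,
    g: ConductanceVector,
    unknowns: Sequence[str],
    targets: DICTargets,
    refs: TimescaleRefs | None = None,
    rtol: float = 1e-10,
    max_cond: float = 1e8,
    max_iter: int = 60,
) -> ConductanceVector | None:
    """Solve 3 conductances so the DICs at V_th hit ``targets`` exactly.

    The remaining N-3 conductances (and gleak) of ``g`` are kept as given.
    Returns the completed vector, or None as a reject-and-resample signal
    when the solve is ill-conditioned or produces a negative conductance.
    Because intracellular calcium (when the model has it) feeds back on
    S(V_th), the linear solve is fixed-point iterated to self-consistency.
    """
    if len(unknowns) != 3:
        raise ValueError("exactly three unknown conductances are required")
    idx = [model.index(n) for n in unknowns]
    if model.N - 1 in idx:
        raise ValueError("gleak cannot be a compensation unknown")
    vals = g.values.copy()
    tvec = targets.vector
    x_raw = vals[idx].copy()
    hist: list[np.ndarray] = []
    scale = max(1.0, float(np.max(np.abs(tvec))))
    Vthv = np.array([targets.V_th])

    def background(xr):
        bg = vals.copy()
        bg[idx] = np.maximum(xr, 0.0)  # calcium background needs valid gbars
        return ConductanceVector(model, bg)

    for _ in range(max_iter):
        S = _assemble_S(model, background(x_raw), Vthv, refs, None)[0]
        A = S[:, idx]
        if np.linalg.cond(A) > max_cond:
            return None
        known = vals.copy()
        known[idx] = 0.0
        rhs = tvec - S @ known
        try:
            x_new = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            return None
        x_raw = _secant_accelerate(hist, x_new)
        # residual of the raw solution in its own (clipped) background
        S2 = _assemble_S(model, background(x_raw), Vthv, refs, None)[0]
        full = vals.copy()
        full[idx] = x_raw
        resid = np.abs(S2 @ full - tvec)
        if float(np.max(resid)) < rtol * scale:
            if np.any(x_raw < 0):
                return None  # converged but infeasible: reject-and-resample
            out = vals.copy()
            out[idx] = x_raw
            return ConductanceVector(model, out)
    return None  # calcium fixed point failed to settle


def _secant_accelerate(hist: list[np.ndarray], x: np.ndarray) -> np.ndarray:
    """Vector-secant extrapolation of a geometrically converging fixed-point
    iteration; falls back to the plain iterate when the contraction estimate
    is unreliable or extrapolation would go negative."""
    hist.append(x.copy())
    if len(hist) < 3:
        return x
    d1 = hist[-2] - hist[-3]
    d2 = hist[-1] - hist[-2]
    denom = float(d1 @ d1)
    if denom <= 0:
        return x
    rho = float(d2 @ d1) / denom
    if not 0.0 < rho < 0.98:
        return x
    xacc = hist[-2] + d2 / (1.0 - rho)
    hist.clear()
    hist.append(xacc.copy())
    return xacc


def zero_sensitivity_direction(
    model: ModelSpec,
    g: ConductanceVector,
    pair: Sequence[str],
    timescale: str = "slow",
    V: float | None = None,
    refs: TimescaleRefs | None = None,
) -> np.ndarray:
    """Unit direction in a conductance pair's plane leaving one DIC unchanged.

    For channels (c1, c2) with total sensitivities (s1, s2) of the chosen
    DIC at V, the direction (d1, d2) with s1*d1 + s2*d2 = 0 moves
    conductances without changing that DIC at V to first order.  The
    sensitivities are total derivatives of the DIC (central differences of
    the self-consistent map), so calcium-mediated feedback is included;
    for calcium-free models they equal the S(V) row entries exactly.
    Sign convention: d1 >= 0.
    """
    row = {"fast": FAST, "slow": SLOW, "ultraslow": ULTRASLOW}[timescale]
    if V is None:
        V = threshold_voltage(model, g, refs=refs)
    s = np.empty(2)
    for k, nm in enumerate(pair):
        j = model.index(nm)
        h = 1e-4 * max(float(g.values[j]), 1.0)
        vp, vm = g.values.copy(), g.values.copy()
        vp[j] += h
        vm[j] = max(vm[j] - h, 0.0)
        dp = _assemble_S(model, ConductanceVector(model, vp), np.array([V]),
                         refs, None)[0] @ vp
        dm = _assemble_S(model, ConductanceVector(model, vm), np.array([V]),
                         refs, None)[0] @ vm
        s[k] = (dp[row] - dm[row]) / (vp[j] - vm[j])
    if np.all(np.abs(s) < 1e-12):
        raise ValueError(f"direction undefined: both {timescale} sensitivities ~ 0")
    d = np.array([s[1], -s[0]])
    d /= np.linalg.norm(d)
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return d
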