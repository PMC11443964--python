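"""Compiled integration kernel for conductance-based models.

The kernel is model-agnostic: a :class:`~neurodegen.modelspec.ModelSpec` is
packed into flat parameter arrays (gating-law exponents, rate-function form
ids and parameters, reversals, calcium bookkeeping) that a single
numba-compiled loop consumes.  Gates, calcium and voltage are advanced with
the exponential-Euler scheme that is standard for this model family: each
state relaxes exactly toward its instantaneous equilibrium over one step,
which is robust across the four decades of time constants these models span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .modelspec import ModelSpec, _MAX_PARAMS

__all__ = ["PackedModel", "pack_model"]


@dataclass(frozen=True)
class PackedModel:
    """Flat-array view of a ModelSpec consumed by the compiled kernel."""

    a: np.ndarray
    b: np.ndarray
    E: np.ndarray
    is_carev: np.ndarray
    is_caflux: np.ndarray
    mf: np.ndarray
    mp: np.ndarray
    tmf: np.ndarray
    tmp: np.ndarray
    hf: np.ndarray
    hp: np.ndarray
    thf: np.ndarray
    thp: np.ndarray
    C: float
    E_leak: float
    has_ca: bool
    ca_tau: float
    ca_f: float
    ca_rest: float
    ca_out: float
    ca_nernst: float
    baseline_gbar: np.ndarray  # appended after the analysis channels

    @property
    def nchan(self) -> int:
        return self.a.shape[0]

    def full_gbar(self, analysis_gbar: np.ndarray) -> np.ndarray:
        """Gated-channel conductances in kernel order (analysis + baseline)."""
        return np.concatenate([np.asarray(analysis_gbar, float), self.baseline_gbar])


_PACK_CACHE: dict[int, PackedModel] = {}


def pack_model(model: ModelSpec) -> PackedModel:
    key = id(model)
    if key in _PACK_CACHE:
        return _PACK_CACHE[key]
    chans = list(model.all_channels)
    n = len(chans)
    a = np.array([c.a for c in chans], dtype=np.int64)
    b = np.array([c.b for c in chans], dtype=np.int64)
    E = np.array(
        [0.0 if c.has_calcium_reversal else float(c.reversal) for c in chans]
    )
    is_carev = np.array([1 if c.has_calcium_reversal else 0 for c in chans], np.int64)
    is_caflux = np.array([1 if c.calcium_source else 0 for c in chans], np.int64)

    def forms(fns):
        ids = np.zeros(n, np.int64)
        ps = np.zeros((n, _MAX_PARAMS))
        for i, fn in enumerate(fns):
            if fn is not None:
                ids[i] = fn.form_id
                ps[i] = fn.packed()
        return ids, ps

    mf, mp = forms([c.m_inf for c in chans])
    tmf, tmp = forms([c.tau_m for c in chans])
    hf, hp = forms([c.h_inf for c in chans])
    thf, thp = forms([c.tau_h for c in chans])
    ca = model.calcium
    packed = PackedModel(
        a=a, b=b, E=E, is_carev=is_carev, is_caflux=is_caflux,
        mf=mf, mp=mp, tmf=tmf, tmp=tmp, hf=hf, hp=hp, thf=thf, thp=thp,
        C=model.C, E_leak=model.E_leak,
        has_ca=ca is not None,
        ca_tau=ca.tau if ca else 1.0,
        ca_f=ca.f if ca else 0.0,
        ca_rest=ca.ca_rest if ca else 0.0,
        ca_out=ca.ca_out if ca else 1.0,
        ca_nernst=ca.nernst_mV if ca else 0.0,
        baseline_gbar=np.array([g for _, g in model.baseline_channels]),
    )
    _PACK_CACHE[key] = packed
    return packed


@njit(cache=True)
def _feval(form, p, V, Ca):  # pragma: no cover - exercised via the kernel
    if form == 0:
        return p[0]
    elif form == 1:
        return 1.0 / (1.0 + np.exp((V - p[0]) / p[1]))
    elif form == 2:
        return p[0] + p[1] / (1.0 + np.exp((V - p[2]) / p[3]))
    elif form == 3:
        return p[0] + p[1] / (np.exp((V - p[2]) / p[3]) + np.exp((V - p[4]) / p[5]))
    elif form == 4:
        return (p[0] / (1.0 + np.exp((V - p[1]) / p[2]))) * (
            p[3] + p[4] / (1.0 + np.exp((V - p[5]) / p[6]))
        )
    elif form == 5:
        return (Ca / (Ca + p[0])) / (1.0 + np.exp((V - p[1]) / p[2]))
    elif form == 6:
        return 1.0 / (1.0 + p[0] * np.exp(p[1] * V))
    return 0.0


@njit(cache=True)
def _run(a, b, E, is_carev, is_caflux, mf, mp, tmf, tmp, hf, hp, thf, thp,
         C, Eleak, has_ca, ca_tau, ca_f, ca_rest, ca_out, ca_nernst,
         gbar, gleak, V0, Ca0, m0, h0, dt, nsteps, rec_every,
         I_base, I_step, t_on, t_off):  # pragma: no cover - compiled
    nchan = a.shape[0]
    m = m0.copy()
    h = h0.copy()
    V = V0
    Ca = Ca0
    nrec = nsteps // rec_every + 1
    trec = np.empty(nrec)
    Vrec = np.empty(nrec)
    Carec = np.empty(nrec)
    trec[0] = 0.0
    Vrec[0] = V
    Carec[0] = Ca
    r = 1
    ok = True
    for step in range(1, nsteps + 1):
        t = step * dt
        for c in range(nchan):
            minf = _feval(mf[c], mp[c], V, Ca)
            taum = _feval(tmf[c], tmp[c], V, Ca)
            m[c] = minf + (m[c] - minf) * np.exp(-dt / taum)
            if b[c] > 0:
                hinf = _feval(hf[c], hp[c], V, Ca)
                tauh = _feval(thf[c], thp[c], V, Ca)
                h[c] = hinf + (h[c] - hinf) * np.exp(-dt / tauh)
        Gtot = gleak
        GE = gleak * Eleak
        Ica = 0.0
        for c in range(nchan):
            g = gbar[c] * m[c] ** a[c]
            if b[c] > 0:
                g = g * h[c] ** b[c]
            Ec = E[c]
            if is_carev[c] == 1:
                Ec = ca_nernst * np.log(ca_out / Ca)
            Gtot += g
            GE += g * Ec
            if is_caflux[c] == 1:
                Ica += g * (V - Ec)
        Iext = I_base
        if t_on <= t < t_off:
            Iext += I_step
        if has_ca:
            ca_tgt = ca_rest - ca_f * Ica
            if ca_tgt < 1e-9:
                ca_tgt = 1e-9
            Ca = ca_tgt + (Ca - ca_tgt) * np.exp(-dt / ca_tau)
        Vinf = (GE + Iext) / Gtot
        V = Vinf + (V - Vinf) * np.exp(-dt * Gtot / C)
        if step % rec_every == 0:
            trec[r] = t
            Vrec[r] = V
            Carec[r] = Ca
            r += 1
            if not np.isfinite(V):
                ok = False
                break
    return trec[:r], Vrec[:r], Carec[:r], ok
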