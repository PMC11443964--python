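"""Reliable neuromodulation of degenerate populations.

The rule is indirect: a neuromodulator sets a new target for the slow DIC
at threshold while the ultraslow DIC is held at each neuron's own value
(preserving burst/interburst period), and a fixed pair of channel
conductances is re-solved from the 2x2 (slow, ultraslow) block of the
sensitivity matrix.  Applied across a degenerate population this yields
the same firing-pattern transition for every member regardless of its
position in conductance space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dic import (
    SLOW,
    ULTRASLOW,
    NoThresholdError,
    TimescaleRefs,
    sensitivity_matrix,
    threshold_voltage,
)
from .modelspec import ConductanceVector, ModelSpec
from .populations import Population

__all__ = [
    "NeuromodState",
    "NeuromodPath",
    "RuleFit",
    "modulate_member",
    "modulate_population",
    "neuromod_path",
    "classify_rule",
]


@dataclass(frozen=True)
class NeuromodState:
    """A neuromodulatory target: slow-DIC value and the modulated pair."""

    label: str  # spiking | light_bursting | strong_bursting | custom
    gs_target: float
    modulated_pair: tuple[str, str]
    gu_target: float | None = None  # None: keep each member's own gu(V_th)


@dataclass
class NeuromodPath:
    """One neuron's trajectory under a schedule of slow-DIC targets."""

    neuron_id: int
    gs_targets: np.ndarray
    pair: tuple[str, str]
    pair_values: np.ndarray  # len(schedule) x 2
    feasible: np.ndarray  # bool per step

    def collinearity_residual(self) -> float:
        """RMS orthogonal distance of path points from their best-fit line,
        relative to the path extent (0 for perfectly straight paths)."""
        pts = self.pair_values[self.feasible]
        if pts.shape[0] < 3:
            return 0.0
        c = pts - pts.mean(axis=0)
        _, s, _ = np.linalg.svd(c, full_matrices=False)
        extent = float(s[0]) if s[0] > 0 else 1.0
        return float(s[1]) / extent


def modulate_member(
    model: ModelSpec,
    g: ConductanceVector,
    state: NeuromodState,
    refs: TimescaleRefs | None = None,
    max_cond: float = 1e8,
) -> ConductanceVector | None:
    """Re-solve the modulated pair so gs(V_th) = target and gu is preserved.

    The sensitivity matrix is evaluated once, at the member's own
    pre-modulation threshold voltage and calcium background: the indirect
    rule is the local linear map of that state, which makes the solve a
    single 2x2 linear system and neuromodulatory paths exactly straight
    lines in the pair plane.  Returns None when the solve is infeasible
    (ill-conditioned block or negative conductances).  All other
    conductances are returned bit-identical.
    """
    idx = [model.index(nm) for nm in state.modulated_pair]
    try:
        vth = threshold_voltage(model, g, refs=refs)
    except NoThresholdError:
        return None
    sm = sensitivity_matrix(model, g, vth, refs)
    dics = sm.S @ g.values
    gu_t = float(dics[ULTRASLOW]) if state.gu_target is None else state.gu_target
    tvec = np.array([state.gs_target, gu_t])
    rows = [SLOW, ULTRASLOW]
    A = sm.S[np.ix_(rows, idx)]
    if np.linalg.cond(A) > max_cond:
        return None
    known = g.values.copy()
    known[idx] = 0.0
    rhs = tvec - (sm.S @ known)[rows]
    try:
        x = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return None
    if np.any(x < 0):
        return None
    vals = g.values.copy()
    vals[idx] = x
    return ConductanceVector(model, vals)


def modulate_population(
    pop: Population, state: NeuromodState, refs: TimescaleRefs | None = None
) -> Population:
    """Apply one neuromodulatory state to every member of a population.

    Infeasible members are dropped; the returned provenance records
    ``source_indices`` (into the input population) for member pairing and
    ``infeasible_indices`` for the flagged ones.
    """
    rows, kept, infeasible = [], [], []
    for i, g in enumerate(pop):
        out = modulate_member(pop.model, g, state, refs)
        if out is None:
            infeasible.append(i)
        else:
            rows.append(out.values)
            kept.append(i)
    return Population(
        pop.model,
        np.array(rows),
        provenance={
            **pop.provenance,
            "neuromod_state": state.label,
            "gs_target": state.gs_target,
            "modulated_pair": list(state.modulated_pair),
            "source_indices": kept,
            "infeasible_indices": infeasible,
        },
    )


def neuromod_path(
    model: ModelSpec,
    neuron: ConductanceVector,
    schedule: Sequence[float],
    pair: tuple[str, str],
    neuron_id: int = 0,
    refs: TimescaleRefs | None = None,
) -> NeuromodPath:
    """Trace a continuous neuromodulatory path over a monotone gs schedule."""
    sched = np.asarray(schedule, dtype=float)
    d = np.diff(sched)
    if sched.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("schedule of gs targets must be monotone")
    vals = np.full((sched.size, 2), np.nan)
    feas = np.zeros(sched.size, dtype=bool)
    for k, gs in enumerate(sched):
        st = NeuromodState(label="custom", gs_target=float(gs), modulated_pair=pair)
        out = modulate_member(model, neuron, st, refs)
        if out is None:
            break  # truncated path; remaining steps stay infeasible
        vals[k] = [out[pair[0]], out[pair[1]]]
        feas[k] = True
    return NeuromodPath(
        neuron_id=neuron_id, gs_targets=sched, pair=pair,
        pair_values=vals, feasible=feas,
    )


@dataclass
class RuleFit:
    """Best-fit direct neuromodulation rule between two paired populations."""

    rule: str  # multiplicative | additive | mixed
    alpha: dict[str, float]  # per-channel gain (multiplicative fit)
    beta: dict[str, float]  # per-channel offset (additive fit)
    residual_multiplicative: float
    residual_additive: float


def classify_rule(
    pop_before: Population,
    pop_after: Population,
    pair: Sequence[str],
    mixed_threshold: float = 0.05,
) -> RuleFit:
    """Fit g_mod = alpha*g_init and g_mod = g_init + beta per channel.

    Populations must be paired member-by-member (``source_indices`` from
    :func:`modulate_population` is honoured).  Reports both fits' relative
    residuals and the rule with the smaller one ("mixed" when neither fits
    within ``mixed_threshold``).
    """
    src = pop_after.provenance.get("source_indices")
    if src is not None:
        before = pop_before.matrix[np.asarray(src, dtype=int)]
    elif len(pop_before) == len(pop_after):
        before = pop_before.matrix
    else:
        raise ValueError("populations are not paired")
    after = pop_after.matrix
    alpha, beta = {}, {}
    res_m = res_a = 0.0
    norm = 0.0
    for nm in pair:
        j = pop_before.model.index(nm)
        b, a = before[:, j], after[:, j]
        al = float(a @ b / (b @ b)) if b @ b > 0 else 1.0
        be = float(np.mean(a - b))
        alpha[nm], beta[nm] = al, be
        res_m += float(np.sum((a - al * b) ** 2))
        res_a += float(np.sum((a - b - be) ** 2))
        norm += float(np.sum(a**2))
    res_m = np.sqrt(res_m / norm) if norm else 0.0
    res_a = np.sqrt(res_a / norm) if norm else 0.0
    if min(res_m, res_a) > mixed_threshold:
        rule = "mixed"
    else:
        rule = "multiplicative" if res_m <= res_a else "additive"
    return RuleFit(rule=rule, alpha=alpha, beta=beta,
                   residual_multiplicative=res_m, residual_additive=res_a)
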