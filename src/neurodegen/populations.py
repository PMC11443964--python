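"""Degenerate-population generators.

Three ways to build a set of conductance vectors sharing a firing phenotype:

* :func:`sample_random_population` -- uniform sampling in a conductance box
  followed by simulation-based post-processing on firing metrics;
* :func:`generate_dic_population` -- the fast constructive alternative:
  draw gleak uniformly, draw N-4 voltage-gated conductances uniformly with
  amplitudes proportional to gleak, then solve the three remaining
  conductances (one per timescale) from the linear system S(V_th).gbar =
  targets, so every member shares the same DIC values at threshold;
* :func:`scaling_only_subset` / :func:`ratio_only_subset` -- the two
  separated-variability subsets: variability purely in gleak (homogeneous
  scaling: every member is a scalar multiple of a base neuron) or purely in
  voltage-gated conductance ratios at fixed gleak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .dic import DICTargets, compensate
from .metrics import BURSTING, TONIC, FiringMetrics, firing_metrics
from .modelspec import ConductanceVector, ModelSpec
from .simulate import SimulationError, simulate

__all__ = [
    "SamplingRanges",
    "AcceptanceCriteria",
    "Population",
    "GenerationError",
    "sample_random_population",
    "generate_dic_population",
    "scaling_only_subset",
    "ratio_only_subset",
    "spot_validate",
]


class GenerationError(RuntimeError):
    """A generator exhausted its candidate budget; carries diagnostics."""


@dataclass(frozen=True)
class SamplingRanges:
    """Uniform sampling box: (low, high) in mS/cm^2 per conductance."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if not 0 <= lo < hi:
                raise ValueError(f"bad range for {name}: ({lo}, {hi})")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.ranges[name]

    def validate_for(self, model: ModelSpec):
        missing = set(model.channel_names) - set(self.ranges)
        if missing:
            raise ValueError(f"ranges missing conductances: {sorted(missing)}")

    def draw(self, rng: np.random.Generator, name: str) -> float:
        lo, hi = self.ranges[name]
        return float(rng.uniform(lo, hi))

    def mean(self, name: str) -> float:
        lo, hi = self.ranges[name]
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class AcceptanceCriteria:
    """Post-processing windows on firing metrics (all configurable)."""

    pattern: str  # "bursting" or "tonic"
    peak_V_min: float = 0.0
    peak_V_max: float | None = None
    hyperpol_V_max: float = -50.0
    hyperpol_V_min: float | None = None
    spikes_per_burst: tuple[float, float] | None = None
    interburst_freq: tuple[float, float] | None = None  # Hz
    intraburst_freq: tuple[float, float] | None = None  # Hz
    burstiness_min: float | None = None
    spike_freq: tuple[float, float] | None = None  # Hz (tonic)
    duration: float = 10_000.0
    transient: float = 2_000.0

    def failures(self, fm: FiringMetrics) -> list[str]:
        """Names of violated criteria (empty list = accepted)."""
        bad = []
        if fm.pattern != self.pattern:
            bad.append(f"pattern={fm.pattern}")
            return bad
        if fm.peak_V < self.peak_V_min:
            bad.append("peak_V")
        if self.peak_V_max is not None and fm.peak_V > self.peak_V_max:
            bad.append("peak_V")
        if fm.hyperpol_V > self.hyperpol_V_max:
            bad.append("hyperpol_V")
        if self.hyperpol_V_min is not None and fm.hyperpol_V < self.hyperpol_V_min:
            bad.append("hyperpol_V")
        if self.spikes_per_burst is not None and not (
            self.spikes_per_burst[0] <= fm.spikes_per_burst <= self.spikes_per_burst[1]
        ):
            bad.append("spikes_per_burst")
        if self.interburst_freq is not None and not (
            self.interburst_freq[0] <= fm.interburst_freq <= self.interburst_freq[1]
        ):
            bad.append("interburst_freq")
        if self.intraburst_freq is not None and not (
            self.intraburst_freq[0] <= fm.intraburst_freq <= self.intraburst_freq[1]
        ):
            bad.append("intraburst_freq")
        if self.burstiness_min is not None and fm.burstiness < self.burstiness_min:
            bad.append("burstiness")
        if self.spike_freq is not None and not (
            self.spike_freq[0] <= fm.spike_freq <= self.spike_freq[1]
        ):
            bad.append("spike_freq")
        return bad


@dataclass
class Population:
    """Ordered collection of conductance vectors from one model."""

    model: ModelSpec
    matrix: np.ndarray  # n x N, columns in model channel order (leak last)
    provenance: dict = field(default_factory=dict)
    labels: list[FiringMetrics] | None = None

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != self.model.N:
            raise ValueError(
                f"population matrix has {self.matrix.shape[1]} columns, "
                f"model {self.model.name} needs {self.model.N}"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def __iter__(self) -> Iterator[ConductanceVector]:
        for row in self.matrix:
            yield ConductanceVector(self.model, row)

    def member(self, i: int) -> ConductanceVector:
        return ConductanceVector(self.model, self.matrix[i])

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.model.index(name)]

    def pair(self, names: Sequence[str]) -> np.ndarray:
        return self.matrix[:, [self.model.index(n) for n in names]]

    def with_matrix(self, matrix: np.ndarray, **prov) -> "Population":
        return Population(self.model, matrix, {**self.provenance, **prov})


def sample_random_population(
    model: ModelSpec,
    ranges: SamplingRanges,
    criteria: AcceptanceCriteria,
    n: int,
    seed: int,
    candidate_budget: int | None = None,
) -> Population:
    """Uniform random sampling with simulation-based post-processing.

    Draws candidates uniformly in the box, simulates each, keeps those whose
    firing metrics satisfy ``criteria``, until ``n`` members are accepted.
    Raises :class:`GenerationError` with a summary of the nearest-miss
    criteria if the candidate budget is exhausted first.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    ranges.validate_for(model)
    budget = candidate_budget if candidate_budget is not None else 100 * n
    rng = np.random.default_rng(seed)
    names = model.channel_names
    accepted: list[np.ndarray] = []
    labels: list[FiringMetrics] = []
    fail_counts: dict[str, int] = {}
    tried = 0
    while len(accepted) < n and tried < budget:
        tried += 1
        vals = np.array([ranges.draw(rng, nm) for nm in names])
        g = ConductanceVector(model, vals)
        try:
            tr = simulate(model, g, duration=criteria.duration,
                          transient=criteria.transient)
        except SimulationError:
            fail_counts["diverged"] = fail_counts.get("diverged", 0) + 1
            continue
        fm = firing_metrics(tr)
        bad = criteria.failures(fm)
        if bad:
            for b in bad:
                fail_counts[b] = fail_counts.get(b, 0) + 1
            continue
        accepted.append(vals)
        labels.append(fm)
    if len(accepted) < n:
        raise GenerationError(
            f"accepted only {len(accepted)}/{n} after {tried} candidates; "
            f"failure summary: {dict(sorted(fail_counts.items(), key=lambda kv: -kv[1]))}"
        )
    pop = Population(
        model,
        np.array(accepted),
        provenance={
            "generator": "random_sampling",
            "seed": seed,
            "n": n,
            "candidates": tried,
            "acceptance_rate": n / tried,
            "criteria": criteria.pattern,
        },
        labels=labels,
    )
    return pop


def _free_channels(model: ModelSpec, solve_channels: Sequence[str]) -> list[str]:
    return [
        nm for nm in model.channel_names[:-1] if nm not in solve_channels
    ]


def _dic_member(
    model: ModelSpec,
    rng: np.random.Generator,
    ranges: SamplingRanges,
    targets: DICTargets,
    solve_channels: Sequence[str],
    gleak: float,
    free_values: dict[str, float] | None,
) -> np.ndarray | None:
    """One candidate: proportional free draw + compensation solve."""
    scale = gleak / ranges.mean("leak")
    vals = np.zeros(model.N)
    vals[-1] = gleak
    for nm in _free_channels(model, solve_channels):
        u = free_values[nm] if free_values is not None else ranges.draw(rng, nm)
        vals[model.index(nm)] = scale * u
    for nm in solve_channels:  # initial guesses for the solve
        vals[model.index(nm)] = scale * ranges.mean(nm)
    sol = compensate(model, ConductanceVector(model, vals), list(solve_channels), targets)
    return None if sol is None else sol.values


def generate_dic_population(
    model: ModelSpec,
    targets: DICTargets,
    n: int,
    seed: int,
    ranges: SamplingRanges,
    solve_channels: Sequence[str],
    max_reject_rate: float = 0.95,
) -> Population:
    """DIC-constrained generation with gleak-proportional sampling.

    Per member: gleak ~ U(leak range); the free voltage-gated conductances
    are drawn uniformly and multiplied by gleak / mean(leak range); the
    three ``solve_channels`` (one per timescale) come from the linear
    system S(V_th).gbar = targets.  Candidates whose solve fails or goes
    negative are rejected and resampled.
    """
    ranges.validate_for(model)
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    tried = 0
    while len(rows) < n:
        tried += 1
        if tried >= 50 and len(rows) < (1 - max_reject_rate) * tried:
            raise GenerationError(
                f"rejection rate {1 - len(rows)/tried:.2f} exceeds ceiling; "
                f"try different solve_channels or ranges"
            )
        gleak = ranges.draw(rng, "leak")
        row = _dic_member(model, rng, ranges, targets, solve_channels, gleak, None)
        if row is not None:
            rows.append(row)
    return Population(
        model,
        np.array(rows),
        provenance={
            "generator": "dic_constrained",
            "seed": seed,
            "n": n,
            "candidates": tried,
            "targets": {"V_th": targets.V_th, "gf": targets.gf,
                        "gs": targets.gs, "gu": targets.gu},
            "solve_channels": list(solve_channels),
        },
    )


def scaling_only_subset(
    model: ModelSpec,
    targets: DICTargets,
    n: int,
    seed: int,
    ranges: SamplingRanges,
    solve_channels: Sequence[str],
    base_free_values: dict[str, float] | None = None,
) -> Population:
    """Homogeneous-scaling subset: variability solely in gleak.

    A single base neuron is built at the reference leak conductance (shared
    deterministic free values; solved channels from the DIC system), then
    each member is that neuron homogeneously scaled by its own randomly
    drawn gleak.  All members are therefore exactly proportional -- points
    on one ray through the origin of the conductance space.
    """
    ranges.validate_for(model)
    rng = np.random.default_rng(seed)
    gleak_ref = ranges.mean("leak")
    if base_free_values is not None:
        base = _dic_member(
            model, rng, ranges, targets, solve_channels, gleak_ref, base_free_values
        )
    else:
        # range midpoints first, then seeded random draws until feasible
        mid = {nm: ranges.mean(nm) for nm in _free_channels(model, solve_channels)}
        base = _dic_member(model, rng, ranges, targets, solve_channels, gleak_ref, mid)
        tries = 0
        while base is None and tries < 200:
            tries += 1
            base = _dic_member(model, rng, ranges, targets, solve_channels,
                               gleak_ref, None)
    if base is None:
        raise GenerationError("base neuron solve failed; adjust targets or ranges")
    lo, hi = ranges["leak"]
    gleaks = rng.uniform(lo, hi, size=n)
    rows = np.array([base * (gl / gleak_ref) for gl in gleaks])
    return Population(
        model,
        rows,
        provenance={
            "generator": "scaling_only",
            "seed": seed,
            "n": n,
            "targets": {"V_th": targets.V_th, "gf": targets.gf,
                        "gs": targets.gs, "gu": targets.gu},
            "solve_channels": list(solve_channels),
        },
    )


def ratio_only_subset(
    model: ModelSpec,
    targets: DICTargets,
    n: int,
    seed: int,
    ranges: SamplingRanges,
    solve_channels: Sequence[str],
    gleak_fixed: float | None = None,
) -> Population:
    """Conductance-ratio subset: fixed gleak, random voltage-gated ratios.

    Every member shares one leak conductance; the free voltage-gated
    conductances vary, and the solved channels absorb the variation so all
    members keep the target DIC values -- variability along DIC
    zero-sensitivity directions only.
    """
    ranges.validate_for(model)
    rng = np.random.default_rng(seed)
    gleak = gleak_fixed if gleak_fixed is not None else ranges.mean("leak")
    rows: list[np.ndarray] = []
    tried = 0
    while len(rows) < n:
        tried += 1
        if tried > 50 and len(rows) < 0.05 * tried:
            raise GenerationError("rejection rate too high in ratio_only_subset")
        row = _dic_member(model, rng, ranges, targets, solve_channels, gleak, None)
        if row is not None:
            rows.append(row)
    return Population(
        model,
        np.array(rows),
        provenance={
            "generator": "ratio_only",
            "seed": seed,
            "n": n,
            "gleak": gleak,
            "targets": {"V_th": targets.V_th, "gf": targets.gf,
                        "gs": targets.gs, "gu": targets.gu},
            "solve_channels": list(solve_channels),
        },
    )


def spot_validate(
    pop: Population,
    criteria: AcceptanceCriteria,
    fraction: float = 0.1,
    seed: int = 0,
) -> float:
    """Simulate a random subset of members; return the fraction passing
    the same firing-metric acceptance used for random sampling."""
    rng = np.random.default_rng(seed)
    k = max(1, int(round(fraction * len(pop))))
    idx = rng.choice(len(pop), size=k, replace=False)
    ok = 0
    for i in idx:
        try:
            tr = simulate(pop.model, pop.member(int(i)),
                          duration=criteria.duration, transient=criteria.transient)
        except SimulationError:
            continue
        if not criteria.failures(firing_metrics(tr)):
            ok += 1
    return ok / k
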