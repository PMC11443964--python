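"""Firing-pattern metrics: spike detection, burst segmentation, burstiness.

Spikes are upward crossings of a reference voltage (0 mV by default) with a
short refractory minimum.  Bursts are groups of spikes separated by
interspike intervals longer than ``burst_gap_factor`` times the median ISI.
Burstiness is 1 - (number of bursts)/(number of spikes): 0 for a regular
tonic train (every spike its own burst), approaching 1 for long bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import VoltageTrace

__all__ = ["FiringMetrics", "firing_metrics", "detect_spikes"]

SILENT = "silent"
TONIC = "tonic"
BURSTING = "bursting"
IRREGULAR = "irregular"


@dataclass
class FiringMetrics:
    """Summary of one voltage trace's firing pattern."""

    pattern: str
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_V: float = np.nan
    hyperpol_V: float = np.nan
    spike_freq: float = 0.0  # Hz, spikes over the whole trace
    intraburst_freq: float = np.nan  # Hz (bursting only)
    interburst_freq: float = np.nan  # Hz, burst start-to-start rate
    spikes_per_burst: float = 0.0
    burstiness: float = 0.0
    n_spikes: int = 0


def detect_spikes(
    t: np.ndarray, V: np.ndarray, threshold: float = 0.0, refractory: float = 2.0
) -> np.ndarray:
    """Times of upward threshold crossings, at least ``refractory`` ms apart."""
    above = V >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if idx.size == 0:
        return np.empty(0)
    times = t[idx]
    kept = [times[0]]
    for ti in times[1:]:
        if ti - kept[-1] >= refractory:
            kept.append(ti)
    return np.asarray(kept)


def firing_metrics(
    trace: VoltageTrace,
    spike_threshold: float = 0.0,
    burst_gap_factor: float = 3.0,
    refractory: float = 2.0,
    tonic_cv_max: float = 0.3,
) -> FiringMetrics:
    """Classify a trace as silent/tonic/bursting/irregular with burst metrics.

    Deterministic given the trace and parameters.  Silent traces yield
    pattern="silent" with an empty spike list.
    """
    t, V = trace.t, trace.V
    duration = t[-1] - t[0]
    peak = float(np.max(V))
    hyper = float(np.min(V))
    spikes = detect_spikes(t, V, spike_threshold, refractory)
    n = spikes.size
    if n == 0:
        return FiringMetrics(pattern=SILENT, peak_V=peak, hyperpol_V=hyper)
    freq = 1000.0 * n / duration
    base = dict(
        spike_times=spikes, peak_V=peak, hyperpol_V=hyper, spike_freq=freq, n_spikes=n
    )
    if n < 3:
        return FiringMetrics(pattern=IRREGULAR, spikes_per_burst=1.0, **base)
    isi = np.diff(spikes)
    med = float(np.median(isi))
    if duration < 5 * med:
        warnings.warn("trace shorter than ~5 estimated periods; metrics may be biased")
    long_gap = isi > burst_gap_factor * med
    n_bursts = int(np.count_nonzero(long_gap)) + 1
    cv = float(np.std(isi) / np.mean(isi))
    if n_bursts == 1:
        # no grouping structure at this gap factor: a continuous train
        pattern = TONIC if cv <= tonic_cv_max else IRREGULAR
        return FiringMetrics(pattern=pattern, spikes_per_burst=1.0, burstiness=0.0, **base)
    starts = np.concatenate([[0], np.flatnonzero(long_gap) + 1])
    ends = np.concatenate([np.flatnonzero(long_gap), [n - 1]])
    sizes = ends - starts + 1
    spb = float(np.mean(sizes))
    intra = np.concatenate(
        [isi[s:e] for s, e in zip(starts, ends) if e > s]
    )
    intraburst = 1000.0 / float(np.mean(intra)) if intra.size else np.nan
    burst_starts = spikes[starts]
    interburst = (
        1000.0 / float(np.mean(np.diff(burst_starts))) if n_bursts >= 2 else np.nan
    )
    burstiness = max(0.0, 1.0 - n_bursts / n)
    if spb >= 2.0 and (np.isnan(interburst) or interburst < intraburst):
        pattern = BURSTING
    elif cv <= tonic_cv_max:
        pattern = TONIC
    else:
        pattern = IRREGULAR
    return FiringMetrics(
        pattern=pattern,
        spikes_per_burst=spb,
        burstiness=burstiness,
        intraburst_freq=intraburst,
        interburst_freq=interburst,
        **base,
    )
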