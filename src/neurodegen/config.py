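"""Per-model experiment configuration: ranges, acceptance windows, targets.

Defaults ship as YAML files under ``configdefs/`` and can be overridden by
user files of the same schema.  Everything the generators and the
neuromodulation rule need -- sampling boxes, firing-pattern acceptance
windows, DIC targets, solve channels, modulated pairs, calibrated
slow-DIC state values -- lives here rather than in code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .dic import DICTargets
from .neuromod import NeuromodState
from .populations import AcceptanceCriteria, SamplingRanges

__all__ = ["ModelConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class ModelConfig:
    """Parsed configuration for one model's experiments."""

    model_name: str
    sampling_ranges: SamplingRanges
    acceptance: AcceptanceCriteria
    generator_ranges: SamplingRanges
    solve_channels: tuple[str, str, str]
    dic_targets: DICTargets
    modulated_pair: tuple[str, str]
    gs_states: dict[str, float]
    V_ref: float
    correlation_threshold: float | None
    sim_duration: float
    sim_transient: float
    raw: dict

    def state(self, label: str, gu_target: float | None = None) -> NeuromodState:
        """A named neuromodulatory state (spiking / light_bursting / ...)."""
        if label not in self.gs_states:
            raise KeyError(
                f"unknown state {label!r}; configured: {sorted(self.gs_states)}"
            )
        return NeuromodState(
            label=label,
            gs_target=self.gs_states[label],
            modulated_pair=self.modulated_pair,
            gu_target=gu_target,
        )


def _ranges(d: dict) -> SamplingRanges:
    return SamplingRanges({k: (float(v[0]), float(v[1])) for k, v in d.items()})


def _criteria(d: dict) -> AcceptanceCriteria:
    def pair(key):
        v = d.get(key)
        return None if v is None else (float(v[0]), float(v[1]))

    def opt(key):
        return None if d.get(key) is None else float(d[key])

    return AcceptanceCriteria(
        pattern=str(d["pattern"]),
        peak_V_min=float(d.get("peak_V_min", 0.0)),
        peak_V_max=opt("peak_V_max"),
        hyperpol_V_max=float(d.get("hyperpol_V_max", -50.0)),
        hyperpol_V_min=opt("hyperpol_V_min"),
        spikes_per_burst=pair("spikes_per_burst"),
        interburst_freq=pair("interburst_freq"),
        intraburst_freq=pair("intraburst_freq"),
        burstiness_min=(
            None if d.get("burstiness_min") is None else float(d["burstiness_min"])
        ),
        spike_freq=pair("spike_freq"),
        duration=float(d.get("duration", 10_000.0)),
        transient=float(d.get("transient", 2_000.0)),
    )


def load_config(path: str | Path) -> ModelConfig:
    """Parse a configuration YAML file into a :class:`ModelConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        gen = raw["dic_generator"]
        tg = gen["targets"]
        ana = raw.get("analysis", {})
        return ModelConfig(
            model_name=str(raw["model"]),
            sampling_ranges=_ranges(raw["sampling_ranges"]),
            acceptance=_criteria(raw["acceptance"]),
            generator_ranges=_ranges(gen["free_ranges"]),
            solve_channels=tuple(gen["solve_channels"]),
            dic_targets=DICTargets(
                V_th=float(tg["V_th"]),
                gs=float(tg["gs"]),
                gu=float(tg["gu"]),
                gf=float(tg.get("gf", 0.0)),
            ),
            modulated_pair=tuple(raw["neuromodulation"]["modulated_pair"]),
            gs_states={
                k: float(v) for k, v in raw["neuromodulation"]["gs_states"].items()
            },
            V_ref=float(ana.get("V_ref", -70.0)),
            correlation_threshold=(
                None
                if ana.get("correlation_threshold") is None
                else float(ana["correlation_threshold"])
            ),
            sim_duration=float(ana.get("sim_duration", 10_000.0)),
            sim_transient=float(ana.get("sim_transient", 2_000.0)),
            raw=raw,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed configuration {path}: {exc}") from exc


def default_config(model_name: str) -> ModelConfig:
    """The shipped configuration for "STG" or "DA"."""
    fname = {"STG": "stg.yaml", "DA": "da.yaml"}.get(model_name)
    if fname is None:
        raise ValueError(f"no default configuration for model {model_name!r}")
    ref = resources.files("neurodegen.configdefs") / fname
    with resources.as_file(ref) as path:
        return load_config(path)
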