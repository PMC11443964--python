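"""Persistence, experiment configs and the pipeline driver.

Populations round-trip through CSV (full float precision, provenance in a
JSON header comment).  ``run_experiment`` chains generate -> analyze ->
(optionally) modulate from a single serialisable experiment description,
writing populations, a JSON report and a text log, all stamped with the
config hash and seeds so any artifact can be regenerated bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis as _an
from .config import ModelConfig, default_config, load_config
from .modelspec import ModelSpec, build_model
from .neuromod import modulate_population
from .populations import (
    Population,
    generate_dic_population,
    ratio_only_subset,
    sample_random_population,
    scaling_only_subset,
)

__all__ = [
    "write_population",
    "read_population",
    "write_trace",
    "ExperimentConfig",
    "run_experiment",
]

_MAGIC = "# neurodegen-population v1"


def write_population(pop: Population, path: str | Path) -> None:
    """CSV with a provenance header; floats at full repr precision."""
    path = Path(path)
    names = pop.model.channel_names
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"# model: {pop.model.name}\n")
        fh.write("# provenance: " + json.dumps(pop.provenance, sort_keys=True) + "\n")
        fh.write(",".join(names) + "\n")
        for row in pop.matrix:
            fh.write(",".join(repr(float(x)) for x in row) + "\n")


def read_population(path: str | Path, model: ModelSpec | None = None) -> Population:
    """Parse a population CSV written by :func:`write_population`.

    Also accepts a plain CSV whose header row names the conductances, as
    long as a ``model`` is supplied.  Column sets must match the model's
    conductance space exactly (any order; stored in model order).
    """
    path = Path(path)
    provenance: dict = {}
    model_name = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            if line.startswith("# model:"):
                model_name = line.split(":", 1)[1].strip()
            elif line.startswith("# provenance:"):
                provenance = json.loads(line.split(":", 1)[1])
    if model is None:
        if model_name is None:
            raise ValueError(f"{path}: no model header and no model given")
        model = build_model(model_name)
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    expected = set(model.channel_names)
    got = set(df.columns)
    if expected != got:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValueError(
            f"{path}: column mismatch for model {model.name}: "
            f"missing {missing}, unexpected {extra}"
        )
    return Population(model, df[model.channel_names].to_numpy(), provenance)


def write_trace(trace, path: str | Path) -> None:
    """Delimited text trace: columns t, V, Iext (+ auxiliary states)."""
    cols = {"t": trace.t, "V": trace.V, "Iext": trace.Iext}
    for k, v in trace.aux.items():
        cols[k] = v
    pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class ExperimentConfig:
    """One pipeline run: generate a population, analyse it, modulate it."""

    model: str  # "STG" or "DA"
    method: str = "dic"  # random | dic | scaling_only | ratio_only
    n: int = 100
    seed: int = 0
    modulate_states: list[str] = field(default_factory=list)
    center_pca: bool = True
    out_dir: str = "results"
    config_file: str | None = None  # None -> shipped per-model defaults

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def model_config(self) -> ModelConfig:
        if self.config_file:
            return load_config(self.config_file)
        return default_config(self.model)


def _generate(cfg: ExperimentConfig, mc: ModelConfig, model) -> Population:
    if cfg.method == "random":
        return sample_random_population(
            model, mc.sampling_ranges, mc.acceptance, cfg.n, cfg.seed
        )
    if cfg.method == "dic":
        return generate_dic_population(
            model, mc.dic_targets, cfg.n, cfg.seed, mc.generator_ranges,
            mc.solve_channels,
        )
    if cfg.method == "scaling_only":
        return scaling_only_subset(
            model, mc.dic_targets, cfg.n, cfg.seed, mc.generator_ranges,
            mc.solve_channels,
        )
    if cfg.method == "ratio_only":
        return ratio_only_subset(
            model, mc.dic_targets, cfg.n, cfg.seed, mc.generator_ranges,
            mc.solve_channels,
        )
    raise ValueError(f"unknown generation method {cfg.method!r}")


def _analysis_report(pop: Population, mc: ModelConfig, center: bool) -> dict:
    rep: dict = {}
    R = _an.pairwise_correlations(pop)
    rep["correlations"] = {
        "channels": list(R.columns),
        "r": [[None if np.isnan(x) else float(x) for x in row] for row in R.to_numpy()],
    }
    G = _an.correlation_graph(pop, mc.correlation_threshold)
    rep["graph_edges"] = [
        {"pair": [a, b], **{k: d[k] for k in ("r", "sign", "weight")}}
        for a, b, d in G.edges(data=True)
    ]
    if len(pop) > pop.model.N:
        P = _an.pca(pop, center=center)
        scal = _an.homogeneous_scaling_direction(pop, in_scale_of=P)
        rep["pca"] = {
            "variance_fraction": P.variance_fraction.tolist(),
            "loadings": P.loadings.tolist(),
            "mean": P.mean.tolist(),
        }
        rep["scaling_direction"] = scal.vector.tolist()
        rep["pc1_scaling_alignment"] = _an.alignment(P.component(0), scal)
    return rep


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute generate -> analyze -> modulate; write artifacts; return report."""
    mc = cfg.model_config()
    model = build_model(cfg.model)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.hash()
    log_lines = [f"config_hash={chash} model={cfg.model} method={cfg.method} "
                 f"n={cfg.n} seed={cfg.seed}"]
    report: dict = {"schema_version": 1, "config": asdict(cfg), "config_hash": chash}
    try:
        pop = _generate(cfg, mc, model)
    except Exception as exc:
        raise RuntimeError(f"[generate] failed (config {chash}): {exc}") from exc
    write_population(pop, out / f"pop_{cfg.model}_{cfg.method}_{chash}.csv")
    if "acceptance_rate" in pop.provenance:
        log_lines.append(f"acceptance_rate={pop.provenance['acceptance_rate']:.4f}")
    try:
        report["analysis"] = _analysis_report(pop, mc, cfg.center_pca)
    except Exception as exc:
        raise RuntimeError(f"[analyze] failed (config {chash}): {exc}") from exc
    report["modulated"] = {}
    for label in cfg.modulate_states:
        try:
            mp = modulate_population(pop, mc.state(label))
        except Exception as exc:
            raise RuntimeError(f"[modulate:{label}] failed (config {chash}): {exc}") from exc
        write_population(mp, out / f"pop_{cfg.model}_{label}_{chash}.csv")
        a, b = mc.modulated_pair
        r = float(np.corrcoef(mp.column(a), mp.column(b))[0, 1])
        report["modulated"][label] = {
            "gs_target": mc.gs_states[label],
            "pair": [a, b],
            "pearson_r": r,
            "n_kept": len(mp),
            "n_infeasible": len(mp.provenance["infeasible_indices"]),
        }
        log_lines.append(f"state={label} r({a},{b})={r:.4f} kept={len(mp)}")
    rpath = out / f"report_{cfg.model}_{cfg.method}_{chash}.json"
    with open(rpath, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out / f"log_{cfg.model}_{cfg.method}_{chash}.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report
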