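"""Configuration loading and validation (YAML or JSON).

A config file declares the optimization problem (parameters with input
domains, metrics with target ranges, the parameter -> metric dependency
mapping), the optimizer settings (``m`` table or ``auto``, maximum DFS
depth, replicates, parallel processes, seed) and the evaluator backend
(a bundled synthetic landscape or an external command).

Example::

    parameters:
      move_size: {domain: [0.05, 20.0]}
    metrics:
      acceptance: {target: [0.3, 0.6]}
    dependencies:
      move_size: [acceptance]
    optimizer:
      m: {1: 3}          # or "auto"
      max_depth: 5
      replicates: 4
      max_processes: 4
      seed: 1
    evaluator:
      type: synthetic     # or: external
      landscape: fig6a
      noise_sd: 0.05
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .evaluators import ExternalEvaluator, NoiseModel, SyntheticEvaluator
from .landscapes import random_landscape, worked_example
from .problem import DependencyGraph, Metric, Parameter, Problem, validate_problem
from .scheduler import OptimizerSettings, recommendation_warnings

__all__ = ["Config", "ConfigError", "load_config", "build_evaluator", "example_config_path"]


def example_config_path(name: str = "fig6a") -> Path:
    """Path to a bundled example config file (e.g. ``fig6a``)."""
    p = Path(__file__).parent / "data" / f"{name}.yaml"
    if not p.exists():
        raise KeyError(f"no bundled config named {name!r}")
    return p


class ConfigError(ValueError):
    """Raised with every violation found in a config, joined into one message."""


@dataclass
class Config:
    """A validated optimization configuration."""

    problem: Problem
    settings: OptimizerSettings
    evaluator_spec: dict[str, Any]
    output_dir: str = "stopt_output"
    source: str | None = None


def _as_pairs(section: Any, key_field: str) -> list[tuple[str, dict]]:
    """Accept either a mapping name -> spec or a list of specs with a name."""
    if isinstance(section, dict):
        return [(str(k), v if isinstance(v, dict) else {key_field: v}) for k, v in section.items()]
    if isinstance(section, list):
        out = []
        for item in section:
            name = item.get("name")
            out.append((str(name), item))
        return out
    raise ConfigError(f"expected a mapping or list, got {type(section).__name__}")


def load_config(path: str | Path) -> Config:
    """Parse and validate a YAML/JSON config file.

    All validation violations are collected and raised together as a
    :class:`ConfigError`.  CPU-economy recommendation violations are
    emitted as warnings, not errors.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)  # JSON is a YAML subset
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping at the top level")

    violations: list[str] = []

    parameters: list[Parameter] = []
    for name, spec in _as_pairs(raw.get("parameters", {}), "domain"):
        dom = spec.get("domain")
        if not (isinstance(dom, (list, tuple)) and len(dom) == 2):
            violations.append(f"parameter {name!r}: domain must be a [low, high] pair")
            continue
        parameters.append(Parameter(name, (float(dom[0]), float(dom[1]))))

    metrics: list[Metric] = []
    for name, spec in _as_pairs(raw.get("metrics", {}), "target"):
        tgt = spec.get("target")
        if not (isinstance(tgt, (list, tuple)) and len(tgt) == 2):
            violations.append(f"metric {name!r}: target must be a [low, high] pair")
            continue
        metrics.append(Metric(name, (float(tgt[0]), float(tgt[1]))))

    deps = raw.get("dependencies", {})
    edges = []
    if not isinstance(deps, dict):
        violations.append("dependencies must map parameter names to lists of metric names")
        deps = {}
    for pname, mnames in deps.items():
        if isinstance(mnames, str):
            mnames = [mnames]
        for mname in mnames:
            edges.append((str(pname), str(mname)))

    problem = Problem(
        parameters=parameters,
        metrics=metrics,
        graph=DependencyGraph(edges),
        name=raw.get("name", path.stem),
    )
    violations.extend(validate_problem(problem))

    opt = raw.get("optimizer", {}) or {}
    m_spec = opt.get("m", "auto")
    if m_spec == "auto" or m_spec is None:
        m_table = None
    elif isinstance(m_spec, dict):
        m_table = {int(k): int(v) for k, v in m_spec.items()}
        for n, m in m_table.items():
            if m < 2:
                violations.append(f"m({n}) = {m}: branching factor must be >= 2")
    elif isinstance(m_spec, int):
        m_table = {1: m_spec}
        if m_spec < 2:
            violations.append(f"m = {m_spec}: branching factor must be >= 2")
    else:
        violations.append("optimizer.m must be 'auto', an integer, or a {n: m} mapping")
        m_table = None

    replicates = int(opt.get("replicates", 1))
    max_processes = int(opt.get("max_processes", 1))
    max_depth = int(opt.get("max_depth", 5))
    if replicates < 1:
        violations.append("optimizer.replicates must be >= 1")
    if max_processes < 1:
        violations.append("optimizer.max_processes must be >= 1")
    if max_depth < 0:
        violations.append("optimizer.max_depth must be >= 0")

    evaluator_spec = raw.get("evaluator", {}) or {}
    etype = evaluator_spec.get("type", "synthetic")
    if etype == "synthetic":
        if "landscape" not in evaluator_spec and "random" not in evaluator_spec:
            violations.append("synthetic evaluator needs a 'landscape' name or 'random' spec")
    elif etype == "external":
        if "command" not in evaluator_spec:
            violations.append("external evaluator needs a 'command'")
    else:
        violations.append(f"unknown evaluator type {etype!r}")

    if violations:
        raise ConfigError(
            f"invalid configuration {path}:\n  - " + "\n  - ".join(violations)
        )

    settings = OptimizerSettings(
        m_table=m_table,
        max_depth=max_depth,
        replicates=replicates,
        max_processes=max_processes,
        seed=int(opt.get("seed", 0)),
    )

    # advisory CPU-economy checks, on the resolved m table
    group_sizes = [g.n for g in problem.groups()]
    resolved = settings.search_settings(group_sizes).m_table
    for msg in recommendation_warnings(resolved, group_sizes, max_processes, replicates):
        warnings.warn(msg, UserWarning, stacklevel=2)

    return Config(
        problem=problem,
        settings=settings,
        evaluator_spec=dict(evaluator_spec),
        output_dir=str(raw.get("output", "stopt_output")),
        source=str(path),
    )


def build_evaluator(config: Config):
    """Instantiate the evaluator backend a config declares."""
    spec = config.evaluator_spec
    etype = spec.get("type", "synthetic")
    if etype == "synthetic":
        if "landscape" in spec:
            land = worked_example(spec["landscape"])
        else:
            r = spec["random"]
            land = random_landscape(
                int(r.get("dimension", 2)),
                int(r.get("smoothness", 5)),
                int(r.get("seed", 0)),
            )
        sd = float(spec.get("noise_sd", land.noise_sd))
        return SyntheticEvaluator(land, NoiseModel(sd))
    command = spec["command"]
    metric_names = spec.get("metrics") or [m.name for m in config.problem.metrics]
    return ExternalEvaluator(command, metric_names, spec.get("workdir"))
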