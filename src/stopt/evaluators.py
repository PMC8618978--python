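"""Metric evaluation backends.

An *evaluator* maps a full parameter vector to one noisy replicate of
every metric.  Two backends are provided:

* :class:`SyntheticEvaluator` — an in-process landscape plus independent
  Gaussian noise per metric and replicate; used for testing, worked
  examples and benchmarks.
* :class:`ExternalEvaluator` — invokes an external command per replicate
  through a small JSON file protocol, emulating a sampling run followed
  by analysis (e.g. one MCMC run reporting acceptance rates).

Evaluators are called as ``evaluator(vector, rng_factory)`` where
``rng_factory(metric_name)`` returns the derived random stream for that
metric.  Per-metric streams keep the noise of one group's metrics
independent of what other groups exist in the problem, which is what
makes co-scheduled group searches bit-identical to isolated ones.
"""

from __future__ import annotations

import json
import math
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .landscapes import Landscape

__all__ = [
    "NoiseModel",
    "EvaluationRecord",
    "EvaluationError",
    "SyntheticEvaluator",
    "ExternalEvaluator",
    "evaluate_synthetic",
    "evaluate_external",
    "average_replicates",
    "mock_sampler_path",
]

RngFactory = Callable[[str], np.random.Generator]


class EvaluationError(RuntimeError):
    """A metric evaluation failed (bad external output, nonzero exit, ...)."""


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean Gaussian observation noise with standard deviation ``sd``.

    ``sd = 0`` means noiseless.  Averaging R replicates reduces the
    effective noise to ``sd / sqrt(R)``.
    """

    sd: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise standard deviation must be >= 0")


@dataclass
class EvaluationRecord:
    """Raw replicate values and their running average for one candidate point."""

    provenance: tuple
    replicates: dict[str, list[float]] = field(default_factory=dict)

    def add(self, values: Mapping[str, float]) -> None:
        for name, v in values.items():
            self.replicates.setdefault(name, []).append(float(v))

    def averaged(self) -> dict[str, float]:
        return average_replicates(self.replicates)


def average_replicates(replicates: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Arithmetic mean of the replicate values, per metric.

    Raises ``ValueError`` if any metric has no replicates.
    """
    out = {}
    for name, vals in replicates.items():
        if len(vals) == 0:
            raise ValueError(f"metric {name!r} has no replicate values to average")
        out[name] = float(np.mean(vals))
    if not out:
        raise ValueError("empty replicate set")
    return out


def evaluate_synthetic(
    vector: Mapping[str, float],
    landscape: Landscape,
    noise: NoiseModel = NoiseModel(0.0),
    stream: np.random.Generator | None = None,
) -> dict[str, float]:
    """One noisy replicate of every landscape metric at ``vector``.

    Noise is drawn independently per metric, in sorted metric-name order,
    from the single provided ``stream``.  With ``sd = 0`` the exact
    landscape values are returned.
    """
    base = landscape.evaluate(vector)
    if noise.sd == 0.0:
        return base
    if stream is None:
        raise ValueError("a random stream is required when noise sd > 0")
    return {name: base[name] + stream.normal(0.0, noise.sd) for name in sorted(base)}


class SyntheticEvaluator:
    """In-process landscape evaluator with per-metric Gaussian noise streams."""

    def __init__(self, landscape: Landscape, noise: NoiseModel = NoiseModel(0.0)):
        self.landscape = landscape
        self.noise = noise

    def __call__(self, vector: Mapping[str, float], rng_factory: RngFactory) -> dict[str, float]:
        base = self.landscape.evaluate(vector)
        if self.noise.sd == 0.0:
            return base
        return {
            name: value + rng_factory(name).normal(0.0, self.noise.sd)
            for name, value in base.items()
        }


def evaluate_external(
    vector: Mapping[str, float],
    command: Sequence[str] | str,
    metric_names: Iterable[str],
    workdir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, float]:
    """Run an external command for one replicate and parse its metric values.

    Protocol: the parameter vector is written to a JSON input file (one
    key per parameter, plus a reserved ``_seed`` key when a seed is
    supplied), and the command is invoked as
    ``<executable...> <input-path> <output-path>``.  The output file must
    be a JSON object with one numeric value per declared metric.  Any
    protocol violation raises :class:`EvaluationError`.
    """
    metric_names = list(metric_names)
    cmd = [command] if isinstance(command, str) else list(command)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        in_path = Path(tmp) / "input.json"
        out_path = Path(tmp) / "output.json"
        payload: dict[str, float | int] = {k: float(v) for k, v in vector.items()}
        if seed is not None:
            payload["_seed"] = int(seed)
        in_path.write_text(json.dumps(payload), encoding="utf-8")

        proc = subprocess.run(
            [*cmd, str(in_path), str(out_path)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise EvaluationError(
                f"external evaluator {cmd!r} exited with {proc.returncode}: "
                f"{proc.stderr.strip()[:500]}"
            )
        if not out_path.exists():
            raise EvaluationError(f"external evaluator {cmd!r} produced no output file")
        try:
            raw = json.loads(out_path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as e:
            raise EvaluationError(f"external evaluator output is not valid JSON: {e}") from e

    out = {}
    for name in metric_names:
        if name not in raw:
            raise EvaluationError(f"external evaluator output is missing metric {name!r}")
        v = raw[name]
        if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
            raise EvaluationError(f"metric {name!r} has non-numeric value {v!r}")
        out[name] = float(v)
    return out


class ExternalEvaluator:
    """Evaluator backend wrapping an external command (one invocation = one replicate)."""

    def __init__(
        self,
        command: Sequence[str] | str,
        metric_names: Iterable[str],
        workdir: str | Path | None = None,
    ):
        self.command = command
        self.metric_names = list(metric_names)
        self.workdir = workdir

    def __call__(self, vector: Mapping[str, float], rng_factory: RngFactory) -> dict[str, float]:
        seed = int(rng_factory("_external").integers(0, 2**31 - 1))
        return evaluate_external(vector, self.command, self.metric_names, self.workdir, seed)


def mock_sampler_path() -> Path:
    """Path to the bundled mock-sampler script.

    The script is a tiny random-walk Metropolis sampler of a standard
    normal whose single reported metric, ``acceptance``, decreases
    monotonically (in expectation) with the ``move_size`` parameter.  It
    demonstrates end-to-end tuning of an acceptance rate into a target
    range such as [0.3, 0.6] through the external-command protocol.
    """
    return Path(__file__).parent / "data" / "mock_sampler.py"
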