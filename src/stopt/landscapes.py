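"""Synthetic metric landscapes: worked one- and two-parameter examples and a
seeded random smooth-landscape generator for benchmarking.

The worked examples are simple polynomials with known target ranges whose
search traces can be computed analytically, which makes them useful both
as documentation and as exact test oracles.  The random generator
produces smooth surfaces on ``[-1, 1]^n`` rescaled to span ``[0, 1]``,
emulating the shape of acceptance-rate response surfaces (bounded,
continuous, multimodal) without claiming to reproduce any particular
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .problem import DependencyGraph, Metric, Parameter, Problem

__all__ = ["Landscape", "worked_example", "random_landscape", "WORKED_EXAMPLES"]

MetricFunction = Callable[[np.ndarray], np.ndarray]


@dataclass
class Landscape:
    """A named set of noiseless metric functions over a parameter box.

    ``functions`` maps a metric name to a vectorized callable evaluated on
    arrays of shape ``(..., n)`` where the last axis lists the parameter
    values in ``parameters`` order.  ``noise_sd`` and ``m`` are the
    recommended noise level and branching factor for demonstrations.
    """

    name: str
    parameters: tuple[Parameter, ...]
    metrics: tuple[Metric, ...]
    functions: dict[str, MetricFunction]
    noise_sd: float = 0.05
    m: int = 3

    @property
    def dimension(self) -> int:
        return len(self.parameters)

    def evaluate(self, vector: Mapping[str, float]) -> dict[str, float]:
        """Noiseless metric values at a parameter vector given as a mapping."""
        x = np.array([vector[p.name] for p in self.parameters], dtype=float)
        out = {}
        for m in self.metrics:
            v = float(np.asarray(self.functions[m.name](x)))
            if not np.isfinite(v):
                raise ValueError(f"metric {m.name!r} is not finite at {dict(vector)}")
            out[m.name] = v
        return out

    def problem(self) -> Problem:
        """Problem with the full bipartite graph (every metric depends on
        every parameter of the landscape)."""
        edges = [(p.name, m.name) for p in self.parameters for m in self.metrics]
        return Problem(
            parameters=list(self.parameters),
            metrics=list(self.metrics),
            graph=DependencyGraph(edges),
            name=self.name,
        )


def _parabola(x: np.ndarray) -> np.ndarray:
    return 1.0 - x[..., 0] ** 2


def _cubic(x: np.ndarray) -> np.ndarray:
    t = x[..., 0]
    return 1.0 - t**3 - 1.2 * t**2 + 0.5 * t


def _mean_parabola(x: np.ndarray) -> np.ndarray:
    s = (x[..., 0] + x[..., 1]) / 2.0
    return 1.0 - s**2


def _shifted_parabola(x: np.ndarray) -> np.ndarray:
    return 1.0 - (x[..., 0] - 0.5) ** 2


def _build_worked_examples() -> dict[str, Landscape]:
    dom = (-1.0, 1.0)
    band = (0.6, 0.68)
    return {
        "fig6a": Landscape(
            name="fig6a",
            parameters=(Parameter("x", dom),),
            metrics=(Metric("f", band),),
            functions={"f": _parabola},
        ),
        "fig6b": Landscape(
            name="fig6b",
            parameters=(Parameter("x", dom),),
            metrics=(Metric("f1", band), Metric("f2", band)),
            functions={"f1": _parabola, "f2": _cubic},
        ),
        "fig6c": Landscape(
            name="fig6c",
            parameters=(Parameter("x1", dom), Parameter("x2", dom)),
            metrics=(Metric("f", band),),
            functions={"f": _mean_parabola},
        ),
        "fig6d": Landscape(
            name="fig6d",
            parameters=(Parameter("x", dom),),
            metrics=(Metric("f", (0.85, 0.95)),),
            functions={"f": _shifted_parabola},
        ),
    }


WORKED_EXAMPLES = _build_worked_examples()


def worked_example(name: str) -> Landscape:
    """Return one of the bundled demonstration landscapes.

    * ``fig6a`` — one parameter, one metric: ``f(x) = 1 - x^2``, target
      ``[0.6, 0.68]``, domain ``[-1, 1]``.
    * ``fig6b`` — one parameter, two metrics: ``f1 = 1 - x^2`` and
      ``f2 = 1 - x^3 - 1.2 x^2 + 0.5 x``, both targeting ``[0.6, 0.68]``.
    * ``fig6c`` — two parameters, one metric:
      ``f = 1 - ((x1 + x2)/2)^2``, target ``[0.6, 0.68]``.
    * ``fig6d`` — one parameter, one metric: ``f = 1 - (x - 0.5)^2`` with
      an unreachable-by-flanking target ``[0.85, 0.95]`` (both root grid
      segments lie entirely below the band, so the search fails).

    All use recommended noise sd 0.05 and branching factor m = 3.
    """
    try:
        return WORKED_EXAMPLES[name]
    except KeyError:
        raise KeyError(
            f"unknown worked example {name!r}; available: {sorted(WORKED_EXAMPLES)}"
        ) from None


def random_landscape(
    dimension: int,
    smoothness: int = 5,
    seed: int = 0,
    target: tuple[float, float] = (0.3, 0.6),
) -> Landscape:
    """Seeded random smooth landscape on ``[-1, 1]^dimension``, rescaled to [0, 1].

    The surface is a sum of ``smoothness`` (h) Gaussian radial bumps with
    random centers in the box, widths drawn uniformly from [0.3, 0.9] and
    signed amplitudes with magnitude in [0.5, 1].  The sum is affinely
    rescaled so its minimum over a dense probe grid is 0 and its maximum
    is 1; the rescaled surface therefore crosses any target band inside
    (0, 1), which guarantees a desired range exists.  ``h = 1`` yields a
    unimodal surface.  Deterministic per ``(dimension, smoothness, seed)``.
    """
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    if smoothness < 1:
        raise ValueError("smoothness (number of bumps) must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([0x1A5D, dimension, smoothness, int(seed)]))
    centers = rng.uniform(-1.0, 1.0, size=(smoothness, dimension))
    widths = rng.uniform(0.3, 0.9, size=smoothness)
    amps = rng.uniform(0.5, 1.0, size=smoothness) * rng.choice([-1.0, 1.0], size=smoothness)

    def raw(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d2 = ((x[..., None, :] - centers) ** 2).sum(axis=-1)  # (..., h)
        return (amps * np.exp(-d2 / (2.0 * widths**2))).sum(axis=-1)

    # Probe the surface densely to fix the affine rescaling to [0, 1].
    if dimension <= 2:
        axes = [np.linspace(-1.0, 1.0, 201)] * dimension
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        probe = mesh.reshape(-1, dimension)
    else:
        probe = rng.uniform(-1.0, 1.0, size=(4096, dimension))
    vals = raw(probe)
    lo, hi = float(vals.min()), float(vals.max())
    span = hi - lo if hi > lo else 1.0

    def f(x: np.ndarray) -> np.ndarray:
        return (raw(x) - lo) / span

    name = f"rand{dimension}d-h{smoothness}-s{seed}"
    params = tuple(
        Parameter(f"x{i + 1}", (-1.0, 1.0)) for i in range(dimension)
    )
    return Landscape(
        name=name,
        parameters=params,
        metrics=(Metric("f", target),),
        functions={"f": f},
        noise_sd=0.05,
        m=5,
    )
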