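import numpy as np
import pytest

from stopt.landscapes import Landscape
from stopt.problem import DependencyGraph, Metric, Parameter, Problem


@pytest.fixture
def docking_problem() -> Problem:
    """Protein-docking example: rigid-body rotation/translation drive the two
    rigid-body acceptance metrics, flexible-bead translation drives the
    flexible-bead acceptance metric."""
    return Problem(
        parameters=[
            Parameter("RBRot", (0.01, 1.0)),
            Parameter("RBTrans", (0.01, 10.0)),
            Parameter("FBTrans", (0.01, 10.0)),
        ],
        metrics=[
            Metric("RB-A", (0.3, 0.6)),
            Metric("RB-B", (0.3, 0.6)),
            Metric("FB-AB", (0.3, 0.6)),
        ],
        graph=DependencyGraph(
            [
                ("RBRot", "RB-A"),
                ("RBRot", "RB-B"),
                ("RBTrans", "RB-A"),
                ("RBTrans", "RB-B"),
                ("FBTrans", "FB-AB"),
            ]
        ),
        name="docking",
    )


def linear_landscape(target=(0.45, 0.55), domain=(0.0, 1.0)) -> Landscape:
    """f(x) = x: the simplest monotone landscape."""
    return Landscape(
        name="linear",
        parameters=(Parameter("x", domain),),
        metrics=(Metric("f", target),),
        functions={"f": lambda x: x[..., 0]},
        noise_sd=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
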