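#!/usr/bin/env python
"""Mock sampling run for the external-evaluator protocol.

A random-walk Metropolis sampler of a standard normal distribution.
Reads a JSON input file with a ``move_size`` parameter (and an optional
reserved ``_seed`` key), runs a short chain proposing uniform steps in
``[-move_size, move_size]``, and writes a JSON output file with one
metric, ``acceptance`` — the fraction of proposals accepted.  Acceptance
decreases monotonically (in expectation) as the move size grows, the
typical response a move-size tuner faces.

Usage: mock_sampler.py <input.json> <output.json>

Intentionally stdlib-only so it can run as a bare subprocess.
"""

import json
import math
import random
import sys

N_STEPS = 3000


def main() -> int:
    in_path, out_path = sys.argv[1], sys.argv[2]
    with open(in_path, encoding="utf-8") as fh:
        params = json.load(fh)
    move_size = float(params["move_size"])
    rng = random.Random(int(params.get("_seed", 0)))

    x = 0.0
    accepted = 0
    for _ in range(N_STEPS):
        prop = x + rng.uniform(-move_size, move_size)
        log_alpha = 0.5 * (x * x - prop * prop)
        if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
            x = prop
            accepted += 1

    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump({"acceptance": accepted / N_STEPS}, fh)
    return 0


if __name__ == "__main__":
    sys.exit(main())
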