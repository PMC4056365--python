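"""Seed-derivation helpers.

A single root seed is carried through the pipeline; every stochastic
operation derives its own child stream from (root seed, operation code) so
that adding or reordering stages never perturbs the draws of another stage.
"""

from __future__ import annotations

import numpy as np

# stable operation codes; never renumber
_OP_CODES = {
    "kinetics": 1,
    "decay_timecourse": 2,
    "labeling": 3,
    "genome": 4,
    "regulators": 5,
    "ortholog_shuffle": 6,
    "expression_profiles": 7,
    "bootstrap": 8,
}


def child_rng(seed: int, operation: str) -> np.random.Generator:
    """Return a Generator for ``operation`` derived from the root ``seed``."""
    try:
        code = _OP_CODES[operation]
    except KeyError:
        raise ValueError(
            f"unknown operation {operation!r}; known: {sorted(_OP_CODES)}"
        ) from None
    return np.random.default_rng(np.random.SeedSequence([int(seed), code]))
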