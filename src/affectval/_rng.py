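"""Seed plumbing: one master seed spawns an independent stream per stage.

Using :class:`numpy.random.SeedSequence` children keeps the stages decoupled —
changing the number of bootstrap draws in one stage cannot perturb another
stage's random numbers.
"""

from __future__ import annotations

import numpy as np

# Fixed stage order; appending new stages keeps existing streams stable.
STAGE_NAMES = (
    "cohort",
    "continuous",
    "fuzzy",
    "mcs",
    "discrete",
    "inferential",
)


def spawn_streams(seed: int, names: tuple[str, ...] = STAGE_NAMES) -> dict[str, np.random.Generator]:
    """Return ``{name: Generator}`` with one independent child stream each."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}
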