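"""Deterministic per-stage random substreams.

One user-facing integer seed expands into independent generators for each
named pipeline stage, so re-running a single stage reproduces its output
regardless of what ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """SeedSequence for a named stage, stable across platforms and runs."""
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator seeded from the global seed and a stage label."""
    return np.random.default_rng(stage_seed(seed, stage))
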