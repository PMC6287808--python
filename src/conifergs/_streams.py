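"""Deterministic per-stage random streams.

All randomness in the package flows from one master seed. Each pipeline
stage (burn-in, trait sampling, phenotyping, MCMC, ...) draws from its own
named stream so that adding a stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(master_seed: int, stage: str, replicate: int = 0) -> int:
    """Derive a stable 31-bit seed for a named stage.

    The stage name is hashed with CRC-32 so the mapping is reproducible
    across sessions and platforms (unlike Python's salted ``hash``).
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(zlib.crc32(stage.encode()), int(replicate))
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stage_rng(master_seed: int, stage: str, replicate: int = 0) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for a named stage."""
    return np.random.default_rng(stage_seed(master_seed, stage, replicate))
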