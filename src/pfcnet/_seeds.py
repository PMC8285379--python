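"""Deterministic fan-out of a master seed into per-stage seeds."""

from __future__ import annotations

import zlib

_MOD = 2**31


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible, stage-specific seed below 2**31.

    Uses a CRC32 of the stage name mixed with the master seed so each pipeline
    stage is independently reproducible from (master seed, stage name).
    """
    h = zlib.crc32(stage.encode("utf-8"))
    return (int(master_seed) * 1_000_003 + h) % _MOD
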