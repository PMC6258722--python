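"""Shared helpers: seeded substreams and structured stage logging."""

from __future__ import annotations

import logging
import sys
import time

import numpy as np

# Fixed per-stage stream ids so each pipeline stage draws from an independent,
# reproducible substream of the single user-supplied seed.
_STAGE_IDS = {
    "genome": 1,
    "genotypes": 2,
    "contacts": 3,
    "expression": 4,
    "effects": 5,
    "monte_carlo": 6,
    "scores": 7,
}


def stage_rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    """Return a Generator on a substream derived from (seed, stage[, extra]).

    The same (seed, stage, extra) triple always yields the same stream, and
    distinct triples yield statistically independent streams.
    """
    if stage not in _STAGE_IDS:
        raise KeyError(f"unknown stage {stage!r}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_IDS[stage], int(extra)))
    )


def get_logger(name: str = "speqtl") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


class StageTimer:
    """Context manager logging a stage's wall time and a summary line."""

    def __init__(self, stage: str, logger: logging.Logger | None = None):
        self.stage = stage
        self.logger = logger or get_logger()

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.logger.info("stage=%s status=start", self.stage)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        status = "fail" if exc_type else "done"
        self.logger.info("stage=%s status=%s wall_s=%.2f", self.stage, status, dt)
        return False
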