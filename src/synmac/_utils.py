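"""Shared errors, logging and RNG plumbing."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("synmac")


class FormatError(ValueError):
    """A file on disk violates its declared format (header/entry mismatch,
    duplicate identifiers, ragged tables)."""


class ConfigError(ValueError):
    """Inconsistent or invalid configuration (dimension mismatches, invalid
    probability vectors, unknown group labels)."""


class EmptyResultError(RuntimeError):
    """An operation produced an empty result where downstream stages require
    at least one row (e.g. no cell survived quality control). Carries the
    report of what was removed when available."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


def spawn_rngs(seed: int | np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    """Split one seed into ``n`` independent generators.

    Counter-based splitting via :class:`numpy.random.SeedSequence` so each
    pipeline stage draws from its own stream and can be re-run independently.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
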