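"""Shared helpers: error types and deterministic seed derivation."""

from __future__ import annotations

import hashlib


class PersonetError(Exception):
    """Base class for all package errors."""


class ConfigError(PersonetError):
    """A configuration value is missing or invalid; names the offending field."""


class ValidationError(PersonetError):
    """An input table or matrix violates a precondition."""


def substream_seed(root_seed: int, stream: str) -> int:
    """Derive a reproducible per-stage seed from a root seed and a stream name.

    All randomness in the pipeline flows from one root seed; each stage draws
    from its own named substream so that adding or reordering stages never
    perturbs the others.  The result is kept below 2**31 so it is a valid seed
    for every RNG backend in use.
    """
    digest = hashlib.sha256(f"{root_seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
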