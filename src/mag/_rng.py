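"""Seed fan-out: every stochastic stage draws from a named substream of one root seed."""

from __future__ import annotations

import hashlib

import numpy as np


def _name_key(name: str) -> int:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def substream(seed: int, *names: str) -> np.random.Generator:
    """Deterministic generator for stage ``names`` under ``seed``.

    The same (seed, names) pair always yields an identical stream; distinct
    names yield statistically independent streams, so stages stay reproducible
    when run individually.
    """
    keys = [int(seed)] + [_name_key(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))


def substream_seed(seed: int, *names: str) -> int:
    """A plain integer seed (< 2**31) for libraries that want one."""
    ss = np.random.SeedSequence([int(seed)] + [_name_key(n) for n in names])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
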