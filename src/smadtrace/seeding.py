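"""Named random substreams derived from one master seed.

Each pipeline stage draws from its own substream so that re-running a single
stage in isolation reproduces the full-pipeline result bit-exactly.
"""

from __future__ import annotations

import numpy as np

_STREAM_IDS = {
    "simulate": 1,
    "render": 2,
    "snapshot": 3,
    "screen": 4,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named substream generator for a master seed."""
    try:
        stream_id = _STREAM_IDS[name]
    except KeyError:
        raise ValueError(f"unknown stream {name!r}; known: {sorted(_STREAM_IDS)}") from None
    return np.random.default_rng([int(seed), stream_id])
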