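"""Named random streams derived from a single root seed.

Every source of randomness in the package draws from a stream obtained via
``stream(seed, name)``.  Streams are independent by construction
(``numpy.random.SeedSequence`` with a name-derived spawn key), so the order
in which modules consume randomness never changes any module's output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named stream under the given root seed.

    The spawn key is the CRC-32 of the stream name, so the mapping
    name -> stream is stable across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(key,)))
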