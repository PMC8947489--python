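"""Named random substreams derived from a single master seed.

Every source of randomness in the package draws from a Generator produced
here, so a run is fully reproducible from one integer.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The same (seed, names) pair always yields the same stream; distinct
    names yield statistically independent streams (SeedSequence keying).
    """
    keys = [zlib.crc32(str(n).encode("utf8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))
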