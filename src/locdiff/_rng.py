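"""Named random substreams derived from one master seed.

Every stochastic stage derives its own `numpy.random.Generator` from the
master seed plus a stable stage name, so adding a stage never perturbs the
randomness of another and no two stages share a stream.
"""

import hashlib

import numpy as np

_MOD = 2**31


def substream_seed(master_seed: int, *names) -> int:
    """A deterministic child seed (< 2^31) for a named substream."""
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for name in names:
        h.update(b"/")
        h.update(str(name).encode())
    return int.from_bytes(h.digest()[:8], "little") % _MOD


def substream(master_seed: int, *names) -> np.random.Generator:
    return np.random.default_rng(substream_seed(master_seed, *names))
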