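"""Seed bookkeeping: one master seed fans out to independent child streams."""

from __future__ import annotations

import numpy as np

_MOD = 2**31  # keep derived integer seeds in int32 range


def child_seed(master: int, *path: int | str) -> int:
    """Derive a deterministic integer seed from ``master`` and a key path.

    String path elements are hashed stably (byte sum is too collision-prone;
    use the SeedSequence entropy pool instead).
    """
    entropy = [int(master) % _MOD]
    for p in path:
        if isinstance(p, str):
            entropy.extend(p.encode())
        else:
            entropy.append(int(p) % _MOD)
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % _MOD)


def rng_from(master: int, *path: int | str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *path))
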