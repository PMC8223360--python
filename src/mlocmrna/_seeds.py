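"""Deterministic seed derivation.

A single master seed drives every stochastic stage (splitting, tuning
subsamples, negative-set draws, forests). Stage seeds are derived by hashing
the master seed together with a stage path, so any stage can be reproduced in
isolation without replaying the whole pipeline.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31 - 1


def derive_seed(master_seed: int, *path: object) -> int:
    """Derive a child seed from ``master_seed`` and a path of labels.

    The result is a stable non-negative integer < 2**31, independent of
    Python's per-process hash randomisation.
    """
    key = ":".join([str(int(master_seed))] + [str(p) for p in path])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
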