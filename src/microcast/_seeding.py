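"""Deterministic sub-seed derivation.

Every stochastic component (ensemble member, simulator, permutation test) derives its
seed from a single global seed plus a component path, so runs reproduce end to end
without carrying explicit seed lists in configs.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31 - 1


def derive_seed(global_seed: int, *path: object) -> int:
    """Hash (global_seed, *path) into a seed in [0, 2**31 - 1).

    Stable across processes and platforms (SHA-256 of the repr string).
    """
    key = repr((int(global_seed),) + tuple(str(p) for p in path)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
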