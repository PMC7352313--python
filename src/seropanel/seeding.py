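"""Deterministic per-task seed derivation.

Every stochastic fit in the panel search gets a seed derived from the global
seed plus its coordinates (panel, algorithm, fold).  Derivation is a stable
cryptographic hash, so results do not depend on scheduling or process state,
and fitting one panel never perturbs the randomness of another.
"""

from __future__ import annotations

import hashlib


def derive_seed(global_seed: int, *tokens) -> int:
    """A reproducible 31-bit seed from a global seed and string-able tokens."""
    key = ":".join([str(int(global_seed))] + [str(t) for t in tokens])
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)
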