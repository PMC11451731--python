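"""Deterministic per-stage seed derivation.

Every source of randomness in the pipeline draws its seed from the master
seed through this single rule, so that repeated stages ("100 parallel
iterations") are reproducible and independent of execution order.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MOD = 2**31


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a stage/run-specific 31-bit seed from ``master_seed``.

    The stage name and run index are hashed together with the master seed
    (SHA-256), so distinct stages and run indices get uncorrelated streams
    while the whole pipeline remains a pure function of the master seed.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
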