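"""Deterministic child-seed derivation.

One master seed per pipeline run; every stage derives its own seed by
hashing the stage label together with the master seed, so adding or
reordering stages never perturbs the streams of the others.
"""

from __future__ import annotations

import hashlib


def child_seed(master_seed: int, *labels: object) -> int:
    """Derive a stage seed (< 2**31) from a master seed and stage labels."""
    key = ":".join([str(int(master_seed))] + [str(l) for l in labels])
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)
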