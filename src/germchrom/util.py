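"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, name: str) -> int:
    """Derive a stable child seed from a master seed and a stage name.

    Hash-based so every pipeline stage gets an independent stream while a
    single ``--seed`` flag still controls the whole run.  The result is kept
    below 2**31 so it is valid for every RNG interface in use.
    """
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
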