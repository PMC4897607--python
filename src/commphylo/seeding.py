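"""Deterministic seed derivation.

All stochastic components take an explicit integer seed.  Sub-components
(per-stage assembly, per-analysis null ensembles, ...) derive their own
substream seeds from the master seed plus a string token, so the order in
which components run can never change any result.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *tokens) -> int:
    """A stable 31-bit seed derived from a master seed and string tokens."""
    key = ":".join([str(int(master))] + [str(t) for t in tokens])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)
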