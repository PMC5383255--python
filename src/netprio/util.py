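"""Small shared helpers: seed fan-out and file digests."""

from __future__ import annotations

import hashlib
from pathlib import Path


def derived_seed(master_seed: int, *labels: object) -> int:
    """Stable sub-seed for a named stage.

    Hashing the master seed together with stage labels gives every stage
    an independent stream and keeps the result below 2**31, so adding a
    stage never perturbs the streams of existing ones.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for label in labels:
        h.update(b"\x1f")
        h.update(str(label).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
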