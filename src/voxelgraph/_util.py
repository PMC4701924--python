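"""Small shared helpers: byte-size parsing, hashing, provenance headers."""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

from .errors import ValidationError

_SIZE_RE = re.compile(r"^\s*([0-9]+(?:\.[0-9]+)?)\s*([A-Za-z]*)\s*$")

_UNITS = {
    "": 1,
    "b": 1,
    "kb": 10**3,
    "mb": 10**6,
    "gb": 10**9,
    "tb": 10**12,
    "kib": 2**10,
    "mib": 2**20,
    "gib": 2**30,
    "tib": 2**40,
    # bare K/M/G are treated as binary, the convention of memory budgets
    "k": 2**10,
    "m": 2**20,
    "g": 2**30,
    "t": 2**40,
}


def parse_bytes(size: str | int) -> int:
    """Parse a human-readable byte size such as ``"512MB"``, ``"4.2GiB"`` or ``"1024"``.

    Decimal suffixes (KB/MB/GB) are powers of 10; binary suffixes (KiB/MiB/GiB)
    and bare K/M/G are powers of 2.
    """
    if isinstance(size, int):
        return size
    m = _SIZE_RE.match(str(size))
    if not m:
        raise ValidationError(f"cannot parse byte size {size!r}")
    value, unit = float(m.group(1)), m.group(2).lower()
    if unit not in _UNITS:
        raise ValidationError(f"unknown size unit {m.group(2)!r} in {size!r}")
    return int(value * _UNITS[unit])


def sha256_file(path: str | Path, chunk: int = 1 << 20) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        while blk := f.read(chunk):
            h.update(blk)
    return h.hexdigest()


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
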