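"""Small shared helpers."""

from __future__ import annotations

import hashlib


def truncated_percent(numerator: int, denominator: int) -> int:
    """Integer percent by truncation (floor), computed in exact integer arithmetic.

    Floor is the package-wide convention for printed integer percentages; a
    ``mode="round"`` alternative is available through :func:`percent`.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (100 * numerator) // denominator


def percent(numerator: int, denominator: int, mode: str = "floor") -> int:
    """Integer percent under the configured rounding mode (``floor`` or ``round``)."""
    if mode == "floor":
        return truncated_percent(numerator, denominator)
    if mode == "round":
        if denominator <= 0:
            raise ValueError("denominator must be positive")
        return int(round(100.0 * numerator / denominator))
    raise ValueError(f"unknown percent mode: {mode!r}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
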