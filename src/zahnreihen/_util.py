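"""Small shared helpers: decimal rounding and config hashing."""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Iterable


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with halves away from zero, as printed tables in this field do.

    Python's builtin ``round`` is banker's rounding, which turns 2.655 into
    2.65; measurement tables round it to 2.66.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def decimal_mean(values: Iterable[float], ndigits: int | None = None) -> float:
    """Mean computed in decimal arithmetic from the printed (shortest-repr) values.

    Used for grand means over already-rounded table cells, where float
    accumulation error would corrupt the final printed digit (e.g. a true
    mean of 2.4775 must round half-up to 2.478, not fall to 2.477).
    """
    vals = [Decimal(repr(float(v))) for v in values]
    if not vals:
        raise ValueError("mean of empty sequence")
    mean = sum(vals) / len(vals)
    if ndigits is None:
        return float(mean)
    return float(mean.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def config_hash(config: Any) -> str:
    """Stable sha256 over a JSON-serialisable configuration object."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()
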