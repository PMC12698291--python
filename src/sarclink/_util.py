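"""Small shared helpers."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding so printed rates match conventional
    reporting of percentages.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
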