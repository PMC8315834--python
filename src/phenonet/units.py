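"""Deciban arithmetic and evidence grading.

All model coefficients, priors, lifts and effect sizes in this package are
expressed in decibans (db): ten times the base-10 logarithm of an odds or
probability ratio.  Jeffreys' evidence grades apply: >5 db substantial
(odds ≈ 3:1), >10 db strong (10:1), >15 db very strong (≈30:1), >20 db
decisive (100:1).
"""

from __future__ import annotations

import math

__all__ = ["db_to_odds", "odds_to_db", "evidence_grade", "JEFFREYS_BANDS"]

#: Lower deciban bound of each Jeffreys evidence grade.
JEFFREYS_BANDS: tuple[tuple[float, str], ...] = (
    (20.0, "decisive"),
    (15.0, "very strong"),
    (10.0, "strong"),
    (5.0, "substantial"),
)


def db_to_odds(db: float) -> float:
    """Convert a deciban value to the corresponding odds ratio, 10^(db/10)."""
    return 10.0 ** (db / 10.0)


def odds_to_db(odds: float) -> float:
    """Convert an odds ratio to decibans, 10·log10(odds)."""
    if odds <= 0:
        raise ValueError("odds ratio must be positive")
    return 10.0 * math.log10(odds)


def evidence_grade(db: float) -> str:
    """Jeffreys grade for a deciban value; 'weak' below 5 db."""
    for lo, name in JEFFREYS_BANDS:
        if db > lo:
            return name
    return "weak"
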