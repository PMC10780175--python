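"""Model-acceptance arithmetic: fold errors, two-fold envelopes, unit helpers.

A prediction is deemed accurate when the fold error — the ratio of predicted
to observed — lies in [0.5, 2], the conventional two-fold acceptance band
for PBPK models.  Printed-precision rendering uses decimal half-up rounding
so reported tables match hand-rounded values (IEEE round-half-even would
turn 22.15 into 22.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "FoldError",
    "ValidationRecord",
    "fold_error",
    "envelope_fraction",
    "convert_clearance",
    "round_half_up",
    "validation_table",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up to ``ndigits`` places (matches printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FoldError:
    """Predicted/observed ratio with the two-fold accuracy verdict."""

    ratio: float
    accurate: bool

    def rounded(self, ndigits: int = 2) -> float:
        return round_half_up(self.ratio, ndigits)


def fold_error(predicted: float, observed: float,
               factor: float = 2.0) -> FoldError:
    """Fold error ``predicted / observed`` and whether it is within ``factor``.

    Both values must be positive and in the same units.
    """
    if predicted <= 0 or observed <= 0:
        raise ValueError("fold error needs positive predicted and observed values")
    ratio = predicted / observed
    return FoldError(ratio=ratio, accurate=(1.0 / factor <= ratio <= factor))


def envelope_fraction(pairs: list[tuple[float, float]], factor: float = 2.0) -> float:
    """Fraction of (predicted, observed) pairs whose ratio lies in [1/factor, factor]."""
    if not pairs:
        raise ValueError("envelope fraction of an empty list is undefined")
    hits = sum(fold_error(p, o, factor).accurate for p, o in pairs)
    return hits / len(pairs)


def convert_clearance(value: float, to: str = "ml_min_kg") -> float:
    """Convert a specific clearance between mL/h/kg and mL/min/kg (factor 60)."""
    if value < 0:
        raise ValueError("clearance must be >= 0")
    if to == "ml_min_kg":
        return value / 60.0
    if to == "ml_h_kg":
        return value * 60.0
    raise ValueError(f"unknown clearance unit {to!r}")


@dataclass(frozen=True)
class ValidationRecord:
    """One observed/predicted comparison row of a validation table."""

    quantity: str
    observed: float
    predicted: float
    units: str = ""

    @property
    def fold_error(self) -> FoldError:
        return fold_error(self.predicted, self.observed)


def validation_table(records: list[ValidationRecord]) -> pd.DataFrame:
    """Render records as a table: quantity, observed, predicted, fold error.

    Fold errors are shown half-up rounded to two decimals; the raw ratio is
    kept in a separate column.
    """
    rows = []
    for r in records:
        fe = r.fold_error
        rows.append({
            "quantity": r.quantity,
            "units": r.units,
            "observed": r.observed,
            "predicted": r.predicted,
            "fold_error": fe.rounded(),
            "fold_error_raw": fe.ratio,
            "within_2fold": fe.accurate,
        })
    return pd.DataFrame(rows)
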