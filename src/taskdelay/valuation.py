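"""Monetary-equivalence ratings -> per-unit subjective values in euros.

Participants state the quantity of an item they judge equivalent to earning
(or losing) 1 EUR and 5 EUR.  Averaging the two per-euro quantities and
inverting yields the per-unit gain equivalent R_i (rewards) or loss
equivalent E_j (efforts, punishments).  Option values are then linear in
quantity: V = N x unit_value.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ItemRating", "UnitValue", "unit_value", "option_value_undiscounted"]

SUBCATEGORIES = ("food", "goods", "cognitive", "motor", "bodily", "abstract")


@dataclass(frozen=True)
class ItemRating:
    """Monetary-equivalence ratings for one item by one participant.

    q1, q5
        Quantities judged equivalent to 1 EUR and 5 EUR respectively.
    """

    participant_id: str
    item_id: str
    category: str  # reward | effort | punishment
    subcategory: str
    q1: float
    q5: float

    def __post_init__(self) -> None:
        if self.q1 <= 0 or self.q5 <= 0:
            raise ValueError(
                f"rating quantities must be positive, got q1={self.q1}, q5={self.q5}"
            )


@dataclass(frozen=True)
class UnitValue:
    """Per-unit subjective value of an item, in euros."""

    participant_id: str
    item_id: str
    value_per_unit: float


def unit_value(rating: ItemRating, *, convention: str = "quantity") -> UnitValue:
    """Per-unit euro value from a pair of monetary-equivalence ratings.

    convention="quantity" (default)
        Average the two per-euro *quantities*, Q = (q1 + q5/5)/2, and invert:
        value = 1/Q euros per unit.
    convention="euros"
        Average the two per-unit *euro* values instead: (1/q1 + 5/q5)/2.
        The two conventions agree exactly when the ratings are mutually
        consistent (q5 = 5·q1) and differ only by the harmonic/arithmetic
        averaging order otherwise.
    """
    if convention == "quantity":
        q_per_euro = (rating.q1 + rating.q5 / 5.0) / 2.0
        v = 1.0 / q_per_euro
    elif convention == "euros":
        v = (1.0 / rating.q1 + 5.0 / rating.q5) / 2.0
    else:
        raise ValueError(f"unknown averaging convention {convention!r}")
    return UnitValue(rating.participant_id, rating.item_id, v)


def option_value_undiscounted(quantity: float, value_per_unit: float) -> float:
    """Linear option value N x unit_value, in euros."""
    if quantity < 0:
        raise ValueError("quantity must be >= 0")
    return quantity * value_per_unit
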