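"""A scalar measurement with an optional standard error.

Uncertainty propagation throughout the package is first-order and assumes
uncorrelated inputs (quadrature), which is the convention behind the "±"
columns of enzyme kinetics and calorimetry tables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class Quantity:
    """A value with an optional nonnegative standard error.

    The unit is carried contextually by the field that holds the quantity
    (e.g. ``ActivationThermo.dG`` is in kJ mol⁻¹).
    """

    value: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.se is not None and not self.se >= 0:
            raise ValueError(f"standard error must be >= 0, got {self.se}")

    def __sub__(self, other: "Quantity") -> "Quantity":
        return Quantity(self.value - other.value, quadrature(self.se, other.se))

    def scaled(self, factor: float) -> "Quantity":
        se = None if self.se is None else abs(factor) * self.se
        return Quantity(factor * self.value, se)


def as_quantity(x) -> Quantity:
    """Coerce a Quantity, a number, or a (value, se) pair to a Quantity."""
    if isinstance(x, Quantity):
        return x
    if isinstance(x, (tuple, list)) and len(x) == 2:
        return Quantity(float(x[0]), float(x[1]))
    return Quantity(float(x))


def quadrature(*ses: float | None) -> float | None:
    """Combine standard errors in quadrature; None if all inputs are None."""
    known = [s for s in ses if s is not None]
    if not known:
        return None
    return math.sqrt(sum(s * s for s in known))
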