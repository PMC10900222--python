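"""First-order (delta-method) error propagation.

The standard deviation of a function f(x, y, ...) of uncertain inputs is

    s_f = sqrt( sum_i (df/dx_i)^2 * s_i^2 )

evaluated at the input means.  :class:`Measurement` pairs a value with its
standard deviation; the helper functions cover the difference, sum, product,
ratio, logarithm and exponential forms that recur in the barrier/rate
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Tuple


@dataclass(frozen=True)
class Measurement:
    """A scalar value with a standard deviation."""

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")

    def __iter__(self):
        yield self.value
        yield self.sd

    def __format__(self, spec: str) -> str:
        return f"{self.value:{spec}} +/- {self.sd:{spec}}"


def propagate_error(partials: Iterable[Tuple[float, float]]) -> float:
    """Combine (partial derivative, input sd) pairs into the output sd."""
    total = 0.0
    for deriv, sd in partials:
        if sd < 0:
            raise ValueError("standard deviation must be >= 0")
        total += (deriv * sd) ** 2
    return math.sqrt(total)


def difference(a: Measurement, b: Measurement) -> Measurement:
    return Measurement(a.value - b.value, propagate_error([(1.0, a.sd), (-1.0, b.sd)]))


def total(a: Measurement, b: Measurement) -> Measurement:
    return Measurement(a.value + b.value, propagate_error([(1.0, a.sd), (1.0, b.sd)]))


def product(a: Measurement, b: Measurement) -> Measurement:
    return Measurement(
        a.value * b.value, propagate_error([(b.value, a.sd), (a.value, b.sd)])
    )


def ratio(a: Measurement, b: Measurement) -> Measurement:
    if b.value == 0:
        raise ZeroDivisionError("ratio denominator is zero")
    val = a.value / b.value
    return Measurement(
        val, propagate_error([(1.0 / b.value, a.sd), (-val / b.value, b.sd)])
    )


def log_of(a: Measurement) -> Measurement:
    if a.value <= 0:
        raise ValueError("log of non-positive measurement")
    return Measurement(math.log(a.value), propagate_error([(1.0 / a.value, a.sd)]))


def exp_of(a: Measurement) -> Measurement:
    val = math.exp(a.value)
    return Measurement(val, propagate_error([(val, a.sd)]))
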