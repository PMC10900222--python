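"""Effective diffusion coefficient and rate extrapolation via Kramers theory.

In the overdamped limit the escape rate over a 1-D free-energy barrier is

    k = (w0 * wb * beta * D / 2 pi) * exp(-beta * dG#),

where w0 = sqrt(curvature of the reactant well), wb = sqrt(|curvature of
the barrier|) (units (kcal/mol)^1/2 deg^-1, so the prefactor has units
s^-1 with D in deg^2/s), and dG# is the activation free energy.  Taking
logarithms,

    ln(k / (w0 wb)) = ln(beta * D / 2 pi) - dG# / (k_B T),

so measurements at several reduced barriers fall on a line of fixed slope
-1/(k_B T); the variance-weighted intercept yields D_eff, and evaluating
the Kramers expression at the full-barrier dG# extrapolates the rate.
All errors follow first-order propagation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .constants import DEFAULT_TEMPERATURE, beta as _beta, kbt
from .uncertainty import Measurement, propagate_error

__all__ = [
    "Measurement",
    "propagate_error",
    "KramersPoint",
    "KramersFit",
    "rate_from_kramers",
    "kramers_regression",
    "extrapolate_rate",
]


@dataclass(frozen=True)
class KramersPoint:
    """One reduced-barrier measurement feeding the fixed-slope regression."""

    alpha: float
    dg: Measurement  # activation free energy for the studied direction, kcal/mol
    k: Measurement  # measured rate, 1/s
    curv_well: Measurement  # kcal mol^-1 deg^-2, > 0
    curv_barrier: Measurement  # kcal mol^-1 deg^-2, < 0

    def __post_init__(self) -> None:
        if self.k.value <= 0:
            raise ValueError("rate must be positive")
        if self.curv_well.value <= 0:
            raise ValueError("well curvature must be positive")
        if self.curv_barrier.value >= 0:
            raise ValueError("barrier curvature must be negative")


@dataclass
class KramersFit:
    """Fixed-slope regression result: D_eff and the dimensionless intercept."""

    d_eff: Measurement  # deg^2/s
    intercept: Measurement  # c = ln(beta D / 2 pi)
    temperature: float
    k_extrapolated: Optional[Measurement] = None
    n_points: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "d_eff": list(self.d_eff),
            "intercept": list(self.intercept),
            "temperature_K": self.temperature,
            "k_extrapolated": list(self.k_extrapolated) if self.k_extrapolated else None,
            "n_points": self.n_points,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _frequencies(curv_well: float, curv_barrier: float) -> float:
    """Product w0 * wb from signed curvatures."""
    if curv_well <= 0 or curv_barrier >= 0:
        raise ValueError("need curv_well > 0 and curv_barrier < 0")
    return math.sqrt(curv_well) * math.sqrt(abs(curv_barrier))


def rate_from_kramers(
    dg: float,
    curv_well: float,
    curv_barrier: float,
    diffusion: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Overdamped Kramers escape rate (1/s)."""
    if diffusion <= 0:
        raise ValueError("diffusion must be positive")
    b = _beta(temperature)
    w0wb = _frequencies(curv_well, curv_barrier)
    return w0wb * b * diffusion / (2.0 * math.pi) * math.exp(-b * dg)


def _log_point(p: KramersPoint, b: float) -> Measurement:
    """c_i = ln(k_i/(w0 wb)) + beta dG_i with its propagated sd."""
    w0wb = _frequencies(p.curv_well.value, p.curv_barrier.value)
    value = math.log(p.k.value / w0wb) + b * p.dg.value
    sd = propagate_error(
        [
            (1.0 / p.k.value, p.k.sd),
            (-0.5 / p.curv_well.value, p.curv_well.sd),
            (-0.5 / abs(p.curv_barrier.value), p.curv_barrier.sd),
            (b, p.dg.sd),
        ]
    )
    return Measurement(value, sd)


def kramers_regression(
    points: Sequence[KramersPoint],
    temperature: float = DEFAULT_TEMPERATURE,
) -> KramersFit:
    """Fit ln(k / w0 wb) = c - beta * dG# with the slope fixed at -beta.

    The intercept is the inverse-variance weighted mean of
    ln(k_i / w0_i wb_i) + beta dG_i; when any point carries zero error the
    fit falls back to equal weights.  D_eff = 2 pi k_B T exp(c).
    """
    if len(points) == 0:
        raise ValueError("need at least one point")
    b = _beta(temperature)
    cs = [_log_point(p, b) for p in points]
    if all(c.sd > 0 for c in cs):
        weights = [1.0 / c.sd**2 for c in cs]
        sw = sum(weights)
        c_val = sum(w * c.value for w, c in zip(weights, cs)) / sw
        c_sd = math.sqrt(1.0 / sw)
    else:
        n = len(cs)
        c_val = sum(c.value for c in cs) / n
        if n > 1:
            var = sum((c.value - c_val) ** 2 for c in cs) / (n - 1)
            c_sd = math.sqrt(var / n)
        else:
            c_sd = 0.0
    kt = kbt(temperature)
    d_eff = 2.0 * math.pi * kt * math.exp(c_val)
    intercept = Measurement(c_val, c_sd)
    return KramersFit(
        d_eff=Measurement(d_eff, d_eff * c_sd),
        intercept=intercept,
        temperature=temperature,
        n_points=len(points),
    )


def extrapolate_rate(
    fit: KramersFit,
    dg_target: Measurement,
    curv_well_target: Measurement,
    curv_barrier_target: Measurement,
    temperature: Optional[float] = None,
) -> Measurement:
    """Kramers rate at the target barrier using the fitted D_eff.

    The relative error combines the D_eff, activation-energy and
    curvature uncertainties to first order.
    """
    temperature = fit.temperature if temperature is None else temperature
    b = _beta(temperature)
    k = rate_from_kramers(
        dg_target.value,
        curv_well_target.value,
        curv_barrier_target.value,
        fit.d_eff.value,
        temperature,
    )
    rel = propagate_error(
        [
            (1.0 / fit.d_eff.value, fit.d_eff.sd),
            (b, dg_target.sd),
            (0.5 / curv_well_target.value, curv_well_target.sd),
            (0.5 / abs(curv_barrier_target.value), curv_barrier_target.sd),
        ]
    )
    return Measurement(k, k * rel)
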