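"""Independent numerical references for the stochastic pipeline.

These routines never touch trajectory data: equilibrium properties come
from direct quadrature of the Boltzmann density and first-passage times
from a finite-difference solve of the backward-equation boundary-value
problem.  They serve as ground-truth oracles for the sampling-based
estimators (WHAM profiles, Kaplan-Meier rates, Kramers regression).
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy.linalg import solve_banded

from .constants import DEFAULT_TEMPERATURE, beta as _beta
from .synthetic_data import RestraintSpec, TorsionPotential, potential_energy, potential_gradient


def boltzmann_bin_free_energy(
    pot: TorsionPotential,
    bin_edges: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    oversample: int = 64,
) -> np.ndarray:
    """Exact binned free energy -kT ln P(bin) by quadrature, anchored at 0.

    P(bin) integrates exp(-beta V) over each bin; this matches what a
    histogram-based estimator converges to, including the finite-bin
    smoothing of sharp features.
    """
    b = _beta(temperature)
    edges = np.asarray(bin_edges, dtype=float)
    probs = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        x = np.linspace(edges[i], edges[i + 1], oversample)
        probs[i] = np.trapezoid(np.exp(-b * potential_energy(pot, x)), x)
    a = -np.log(probs / probs.sum()) / b
    return a - a.min()


def boltzmann_point_free_energy(
    pot: TorsionPotential, x: np.ndarray, temperature: float = DEFAULT_TEMPERATURE
) -> np.ndarray:
    """Pointwise free energy (= potential up to a constant in 1-D), anchored."""
    a = np.asarray(potential_energy(pot, x), dtype=float)
    return a - a.min()


def biased_window_mean(
    pot: TorsionPotential,
    restraint: RestraintSpec,
    temperature: float = DEFAULT_TEMPERATURE,
    n_grid: int = 20001,
) -> float:
    """Mean omega under the restrained Boltzmann density, by quadrature.

    Evaluated on the 360-deg interval centred at the restraint reference,
    where the harmonic bias needs no minimum-image wrapping.
    """
    b = _beta(temperature)
    ref = restraint.reference_omega
    x = np.linspace(ref - 180.0, ref + 180.0, n_grid)
    u = potential_energy(pot, x) + 0.5 * restraint.force_constant * (x - ref) ** 2
    w = np.exp(-b * (u - u.min()))
    return float(np.trapezoid(x * w, x) / np.trapezoid(w, x))


def mean_first_passage_time(
    pot: TorsionPotential,
    diffusion: float,
    start: float,
    absorb_at: float,
    far_boundary: float,
    far_condition: Literal["reflecting", "absorbing"] = "reflecting",
    temperature: float = DEFAULT_TEMPERATURE,
    n_grid: int = 8001,
) -> float:
    """MFPT from ``start`` to ``absorb_at`` on the 1-D potential.

    Solves D * (tau'' - beta V' tau') = -1 by central finite differences
    with tau = 0 at the absorbing boundary and either a reflecting
    (tau' = 0) or absorbing condition at the far boundary.
    """
    lo, hi = sorted((absorb_at, far_boundary))
    x = np.linspace(lo, hi, n_grid)
    h = x[1] - x[0]
    b = _beta(temperature)
    drift = -b * np.asarray(potential_gradient(pot, x))  # deterministic velocity / D

    # banded system: sub, diag, super
    n = n_grid
    diag = np.full(n, -2.0 / h**2)
    sub = np.full(n, 1.0 / h**2)
    sup = np.full(n, 1.0 / h**2)
    sub = sub - drift / (2.0 * h)
    sup = sup + drift / (2.0 * h)
    rhs = np.full(n, -1.0 / diffusion)

    def set_dirichlet(i):
        diag[i] = 1.0
        rhs[i] = 0.0
        if i == 0:
            sup[i] = 0.0
        else:
            sub[i] = 0.0

    absorb_is_lo = np.isclose(lo, absorb_at)
    if absorb_is_lo:
        set_dirichlet(0)
        if far_condition == "absorbing":
            set_dirichlet(n - 1)
        else:  # reflecting: ghost node tau_{n} = tau_{n-2}
            diag[n - 1] = -2.0 / h**2
            sub[n - 1] = 2.0 / h**2
    else:
        set_dirichlet(n - 1)
        if far_condition == "absorbing":
            set_dirichlet(0)
        else:
            diag[0] = -2.0 / h**2
            sup[0] = 2.0 / h**2

    ab = np.zeros((3, n))
    ab[0, 1:] = sup[:-1]
    ab[1, :] = diag
    ab[2, :-1] = sub[1:]
    tau = solve_banded((1, 1), ab, rhs)
    return float(np.interp(start, x, tau))
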