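"""Extrapolation of scaled-barrier free-energy profiles to the full barrier.

With the dihedral barrier term scaled by alpha, a first-order cumulant
expansion gives per omega-bin

    A(omega; alpha) ~= A0(omega) - (1 - alpha) * B(omega),

where A0 is the unscaled-potential profile and B(omega) is the effective
(mean) dihedral potential at fixed omega.  A variance-weighted linear
regression of A(omega; alpha) on (1 - alpha) therefore yields A0 as the
per-bin intercept (with its standard error) and -B as the slope.
Higher-order cumulants are dropped by construction.

Profiles measured at different alpha are first superposed by matching
their values at omega = 0 and 180 deg, where the scaled term vanishes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .free_energy import FreeEnergyProfile

logger = logging.getLogger(__name__)

ANCHOR_ANGLES = (0.0, 180.0)


@dataclass
class ExtrapolationResult:
    """Per-bin intercepts A0 (anchored at 0), slopes -B, and diagnostics."""

    profile: FreeEnergyProfile  # A0 with intercept standard errors
    b: np.ndarray  # effective potential B(omega) per bin
    r_squared: np.ndarray
    weighted: bool
    alphas: Tuple[float, ...]


def _check_common_grid(profiles: Sequence[FreeEnergyProfile]) -> None:
    ref = profiles[0].bin_centers
    for p in profiles[1:]:
        if len(p.bin_centers) != len(ref) or not np.allclose(p.bin_centers, ref):
            raise ValueError("profiles must share a common bin grid")


def superpose_profiles(
    profiles: Sequence[FreeEnergyProfile],
) -> List[FreeEnergyProfile]:
    """Shift profiles to agree at the alpha-insensitive anchor angles.

    Each profile after the first is shifted by the constant minimizing the
    sum of squared differences to the first profile at the bins nearest
    0 and 180 deg (the mean residual over the anchor bins); the first
    profile is returned unshifted.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    _check_common_grid(profiles)
    ref = profiles[0]
    anchor_idx = [ref.index_of(a) for a in ANCHOR_ANGLES]
    out = [ref]
    for p in profiles[1:]:
        shift = float(np.mean(ref.a[anchor_idx] - p.a[anchor_idx]))
        out.append(
            FreeEnergyProfile(
                p.bin_centers, p.a + shift, p.a_err, p.counts, p.alpha, p.temperature
            )
        )
    return out


def extrapolate_profile(
    profiles: Sequence[Tuple[float, FreeEnergyProfile]],
    superpose: bool = True,
) -> ExtrapolationResult:
    """Per-bin weighted regression of A(omega; alpha) on (1 - alpha).

    Weights are inverse bootstrap variances; bins whose errors are all
    zero fall back to an unweighted fit (logged).  Bins missing in any
    profile are flagged NaN.  The assembled A0 is re-anchored to
    min(A0) = 0.
    """
    if len(profiles) < 2:
        raise ValueError("extrapolation needs profiles at >= 2 distinct alpha values")
    alphas = np.array([a for a, _ in profiles], dtype=float)
    if len(np.unique(alphas)) < 2:
        raise ValueError("alpha values must be distinct")
    profs = [p for _, p in profiles]
    _check_common_grid(profs)
    if superpose:
        profs = superpose_profiles(profs)

    x = 1.0 - alphas
    n_bins = len(profs[0].bin_centers)
    a_mat = np.array([p.a for p in profs])  # (n_alpha, n_bins)
    e_mat = np.array([p.a_err for p in profs])
    counts = np.minimum.reduce([p.counts for p in profs])

    a0 = np.full(n_bins, np.nan)
    a0_err = np.full(n_bins, np.nan)
    slope = np.full(n_bins, np.nan)
    r2 = np.full(n_bins, np.nan)
    used_weights = True
    for j in range(n_bins):
        y = a_mat[:, j]
        if not np.all(np.isfinite(y)):
            continue  # bin missing in some profile: flagged NaN
        e = e_mat[:, j]
        if np.all(e > 0):
            w = 1.0 / e**2
        else:
            w = np.ones_like(y)
            used_weights = False
        sw, swx = w.sum(), (w * x).sum()
        swxx, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
        delta = sw * swxx - swx**2
        if delta <= 0 or not np.isfinite(delta):
            raise ValueError("degenerate regression weights")
        b1 = (sw * swxy - swx * swy) / delta
        b0 = (swxx * swy - swx * swxy) / delta
        a0[j] = b0
        a0_err[j] = np.sqrt(swxx / delta)
        slope[j] = b1
        yhat = b0 + b1 * x
        ss_res = (w * (y - yhat) ** 2).sum()
        ybar = swy / sw
        ss_tot = (w * (y - ybar) ** 2).sum()
        r2[j] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if not used_weights:
        logger.info("zero bootstrap errors encountered; unweighted fit used")

    a0 -= np.nanmin(a0)
    profile = FreeEnergyProfile(
        profs[0].bin_centers, a0, a0_err, counts,
        alpha=1.0, temperature=profs[0].temperature,
    )
    return ExtrapolationResult(
        profile=profile, b=-slope, r_squared=r2,
        weighted=used_weights, alphas=tuple(alphas),
    )
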