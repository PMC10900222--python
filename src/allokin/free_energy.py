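"""Free-energy profiles from umbrella-window time series.

The weighted histogram analysis method (WHAM) combines biased histograms
from harmonically restrained windows into an unbiased probability along
omega, iterating the self-consistent equations

    P(b) = sum_w H_wb / sum_w N_w f_w c_wb,      c_wb = exp(-beta u_w(b)),
    1/f_w = sum_b c_wb P(b),

until the window free-energy shifts g_w = -kT ln f_w change by less than
the tolerance.  Per-bin errors come from a Monte Carlo bootstrap that
resamples each window at its decorrelation stride.  Downstream helpers
locate the cis/trans wells and the transition state, and turn the profile
into barrier heights, the cis-trans free-energy difference, and quadratic
(parabolic-fit) curvatures at the stationary points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .constants import DEFAULT_TEMPERATURE, beta as _beta, kbt
from .synthetic_data import RestraintSpec, TrajectorySeries, angle_difference
from .uncertainty import Measurement, propagate_error

#: default binning: 80 uniform bins between -31.5 and 208.5 degrees
DEFAULT_BIN_RANGE = (-31.5, 208.5)
DEFAULT_N_BINS = 80


def make_bins(
    n_bins: int = DEFAULT_N_BINS,
    lo: float = DEFAULT_BIN_RANGE[0],
    hi: float = DEFAULT_BIN_RANGE[1],
) -> np.ndarray:
    """Uniform bin edges over [lo, hi]."""
    return np.linspace(lo, hi, n_bins + 1)


@dataclass
class FreeEnergyProfile:
    """Binned free energy A(omega) with per-bin bootstrap errors.

    Bins with no samples hold NaN in ``a`` and are flagged by
    ``sampled``; the profile is anchored so that min(A) = 0 over sampled
    bins.
    """

    bin_centers: np.ndarray
    a: np.ndarray
    a_err: np.ndarray
    counts: np.ndarray
    alpha: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.a_err = np.asarray(self.a_err, dtype=float)
        self.counts = np.asarray(self.counts)
        widths = np.diff(self.bin_centers)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ValueError("bins must be strictly increasing and uniform")
        if np.any(self.a_err[np.isfinite(self.a_err)] < 0):
            raise ValueError("errors must be >= 0")

    @property
    def sampled(self) -> np.ndarray:
        return np.isfinite(self.a) & (self.counts > 0)

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def anchored(self) -> "FreeEnergyProfile":
        shift = np.nanmin(self.a)
        return FreeEnergyProfile(
            self.bin_centers, self.a - shift, self.a_err, self.counts,
            self.alpha, self.temperature,
        )

    def index_of(self, omega: float) -> int:
        return int(np.argmin(np.abs(self.bin_centers - omega)))

    def write(self, path) -> None:
        header = (
            f"alpha {self.alpha}\ntemperature_K {self.temperature}\n"
            "bin_center_deg A_kcal_mol A_err_kcal_mol counts"
        )
        np.savetxt(
            path,
            np.column_stack([self.bin_centers, self.a, self.a_err, self.counts]),
            header=header,
            fmt="%.10g",
        )

    @classmethod
    def read(cls, path) -> "FreeEnergyProfile":
        meta = {}
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2:
                    try:
                        meta[parts[0]] = float(parts[1])
                    except ValueError:
                        pass
        arr = np.loadtxt(path)
        return cls(
            arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3],
            alpha=meta.get("alpha", 1.0),
            temperature=meta.get("temperature_K", DEFAULT_TEMPERATURE),
        )


@dataclass(frozen=True)
class StateAssignment:
    """Angular positions of the cis well, transition state, and trans well."""

    omega_cis: float
    omega_ts: float
    omega_trans: float

    def __post_init__(self) -> None:
        if not self.omega_cis < self.omega_ts < self.omega_trans:
            raise ValueError("expected omega_cis < omega_ts < omega_trans")


@dataclass(frozen=True)
class BarrierStats:
    """Barrier heights, well asymmetry and stationary-point curvatures."""

    dg_tc: Measurement  # trans -> cis activation free energy
    dg_ct: Measurement  # cis -> trans activation free energy
    dg_cis_trans: Measurement  # A(cis) - A(trans)
    curv_trans: Measurement  # kcal mol^-1 deg^-2
    curv_cis: Measurement
    curv_ts: Measurement


def estimate_decorrelation(series: TrajectorySeries) -> float:
    """Decorrelation time: twice the 1/e decay lag of the autocorrelation."""
    x = np.asarray(series.omega, dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 samples")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("constant series has undefined autocorrelation")
    n = len(x)
    # FFT autocorrelation
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n]
    acf = acov / acov[0]
    below = np.nonzero(acf < 1.0 / math.e)[0]
    lag = int(below[0]) if below.size else n - 1
    return 2.0 * lag * series.dt


Window = Tuple[RestraintSpec, TrajectorySeries]


def _window_arrays(windows: Sequence[Window]) -> Tuple[List[np.ndarray], List[RestraintSpec]]:
    samples = [series.wrapped() for _, series in windows]
    restraints = [r for r, _ in windows]
    return samples, restraints


def _wham_core(
    samples: Sequence[np.ndarray],
    restraints: Sequence[RestraintSpec],
    bin_edges: np.ndarray,
    temperature: float,
    tolerance: float,
    max_iter: int,
    check_connectivity: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """Self-consistent WHAM solve; returns (A per bin with NaN gaps, counts)."""
    b = _beta(temperature)
    kt = kbt(temperature)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    hist = np.array([np.histogram(s, bins=bin_edges)[0] for s in samples], dtype=float)
    n_w = hist.sum(axis=1)
    if np.any(n_w == 0):
        raise ValueError("a window has no samples inside the binned range")

    if check_connectivity and len(samples) > 1:
        occ = hist > 0
        adj = (occ @ occ.T) > 0
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp > 1:
            raise ValueError(
                f"umbrella windows form {n_comp} disconnected groups; "
                "no common free-energy scale exists"
            )

    bias = np.array(
        [0.5 * r.force_constant * angle_difference(centers, r.reference_omega) ** 2
         for r in restraints]
    )
    c = np.exp(-b * bias)  # (W, B)
    m_b = hist.sum(axis=0)
    f = np.ones(len(samples))
    g_old = np.zeros_like(f)
    for _ in range(max_iter):
        denom = (n_w * f) @ c  # (B,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, m_b / denom, 0.0)
        norm = c @ p
        f = 1.0 / norm
        g = -kt * np.log(f)
        g -= g[0]
        if np.max(np.abs(g - g_old)) < tolerance:
            g_old = g
            break
        g_old = g
    else:
        raise RuntimeError(f"WHAM did not converge within {max_iter} iterations")

    with np.errstate(divide="ignore"):
        a = np.where(m_b > 0, -kt * np.log(np.where(m_b > 0, p, 1.0)), np.nan)
    a = a - np.nanmin(a)
    return a, m_b


def wham_solve(
    windows: Sequence[Window],
    bin_edges: Optional[np.ndarray] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    tolerance: float = 1e-6,
    max_iter: int = 100_000,
) -> FreeEnergyProfile:
    """Unbiased free-energy profile from restrained windows via WHAM."""
    if len(windows) == 0:
        raise ValueError("need at least one window")
    if bin_edges is None:
        bin_edges = make_bins()
    samples, restraints = _window_arrays(windows)
    a, counts = _wham_core(
        samples, restraints, bin_edges, temperature, tolerance, max_iter
    )
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    alpha = windows[0][1].metadata.get("alpha", 1.0)
    return FreeEnergyProfile(
        centers, a, np.zeros_like(a), counts, alpha=alpha, temperature=temperature
    )


def bootstrap_profile_errors(
    windows: Sequence[Window],
    bin_edges: Optional[np.ndarray] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    n_trials: int = 10,
    decorrelation: float = 0.0,
    seed: int = 1234,
    tolerance: float = 1e-6,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Per-bin profile errors by decorrelated-index Monte Carlo bootstrap.

    Each trial draws, per window, N_eff points with replacement from the
    series decimated at the decorrelation stride (random phase), re-solves
    WHAM, and the error is the standard deviation across trials.
    """
    if bin_edges is None:
        bin_edges = make_bins()
    samples, restraints = _window_arrays(windows)
    rng = np.random.default_rng(seed)
    strides = []
    for _, series in windows:
        stride = max(1, int(math.ceil(decorrelation / series.dt)))
        if stride >= len(series):
            raise ValueError("decorrelation time exceeds series duration")
        strides.append(stride)
    trials = []
    for _ in range(n_trials):
        resampled = []
        for s, stride in zip(samples, strides):
            phase = int(rng.integers(stride))
            idx = np.arange(phase, len(s), stride)
            pick = rng.choice(idx, size=len(idx), replace=True)
            resampled.append(s[pick])
        a, _ = _wham_core(
            resampled, restraints, bin_edges, temperature, tolerance, max_iter,
            check_connectivity=False,
        )
        trials.append(a)
    stack = np.array(trials)
    with warnings.catch_warnings():
        # bins unsampled in every trial yield all-NaN slices; keep them NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(stack, axis=0, ddof=1)


def solve_profile_with_errors(
    windows: Sequence[Window],
    bin_edges: Optional[np.ndarray] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    tolerance: float = 1e-6,
    n_trials: int = 10,
    decorrelation: Optional[float] = None,
    seed: int = 1234,
) -> FreeEnergyProfile:
    """WHAM profile with bootstrap errors in one call.

    If ``decorrelation`` is omitted it is estimated from the first window
    (twice the 1/e autocorrelation decay lag).
    """
    profile = wham_solve(windows, bin_edges, temperature, tolerance)
    if decorrelation is None:
        decorrelation = estimate_decorrelation(windows[0][1])
    profile.a_err = bootstrap_profile_errors(
        windows, bin_edges, temperature, n_trials, decorrelation, seed, tolerance
    )
    return profile


def locate_states(
    profile: FreeEnergyProfile,
    cis_box: Tuple[float, float] = (-45.0, 45.0),
    trans_box: Tuple[float, float] = (135.0, 225.0),
) -> StateAssignment:
    """Find the cis/trans wells (box minima) and the barrier between them."""
    c = profile.bin_centers
    a = np.where(profile.sampled, profile.a, np.inf)

    def box_min(lo, hi, name):
        mask = (c >= lo) & (c <= hi) & profile.sampled
        if not mask.any():
            raise ValueError(f"no sampled bins in the {name} search box")
        idx = np.flatnonzero(mask)
        return idx[np.argmin(a[idx])]

    i_cis = box_min(*cis_box, "cis")
    i_trans = box_min(*trans_box, "trans")
    between = np.flatnonzero(profile.sampled)
    between = between[(between > i_cis) & (between < i_trans)]
    if between.size == 0:
        raise ValueError("no sampled bins between the wells")
    i_ts = between[np.argmax(profile.a[between])]
    if not (profile.a[i_ts] > profile.a[i_cis] and profile.a[i_ts] > profile.a[i_trans]):
        raise ValueError("profile has no barrier between the wells (monotone?)")
    return StateAssignment(
        omega_cis=float(c[i_cis]), omega_ts=float(c[i_ts]), omega_trans=float(c[i_trans])
    )


def _quadratic_curvature(
    profile: FreeEnergyProfile, x0: float, halfwidth: float
) -> Measurement:
    c = profile.bin_centers
    mask = np.abs(c - x0) <= halfwidth
    if mask.sum() < 4:
        raise ValueError("fewer than 4 bins in the curvature fit window")
    if not profile.sampled[mask].all():
        raise ValueError(
            "unsampled bins inside the curvature fit window; refusing to interpolate"
        )
    x = c[mask] - x0
    y = profile.a[mask]
    err = profile.a_err[mask]
    X = np.column_stack([x**2, x, np.ones_like(x)])
    if np.all(err > 0):
        w = 1.0 / err**2
        xtw = X.T * w
        cov = np.linalg.inv(xtw @ X)
        coef = cov @ (xtw @ y)
        s2_c2 = cov[0, 0]
    else:
        coef, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
        dof = len(y) - 3
        sigma2 = float(res[0]) / dof if res.size and dof > 0 else 0.0
        cov = np.linalg.inv(X.T @ X) * sigma2
        s2_c2 = cov[0, 0]
    return Measurement(2.0 * float(coef[0]), 2.0 * math.sqrt(max(s2_c2, 0.0)))


def barrier_stats(
    profile: FreeEnergyProfile,
    states: StateAssignment,
    fit_halfwidth: float = 10.0,
) -> BarrierStats:
    """Barrier heights and curvatures from a located profile.

    Heights are bin differences with errors combined in quadrature from
    the per-bin bootstrap errors; curvatures are twice the quadratic
    coefficient of a parabola fitted to bins within ``fit_halfwidth`` of
    each stationary point (inverse-variance weighted when bootstrap
    errors are available).
    """
    i_cis = profile.index_of(states.omega_cis)
    i_ts = profile.index_of(states.omega_ts)
    i_trans = profile.index_of(states.omega_trans)
    a, e = profile.a, profile.a_err

    def diff(i, j) -> Measurement:
        return Measurement(
            float(a[i] - a[j]), propagate_error([(1.0, e[i]), (-1.0, e[j])])
        )

    return BarrierStats(
        dg_tc=diff(i_ts, i_trans),
        dg_ct=diff(i_ts, i_cis),
        dg_cis_trans=diff(i_cis, i_trans),
        curv_trans=_quadratic_curvature(profile, states.omega_trans, fit_halfwidth),
        curv_cis=_quadratic_curvature(profile, states.omega_cis, fit_halfwidth),
        curv_ts=_quadratic_curvature(profile, states.omega_ts, fit_halfwidth),
    )


def convergence_trace(
    windows: Sequence[Window],
    bin_edges: Optional[np.ndarray] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    block: float = 0.0,
    tolerance: float = 1e-6,
    change_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Cumulative-time trace of the state free-energy differences.

    WHAM is re-solved on data truncated at successive block boundaries.
    If ``change_threshold`` is given, the trace carries a ``converged``
    attribute: True when the last two blocks agree within the threshold
    on all three free-energy differences.
    """
    if block <= 0:
        raise ValueError("block must be positive")
    t_end = min(series.times[-1] for _, series in windows)
    n_blocks = max(1, int(t_end / block))
    rows = []
    for k in range(1, n_blocks + 1):
        t_cut = k * block
        truncated = [(r, s.truncated(t_cut)) for r, s in windows]
        profile = wham_solve(truncated, bin_edges, temperature, tolerance)
        states = locate_states(profile)
        stats = barrier_stats(profile, states)
        rows.append(
            {
                "cumulative_time_s": t_cut,
                "dg_tc": stats.dg_tc.value,
                "dg_ct": stats.dg_ct.value,
                "dg_cis_trans": stats.dg_cis_trans.value,
            }
        )
    trace = pd.DataFrame(rows)
    if change_threshold is not None and len(trace) >= 2:
        last, prev = trace.iloc[-1], trace.iloc[-2]
        change = max(
            abs(last[q] - prev[q]) for q in ("dg_tc", "dg_ct", "dg_cis_trans")
        )
        trace.attrs["converged"] = bool(change < change_threshold)
        trace.attrs["last_change"] = float(change)
    return trace
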