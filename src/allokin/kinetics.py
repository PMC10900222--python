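"""Rates from unrestrained escape replicas via survival analysis.

First-passage events are detected at sample resolution against the
transition-state angle (the free-energy peak between the wells).  The
survival function S(t) is estimated by the Kaplan-Meier product-limit
method with 95% exponential-Greenwood confidence intervals (lifelines),
evaluated on a uniform time grid.  Rate constants come from confidence-
interval-weighted exponential fits:

    S(t) = sum_i A_i exp(-k_i t),    sum_i A_i = 1,  A_i, k_i > 0,

with the single-exponential case fitted as a weighted linear regression
of ln S on t through the origin, and the effective rate as the weighted
average k = sum A_i k_i / sum A_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.optimize import least_squares

from .synthetic_data import TrajectorySeries
from .uncertainty import Measurement


@dataclass(frozen=True)
class EventRecord:
    """One replica's first-passage outcome (event or right-censored)."""

    replica_id: int
    time: float  # s
    status: str  # "event" | "censored"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("event/censoring time must be positive")
        if self.status not in ("event", "censored"):
            raise ValueError("status must be 'event' or 'censored'")


@dataclass
class SurvivalCurve:
    """Kaplan-Meier S(t) with 95% CI on a uniform time grid."""

    times: np.ndarray
    s: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_events: int = 0
    n_total: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.ci_low = np.asarray(self.ci_low, dtype=float)
        self.ci_high = np.asarray(self.ci_high, dtype=float)
        if np.any(np.diff(self.s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        for arr in (self.s, self.ci_low, self.ci_high):
            if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
                raise ValueError("survival values must lie in [0, 1]")
        if np.any(self.ci_low > self.s + 1e-9) or np.any(self.ci_high < self.s - 1e-9):
            raise ValueError("CI must bracket the estimate")

    def write(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.s, self.ci_low, self.ci_high]),
            header="time_s S ci_low ci_high",
            fmt="%.10g",
        )

    @classmethod
    def read(cls, path) -> "SurvivalCurve":
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


@dataclass
class RateEstimate:
    """Fitted exponential components and the effective rate constant."""

    components: List[Tuple[float, float]]  # (A_i, k_i), sum A_i = 1
    k: Measurement
    n_components: int
    cov: Optional[np.ndarray] = None  # covariance of (A_1..A_n, k_1..k_n)
    diagnostics: dict = field(default_factory=dict)


def detect_transition(
    series: TrajectorySeries,
    omega_ts: float,
    direction: str = "trans_to_cis",
) -> EventRecord:
    """First sample crossing of the transition-state angle.

    trans->cis events occur at the first sample with wrapped omega below
    ``omega_ts``; cis->trans at the first sample above.  A series that
    never crosses is censored at its final time.
    """
    if direction not in ("trans_to_cis", "cis_to_trans"):
        raise ValueError("direction must be 'trans_to_cis' or 'cis_to_trans'")
    w = series.wrapped()
    crossed = w < omega_ts if direction == "trans_to_cis" else w > omega_ts
    if crossed[0]:
        raise ValueError("series starts on the product side of omega_ts")
    replica_id = int(series.metadata.get("replica_id", 0))
    hits = np.flatnonzero(crossed)
    if hits.size:
        return EventRecord(replica_id, float(series.times[hits[0]]), "event")
    return EventRecord(replica_id, float(series.times[-1]), "censored")


def events_from_replicas(
    replicas: Sequence[TrajectorySeries],
    omega_ts: float,
    direction: str = "trans_to_cis",
) -> List[EventRecord]:
    return [detect_transition(s, omega_ts, direction) for s in replicas]


def write_events(records: Sequence[EventRecord], path) -> None:
    lines = ["# replica_id time_s status"]
    lines += [f"{r.replica_id} {r.time:.10g} {r.status}" for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


def read_events(path) -> List[EventRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rid, t, status = line.split()
        records.append(EventRecord(int(rid), float(t), status))
    return records


def survival_grid(records: Sequence[EventRecord], spacing: float) -> np.ndarray:
    """Uniform grid from 0 to the latest event time at the given spacing."""
    event_times = [r.time for r in records if r.status == "event"]
    t_max = max(event_times) if event_times else max(r.time for r in records)
    n = max(2, int(math.ceil(t_max / spacing)) + 1)
    return np.arange(n) * spacing


def km_survival(records: Sequence[EventRecord], grid: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier survival with exponential-Greenwood 95% CI on a grid."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    durations = np.array([r.time for r in records])
    observed = np.array([r.status == "event" for r in records], dtype=int)
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(durations, event_observed=observed)
    grid = np.asarray(grid, dtype=float)
    s = kmf.survival_function_at_times(grid).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    timeline = ci.index.to_numpy(dtype=float)
    lo_step = ci.iloc[:, 0].to_numpy()
    hi_step = ci.iloc[:, 1].to_numpy()
    pos = np.clip(np.searchsorted(timeline, grid, side="right") - 1, 0, len(timeline) - 1)
    lo, hi = lo_step[pos], hi_step[pos]
    # degenerate bands (S = 1 with no events yet, or S = 0) are NaN in the
    # log(-log) transform; collapse them onto the estimate
    lo = np.where(np.isnan(lo), s, lo)
    hi = np.where(np.isnan(hi), s, hi)
    return SurvivalCurve(
        grid, s, np.minimum(lo, s), np.maximum(hi, s),
        n_events=int(observed.sum()), n_total=len(records),
    )


def _fit_points(curve: SurvivalCurve) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid points usable for fitting and their CI-derived weights."""
    mask = (curve.s > 0.0) & (curve.s < 1.0)
    t = curve.times[mask]
    s = curve.s[mask]
    hw = 0.5 * (curve.ci_high[mask] - curve.ci_low[mask])
    if np.all(hw == 0):
        w = np.ones_like(s)
    else:
        w = np.zeros_like(s)
        w[hw > 0] = 1.0 / hw[hw > 0] ** 2
    return t, s, w


def fit_survival(
    curve: SurvivalCurve, n_components: int = 1, seed: int = 0
) -> RateEstimate:
    """CI-weighted exponential fit of the survival curve.

    n = 1: weighted linear regression of ln S on t through the origin
    (slope = -k).  n > 1: weighted nonlinear least squares of the
    multi-exponential mixture with positivity bounds and the sum
    constraint, multi-start initialized deterministically from ``seed``.
    """
    t, s, w = _fit_points(curve)
    if len(t) < max(3, 3 * n_components):
        raise ValueError("too few grid points with 0 < S < 1 for the fit")
    if n_components == 1:
        y = np.log(s)
        # inverse-variance weights in the fitting (log) space: the CI
        # half-width of ln S
        mask = (curve.s > 0.0) & (curve.s < 1.0)
        lo = np.maximum(curve.ci_low[mask], 1e-300)
        hi = np.maximum(curve.ci_high[mask], 1e-300)
        hw_log = 0.5 * (np.log(hi) - np.log(lo))
        if np.all(hw_log == 0):
            w = np.ones_like(y)
        else:
            w = np.zeros_like(y)
            w[hw_log > 0] = 1.0 / hw_log[hw_log > 0] ** 2
        sxx = float((w * t * t).sum())
        slope = float((w * t * y).sum()) / sxx
        k = -slope
        if k <= 0:
            raise ValueError("survival curve shows no decay")
        resid = y - slope * t
        dof = len(t) - 1
        s2 = float((w * resid**2).sum()) / dof
        k_err = math.sqrt(s2 / sxx)
        cov = np.array([[0.0, 0.0], [0.0, k_err**2]])
        est = RateEstimate(
            components=[(1.0, k)], k=Measurement(k, k_err), n_components=1,
            cov=cov, diagnostics={"n_points": len(t), "wssr": _wssr([(1.0, k)], t, s, w)},
        )
        return est

    n = n_components
    sw = np.sqrt(w)

    def residuals(p):
        amps, rates = p[:n], p[n:]
        model = (amps[None, :] * np.exp(-np.outer(t, rates))).sum(axis=1)
        return np.concatenate([sw * (model - s), [100.0 * (amps.sum() - 1.0)]])

    # deterministic multi-start around a single-exponential scale
    k0 = max(fit_survival(curve, 1).k.value, 1e-300)
    rng = np.random.default_rng(seed)
    best = None
    spreads = [3.0, 10.0, 30.0]
    for spread in spreads:
        for _ in range(3):
            rates0 = k0 * spread ** np.linspace(-1, 1, n)
            rates0 = rates0 * np.exp(rng.normal(scale=0.3, size=n))
            amps0 = np.full(n, 1.0 / n)
            p0 = np.concatenate([amps0, rates0])
            res = least_squares(
                residuals, p0,
                bounds=(np.full(2 * n, 1e-15), np.full(2 * n, np.inf)),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or res.cost < best.cost:
                best = res
    amps, rates = best.x[:n], best.x[n:]
    if np.any(amps <= 0) or np.any(rates <= 0):
        raise RuntimeError("component collapse: nonpositive amplitude or rate")
    total = amps.sum()
    if abs(total - 1.0) > 0.05:
        raise RuntimeError("amplitude sum failed to converge to 1")
    amps = amps / total
    order = np.argsort(-rates)
    amps, rates = amps[order], rates[order]

    jac = best.jac[:-1, :]  # drop the constraint row
    dof = max(len(t) - 2 * n, 1)
    s2 = 2 * 0.5 * float((residuals(best.x)[:-1] ** 2).sum()) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        cov = cov[np.ix_(np.concatenate([order, order + n]),
                         np.concatenate([order, order + n]))]
    except np.linalg.LinAlgError:
        cov = None
    components = list(zip(amps.tolist(), rates.tolist()))
    est = RateEstimate(
        components=components, k=Measurement(0.0), n_components=n, cov=cov,
        diagnostics={"n_points": len(t), "wssr": _wssr(components, t, s, w)},
    )
    est.k = effective_rate(est)
    return est


def _wssr(components, t, s, w) -> float:
    model = sum(a * np.exp(-k * t) for a, k in components)
    return float((w * (model - s) ** 2).sum())


def effective_rate(est: RateEstimate) -> Measurement:
    """Amplitude-weighted average rate k = sum A_i k_i / sum A_i."""
    amps = np.array([a for a, _ in est.components])
    rates = np.array([k for _, k in est.components])
    total = amps.sum()
    k_eff = float((amps * rates).sum() / total)
    if est.cov is None:
        return Measurement(k_eff, 0.0)
    n = len(amps)
    grad = np.concatenate([(rates - k_eff) / total, amps / total])
    if est.cov.shape[0] == 2 and n == 1:  # single-exponential layout (A, k)
        grad = np.array([0.0, 1.0])
    var = float(grad @ est.cov @ grad)
    return Measurement(k_eff, math.sqrt(max(var, 0.0)))


def model_select(
    curve: SurvivalCurve, max_components: int = 3, seed: int = 0
) -> RateEstimate:
    """Pick the component count by the small-sample information criterion.

    AICc over the CI-weighted residuals, with p = 2n - 1 free parameters
    (amplitudes constrained to sum to one).  All candidate fits are kept
    in ``diagnostics['candidates']``.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    t, _, _ = _fit_points(curve)
    n_pts = len(t)
    candidates = []
    for n in range(1, max_components + 1):
        try:
            est = fit_survival(curve, n, seed=seed)
        except (ValueError, RuntimeError):
            continue
        p = 2 * n - 1
        if n_pts - p - 1 <= 0:
            continue
        # floor at the machine-precision residual level so that exact
        # (noise-free) fits are compared by parameter count alone
        wssr = max(est.diagnostics["wssr"], n_pts * 1e-24)
        aicc = n_pts * math.log(wssr / n_pts) + 2 * p + (
            2 * p * (p + 1) / (n_pts - p - 1)
        )
        candidates.append((n, aicc, est))
    if not candidates:
        raise RuntimeError("no exponential model could be fitted")
    best_n, best_aicc, best = min(candidates, key=lambda c: c[1])
    best.diagnostics["candidates"] = [(n, aicc) for n, aicc, _ in candidates]
    return best
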