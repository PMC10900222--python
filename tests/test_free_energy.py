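"""WHAM, bootstrap errors, state location, barrier statistics."""

import math

import numpy as np
import pytest

from allokin import pipelines
from allokin.constants import kbt
from allokin.free_energy import (
    FreeEnergyProfile,
    barrier_stats,
    bootstrap_profile_errors,
    convergence_trace,
    estimate_decorrelation,
    locate_states,
    make_bins,
    solve_profile_with_errors,
    wham_solve,
)
from allokin.synthetic_data import (
    BrownianConfig,
    RestraintSpec,
    TorsionPotential,
    TrajectorySeries,
    generate_umbrella_set,
    simulate_overdamped,
)

D = pipelines.D_TRUE
DT = pipelines.DT


def profile_from_function(func, n_bins=80, lo=-31.5, hi=208.5, err=0.0):
    edges = make_bins(n_bins, lo, hi)
    centers = 0.5 * (edges[:-1] + edges[1:])
    a = func(centers)
    a = a - a.min()
    return FreeEnergyProfile(
        centers, a, np.full_like(a, err), np.full(len(a), 1000)
    )


def cos_profile(centers):
    """A(omega) = 14 * (1 + cos(2 omega - 180 deg)): wells 0/180, barrier 28."""
    return 14.0 * (1.0 + np.cos(np.deg2rad(2.0 * centers - 180.0)))


class TestDecorrelation:
    def test_white_noise_gives_two_sampling_intervals(self, rng):
        x = rng.normal(size=10_000)
        series = TrajectorySeries(np.arange(10_000) * 1e-9, x)
        assert estimate_decorrelation(series) == pytest.approx(2e-9)

    def test_ar1_recovers_twice_correlation_time(self, rng):
        phi = 0.98
        tau = -1.0 / math.log(phi)  # in sampling intervals
        n = 100_000
        x = np.empty(n)
        x[0] = 0.0
        noise = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + noise[i]
        series = TrajectorySeries(np.arange(n) * 1e-9, x)
        assert estimate_decorrelation(series) == pytest.approx(2 * tau * 1e-9, rel=0.2)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            estimate_decorrelation(
                TrajectorySeries(np.arange(200) * 1e-9, np.full(200, 5.0))
            )
        with pytest.raises(ValueError):
            estimate_decorrelation(
                TrajectorySeries(np.arange(50) * 1e-9, np.random.default_rng(0).normal(size=50))
            )


class TestWham:
    def test_single_unbiased_window_equals_direct_inversion_and_is_flat(self):
        """With one unbiased window, WHAM is exactly -kT ln(histogram).

        On a flat potential the profile is also flat to within sampling
        noise (the run spans ~20 wrap-around diffusion times; observed
        bin scatter is ~0.2 kcal/mol, asserted < 0.4).
        """
        pot = TorsionPotential(terms=((1, 0.0, 0.0),))
        cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=4_000_000,
                             save_stride=40, seed=31)
        series = simulate_overdamped(pot, cfg)
        profile = wham_solve([(RestraintSpec(0.0, 0.0), series)])
        mask = profile.counts >= 100
        counts, _ = np.histogram(series.wrapped(), bins=make_bins())
        a_direct = -kbt() * np.log(counts[mask] / counts.sum())
        a_direct -= a_direct.min()
        assert np.allclose(profile.a[mask], a_direct, atol=1e-9)
        assert np.abs(profile.a[mask] - profile.a[mask].mean()).max() < 0.4

    def test_duplicate_windows_match_concatenated_data(self, double_well_84):
        cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=50_000,
                             save_stride=10, seed=32)
        restraint = RestraintSpec(90.0, 0.01)
        series = simulate_overdamped(double_well_84, cfg, restraint)
        twice = TrajectorySeries(
            np.arange(2 * len(series)) * series.dt,
            np.concatenate([series.omega, series.omega]),
        )
        edges = make_bins(40, 30.0, 150.0)
        p_two = wham_solve([(restraint, series), (restraint, series)], edges)
        p_cat = wham_solve([(restraint, twice)], edges)
        m = p_two.sampled
        assert np.allclose(p_two.a[m], p_cat.a[m], atol=1e-9)

    def test_profile_invariant_under_window_reordering(self, double_well_84):
        cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=20_000,
                             save_stride=10, seed=33)
        windows = generate_umbrella_set(
            double_well_84, cfg, window_refs=np.arange(60.0, 125.0, 5.0)
        )
        edges = make_bins(40, 40.0, 140.0)
        a = wham_solve(windows, edges)
        b = wham_solve(list(reversed(windows)), edges)
        m = a.sampled
        assert np.allclose(a.a[m], b.a[m], atol=1e-9)

    def test_anchored_at_zero(self, wham_experiment):
        profile = wham_experiment["profile"]
        assert np.nanmin(profile.a) == pytest.approx(0.0, abs=1e-12)

    def test_disconnected_windows_raise(self):
        rng = np.random.default_rng(34)
        t = np.arange(2000) * 1e-9
        s1 = TrajectorySeries(t, rng.normal(0.0, 2.0, 2000))
        s2 = TrajectorySeries(t, rng.normal(180.0, 2.0, 2000))
        windows = [
            (RestraintSpec(0.0, 1.0), s1),
            (RestraintSpec(180.0, 1.0), s2),
        ]
        with pytest.raises(ValueError, match="disconnected"):
            wham_solve(windows)


class TestBootstrap:
    def test_reproducible_for_fixed_seed(self, double_well_84):
        cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=20_000,
                             save_stride=10, seed=35)
        windows = generate_umbrella_set(
            double_well_84, cfg, window_refs=np.arange(150.0, 215.0, 5.0)
        )
        edges = make_bins(30, 140.0, 215.0)
        kwargs = dict(bin_edges=edges, n_trials=2, decorrelation=20 * DT * 10, seed=1234)
        e1 = bootstrap_profile_errors(windows, **kwargs)
        e2 = bootstrap_profile_errors(windows, **kwargs)
        assert np.array_equal(e1[np.isfinite(e1)], e2[np.isfinite(e2)])

    def test_decorrelation_longer_than_series_raises(self, double_well_84, quick_cfg):
        windows = generate_umbrella_set(
            double_well_84, quick_cfg, window_refs=[180.0]
        )
        with pytest.raises(ValueError, match="decorrelation"):
            bootstrap_profile_errors(
                windows, make_bins(), decorrelation=1.0, n_trials=2
            )

    def test_bootstrap_errors_track_replicate_scatter(self):
        """Bootstrap SDs agree within 3x with SDs across regenerated data."""
        pot = TorsionPotential(terms=((2, 3.0, 180.0),))
        edges = make_bins(60, -20.0, 200.0)
        refs = np.arange(-15.0, 200.0, 15.0)
        dg_values = []
        boot_errs = []
        for i in range(10):
            cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=30_000,
                                 save_stride=10, seed=400 + i)
            windows = generate_umbrella_set(pot, cfg, window_refs=refs, k_production=0.005)
            profile = solve_profile_with_errors(
                windows, edges, n_trials=10, decorrelation=30 * DT * 10, seed=1234
            )
            states = locate_states(profile)
            stats = barrier_stats(profile, states)
            dg_values.append(stats.dg_tc.value)
            boot_errs.append(stats.dg_tc.sd)
        scatter = np.std(dg_values, ddof=1)
        mean_boot = np.mean(boot_errs)
        assert mean_boot / 3 < scatter < mean_boot * 3


class TestStates:
    def test_symmetric_profile_states(self):
        profile = profile_from_function(cos_profile)
        states = locate_states(profile)
        assert (states.omega_cis, states.omega_ts, states.omega_trans) == (0.0, 90.0, 180.0)

    def test_shifted_wells_detected(self):
        shifted = profile_from_function(
            lambda c: 14.0 * (1.0 + np.cos(np.deg2rad(2.0 * (c + 5.0) - 180.0)))
        )
        states = locate_states(shifted)
        assert states.omega_cis == pytest.approx(-6.0, abs=1.6)
        assert states.omega_trans == pytest.approx(174.0, abs=1.6)

    def test_monotone_profile_raises(self):
        profile = profile_from_function(lambda c: 0.01 * c)
        with pytest.raises(ValueError):
            locate_states(profile)


class TestBarrierStats:
    def test_closed_form_cosine_profile(self):
        profile = profile_from_function(cos_profile)
        states = locate_states(profile)
        stats = barrier_stats(profile, states)
        assert stats.dg_tc.value == pytest.approx(28.0, abs=1e-9)
        assert stats.dg_ct.value == pytest.approx(28.0, abs=1e-9)
        assert stats.dg_cis_trans.value == pytest.approx(0.0, abs=1e-9)
        assert stats.curv_ts.value < 0 < stats.curv_trans.value

    def test_identity_dg_tc_minus_dg_ct(self):
        profile = profile_from_function(
            lambda c: cos_profile(c) + 0.01 * np.sin(np.deg2rad(c))
        )
        stats = barrier_stats(profile, locate_states(profile))
        assert stats.dg_tc.value - stats.dg_ct.value == pytest.approx(
            stats.dg_cis_trans.value, abs=1e-9
        )

    def test_gaussian_well_curvatures_match_analytic(self):
        s1, s2 = 25.0, 30.0
        depth = 5.0

        def func(c):
            return (
                depth
                - depth * np.exp(-(c**2) / (2 * s1**2))
                - depth * np.exp(-((c - 180.0) ** 2) / (2 * s2**2))
            )

        profile = profile_from_function(func)
        states = locate_states(profile)
        stats = barrier_stats(profile, states, fit_halfwidth=10.0)
        assert stats.curv_cis.value == pytest.approx(depth / s1**2, rel=0.05)
        assert stats.curv_trans.value == pytest.approx(depth / s2**2, rel=0.05)

    def test_too_few_bins_in_fit_window(self):
        profile = profile_from_function(cos_profile)
        with pytest.raises(ValueError, match="4 bins"):
            barrier_stats(profile, locate_states(profile), fit_halfwidth=4.0)

    def test_unsampled_bins_abort(self):
        profile = profile_from_function(cos_profile)
        profile.counts[profile.index_of(85.5)] = 0
        profile.a[profile.index_of(85.5)] = np.nan
        with pytest.raises(ValueError, match="refusing to interpolate"):
            barrier_stats(profile, locate_states(profile))


@pytest.fixture(scope="module")
def stationary_windows():
    pot = TorsionPotential(terms=((2, 3.0, 180.0),))
    cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=60_000,
                         save_stride=10, seed=41)
    return pot, generate_umbrella_set(
        pot, cfg, window_refs=np.arange(-15.0, 200.0, 15.0), k_production=0.005
    )


class TestConvergenceTrace:
    def test_stationary_fixture_converges(self, stationary_windows):
        pot, windows = stationary_windows
        edges = make_bins(60, -20.0, 200.0)
        duration = windows[0][1].times[-1]
        trace = convergence_trace(
            windows, edges, block=duration / 4, change_threshold=0.5
        )
        assert len(trace) == 4
        assert trace.attrs["converged"]
        assert trace["cumulative_time_s"].is_monotonic_increasing

    def test_single_block_gives_one_row(self, stationary_windows):
        _, windows = stationary_windows
        edges = make_bins(60, -20.0, 200.0)
        duration = windows[0][1].times[-1]
        trace = convergence_trace(windows, edges, block=duration * 1.01)
        assert len(trace) == 1

    def test_drifting_fixture_flagged(self, stationary_windows):
        """A potential that deepens the trans well mid-run fails the check."""
        pot, windows = stationary_windows
        drifted = []
        for restraint, series in windows:
            n = len(series)
            shifted_pot = TorsionPotential(
                terms=((2, 3.0, 180.0),), background=((1, 2.5, 0.0),)
            )
            cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=60_000,
                                 save_stride=10, seed=int(restraint.reference_omega) + 600)
            late = simulate_overdamped(
                shifted_pot, cfg, restraint, initial_omega=series.omega[-1]
            )
            omega = np.concatenate([series.omega[: n // 2], late.omega[: n - n // 2]])
            drifted.append(
                (restraint, TrajectorySeries(np.arange(len(omega)) * series.dt, omega))
            )
        edges = make_bins(60, -20.0, 200.0)
        duration = drifted[0][1].times[-1]
        trace = convergence_trace(
            drifted, edges, block=duration / 2, change_threshold=0.2
        )
        assert not trace.attrs["converged"]
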