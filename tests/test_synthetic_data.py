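"""Ground-truth generator: potential, integrator, umbrella/escape fixtures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allokin import pipelines, theory
from allokin.constants import kbt
from allokin.free_energy import estimate_decorrelation
from allokin.synthetic_data import (
    BrownianConfig,
    RestraintSpec,
    TorsionPotential,
    TrajectorySeries,
    generate_escape_replicas,
    generate_mode_ensembles,
    generate_umbrella_set,
    potential_energy,
    potential_gradient,
    simulate_overdamped,
    wrap_angle,
)

D = pipelines.D_TRUE
DT = pipelines.DT


class TestPotential:
    @pytest.mark.parametrize(
        "alpha,phi,expected",
        [
            (1.0, 90.0, 28.0),  # barrier height equals the V2 amplitude
            (1.0, 0.0, 0.0),
            (0.35, 90.0, 9.8),  # a scaled-barrier value used in the study systems
        ],
    )
    def test_standard_term_values(self, alpha, phi, expected):
        pot = TorsionPotential(terms=((2, 28.0, 180.0),), alpha=alpha)
        assert potential_energy(pot, phi) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 45.0, 90.0, 123.4, -60.0])
    def test_gradient_matches_central_difference(self, phi):
        pot = TorsionPotential(
            terms=((2, 28.0, 180.0),), alpha=0.7, background=((1, 2.0, 30.0),)
        )
        h = 1e-4
        fd = (potential_energy(pot, phi + h) - potential_energy(pot, phi - h)) / (2 * h)
        assert potential_gradient(pot, phi) == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_gradient_zero_at_stationary_points(self):
        pot = TorsionPotential(terms=((2, 28.0, 180.0),))
        assert potential_gradient(pot, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert potential_gradient(pot, 90.0) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(phi=st.floats(-1000, 1000))
    def test_periodicity_and_wrapping(self, phi):
        pot = TorsionPotential(terms=((2, 8.4, 180.0),), background=((1, 1.0, 10.0),))
        assert potential_energy(pot, phi) == pytest.approx(
            potential_energy(pot, phi + 360.0), abs=1e-9
        )
        assert -90.0 <= wrap_angle(phi) < 270.0

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            TorsionPotential(terms=((2, 28.0, 180.0),), alpha=0.0)
        with pytest.raises(ValueError):
            TorsionPotential(terms=((0, 28.0, 180.0),))


class TestIntegrator:
    def test_step_stability_guard(self):
        with pytest.raises(ValueError, match="RMS displacement"):
            BrownianConfig(d_true=1e8, timestep=1e-7, n_steps=10)

    def test_bit_identical_for_same_seed(self, double_well_84, quick_cfg):
        a = simulate_overdamped(double_well_84, quick_cfg)
        b = simulate_overdamped(double_well_84, quick_cfg)
        assert np.array_equal(a.omega, b.omega)
        c = simulate_overdamped(
            double_well_84,
            BrownianConfig(d_true=D, timestep=DT, n_steps=20_000, save_stride=10, seed=1),
        )
        assert not np.array_equal(a.omega, c.omega)

    def test_free_diffusion_msd(self):
        """On a flat potential the MSD grows as 2 D t (within 5%)."""
        pot = TorsionPotential(terms=((1, 0.0, 0.0),))
        cfg = BrownianConfig(d_true=D, timestep=1e-9, n_steps=100_000, seed=3)
        series = simulate_overdamped(pot, cfg)
        x = series.omega
        for lag in (10, 100):
            disp = x[lag:] - x[:-lag]
            msd = np.mean(disp**2)
            assert msd == pytest.approx(2 * D * lag * 1e-9, rel=0.05)

    def test_harmonic_equipartition(self):
        """Stationary variance under a pure restraint is k_B T / k_r."""
        pot = TorsionPotential(terms=((1, 0.0, 0.0),))
        restraint = RestraintSpec(0.0, 0.06)
        cfg = BrownianConfig(d_true=D, timestep=1e-9, n_steps=400_000,
                             save_stride=10, seed=4)
        series = simulate_overdamped(pot, cfg, restraint)
        expected = kbt() / 0.06  # ~9.94 deg^2 at 300 K
        assert np.var(series.omega[100:]) == pytest.approx(expected, rel=0.10)

    def test_equilibrium_histogram_matches_boltzmann(self):
        """Unrestrained sampling reproduces exp(-beta V)/Z (chi-square GOF).

        A low barrier (~1.3 k_B T) keeps well exchange fast enough for
        global equilibration within the run.
        """
        pot = TorsionPotential(terms=((2, 0.8, 180.0),))
        cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=4_000_000,
                             save_stride=20, seed=5)
        series = simulate_overdamped(pot, cfg)
        decorr = estimate_decorrelation(series)
        stride = max(1, int(math.ceil(decorr / series.dt)))
        sub = series.wrapped()[::stride]
        edges = np.linspace(-90, 270, 19)
        counts, _ = np.histogram(sub, bins=edges)
        from allokin.constants import beta as beta_fn

        b = beta_fn(cfg.temperature)
        grid_probs = []
        for i in range(len(edges) - 1):
            xs = np.linspace(edges[i], edges[i + 1], 64)
            grid_probs.append(np.trapezoid(np.exp(-b * potential_energy(pot, xs)), xs))
        grid_probs = np.array(grid_probs)
        grid_probs /= grid_probs.sum()
        from scipy.stats import chisquare

        stat, pvalue = chisquare(counts, f_exp=grid_probs * counts.sum())
        assert pvalue > 0.01

    def test_restrained_window_mean_matches_quadrature(self):
        """Window sample means agree with the biased Boltzmann density."""
        pot = TorsionPotential(terms=((2, 8.4, 180.0),))
        for ref in (0.0, 90.0, 180.0):
            restraint = RestraintSpec(ref, 0.06)
            cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=200_000,
                                 save_stride=10, seed=int(ref) + 7)
            series = simulate_overdamped(pot, cfg, restraint)
            x = series.omega[50:]
            expected = theory.biased_window_mean(pot, restraint)
            decorr = estimate_decorrelation(series)
            n_eff = max(4.0, len(x) / max(1.0, decorr / series.dt))
            se = np.std(x) / math.sqrt(n_eff)
            assert abs(x.mean() - expected) < 3 * se


class TestUmbrellaSet:
    def test_default_layout_has_49_windows(self, double_well_84, quick_cfg):
        windows = generate_umbrella_set(double_well_84, quick_cfg)
        assert len(windows) == 49
        refs = [r.reference_omega for r, _ in windows]
        assert refs[0] == -30.0 and refs[-1] == 210.0
        assert np.allclose(np.diff(refs), 5.0)

    def test_windows_are_chained(self, double_well_84, quick_cfg):
        windows = generate_umbrella_set(
            double_well_84, quick_cfg, window_refs=[0.0, 10.0]
        )
        assert windows[1][1].omega[0] == windows[0][1].omega[-1]

    def test_zero_bias_single_window_reduces_to_free_run(self, double_well_84, quick_cfg):
        from allokin.synthetic_data import derive_seed
        from dataclasses import replace

        windows = generate_umbrella_set(
            double_well_84, quick_cfg, window_refs=[180.0], k_production=0.0
        )
        free = simulate_overdamped(
            double_well_84,
            replace(quick_cfg, seed=derive_seed(quick_cfg.seed, 0)),
            initial_omega=180.0,
        )
        assert np.array_equal(windows[0][1].omega, free.omega)

    def test_empty_refs_rejected(self, double_well_84, quick_cfg):
        with pytest.raises(ValueError):
            generate_umbrella_set(double_well_84, quick_cfg, window_refs=[])


class TestEscapeReplicas:
    def test_no_barrier_all_events_fast(self):
        pot = TorsionPotential(terms=((1, 0.0, 0.0),))
        cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=200_000,
                             save_stride=4, seed=11)
        replicas = generate_escape_replicas(pot, 10, cfg)
        for series in replicas:
            assert series.wrapped()[-1] < 90.0  # terminated at a crossing

    def test_high_barrier_short_run_all_censored(self):
        pot = TorsionPotential(terms=((2, 28.0, 180.0),))
        cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=5_000,
                             save_stride=4, seed=12)
        replicas = generate_escape_replicas(pot, 5, cfg)
        for series in replicas:
            assert np.all(series.wrapped() >= 90.0)

    def test_escape_rate_matches_mfpt_oracle(self):
        """Mean first-passage rate within 1.5x of the quadrature oracle.

        Uses a 3 kcal/mol barrier so 100 replicas stay affordable; the
        oracle uses the same boundary conditions (absorbing at the
        transition state, reflecting at 270 deg).
        """
        pot = TorsionPotential(terms=((2, 3.0, 180.0),))
        mfpt = theory.mean_first_passage_time(
            pot, D, start=180.0, absorb_at=90.0, far_boundary=270.0
        )
        cfg = BrownianConfig(d_true=D, timestep=DT, n_steps=int(8 * mfpt / DT),
                             save_stride=4, seed=13)
        replicas = generate_escape_replicas(pot, 100, cfg)
        times = []
        for series in replicas:
            w = series.wrapped()
            hits = np.flatnonzero(w < 90.0)
            assert hits.size, "expected an event within 8 MFPT"
            times.append(series.times[hits[0]])
        rate = 1.0 / np.mean(times)
        assert 1.0 / 1.5 < rate * mfpt < 1.5


class TestTrajectorySeries:
    def test_roundtrip(self, double_well_84, quick_cfg, tmp_path):
        series = simulate_overdamped(
            double_well_84, quick_cfg, RestraintSpec(90.0, 0.01)
        )
        path = tmp_path / "series.traj"
        series.write(path)
        back = TrajectorySeries.read(path)
        assert np.allclose(back.omega, series.omega)
        assert back.metadata["restraint"].reference_omega == 90.0
        assert back.metadata["restraint"].force_constant == 0.01

    def test_validation(self):
        with pytest.raises(ValueError):
            TrajectorySeries(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            TrajectorySeries(np.array([0.0, 0.0]), np.array([1.0, 2.0]))


class TestModeEnsembles:
    def test_exact_linear_relation_without_noise(self, rng):
        planted = rng.normal(size=30)
        planted /= np.linalg.norm(planted)
        stack = generate_mode_ensembles(
            10, np.linspace(0, 180, 5), 20, planted_mode=planted,
            coupling=0.02, noise_modes=0, noise_sd=0.0, jitter_sd=0.0, seed=21,
        )
        x = stack.masked()
        proj = (x - x.mean(axis=0)) @ planted
        rho = np.corrcoef(proj, stack.frame_labels)[0, 1]
        assert abs(rho) == pytest.approx(1.0, abs=1e-12)

    def test_zero_coupling_has_no_linear_signal(self):
        from allokin.functional_modes import functional_pc, multiensemble_pca

        stack = generate_mode_ensembles(
            50, np.linspace(0, 180, 10), 50, coupling=0.0,
            noise_modes=5, noise_sd=1.0, jitter_sd=0.1, seed=22,
        )
        modes, _ = multiensemble_pca(stack)
        best = functional_pc(modes, top_n=10)
        assert abs(best.rho) < 0.2
        assert best.low_signal

    def test_label_and_mask_validation(self, rng):
        stack = generate_mode_ensembles(5, [0.0, 90.0], 3, seed=23)
        with pytest.raises(ValueError):
            type(stack)(
                stack.coordinates, stack.frame_labels[:-1],
                stack.atom_mask, stack.reference_structure,
            )
        with pytest.raises(ValueError):
            type(stack)(
                stack.coordinates, stack.frame_labels,
                np.array([99]), stack.reference_structure,
            )

    def test_stack_roundtrip(self, tmp_path):
        stack = generate_mode_ensembles(5, [0.0, 90.0], 3, seed=24)
        prefix = tmp_path / "stack"
        stack.save(prefix)
        back = type(stack).load(prefix)
        assert np.allclose(back.coordinates, stack.coordinates)
        assert np.allclose(back.frame_labels, stack.frame_labels)
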