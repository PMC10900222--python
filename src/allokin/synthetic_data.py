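"""Synthetic ground-truth inputs for the isomerization analysis pipeline.

Two families of inputs are generated:

* one-dimensional overdamped (Brownian) trajectories of the prolyl torsion
  angle omega on a periodic dihedral potential, restrained (umbrella
  windows) or free (escape replicas), with the barrier term optionally
  scaled by a factor alpha in (0, 1];
* pseudo-structure conformational ensembles in which one planted
  collective mode varies linearly with each umbrella window's reference
  omega, for testing collective-mode detection.

The torsional double well has minima near 0 deg (cis) and 180 deg (trans)
and, with the single standard term (n=2, V2, gamma=180 deg), barrier
maxima of height V2 at +/-90 deg.  Angles are wrapped to [-90, 270) so
both wells and the studied barrier at ~90 deg are interior to the
interval; the equivalent pathway through 270 deg is outside the modelled
range (escape simulations place a reflecting wall there by default, see
:func:`generate_escape_replicas`).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from . import _kernels
from .constants import DEFAULT_TEMPERATURE, beta as _beta

_DEG = math.pi / 180.0

#: default umbrella window references: -30 to 210 deg in 5 deg increments
DEFAULT_WINDOW_REFS = tuple(float(x) for x in range(-30, 211, 5))

#: default production restraint force constant, kcal mol^-1 deg^-2
DEFAULT_PRODUCTION_K = 0.01


def wrap_angle(omega):
    """Wrap angles (degrees) into the canonical interval [-90, 270)."""
    return ((np.asarray(omega, dtype=float) + 90.0) % 360.0) - 90.0


def angle_difference(a, b):
    """Minimum-image difference a - b in degrees, in [-180, 180)."""
    return ((np.asarray(a, dtype=float) - b + 180.0) % 360.0) - 180.0


def derive_seed(parent: int, index: int) -> int:
    """Independent child seed from a parent seed, stable across runs."""
    ss = np.random.SeedSequence(entropy=int(parent), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class TorsionPotential:
    """Periodic dihedral potential with a scalable barrier term.

    ``terms`` are (periodicity n, amplitude V_n in kcal/mol, phase gamma in
    degrees) triples contributing alpha * (V_n/2) * (1 + cos(n*phi - gamma)).
    ``background`` terms follow the same form but are never scaled by alpha;
    they stand in for the (unmodified) molecular environment and allow
    asymmetric well depths.
    """

    terms: Tuple[Tuple[int, float, float], ...] = ((2, 28.0, 180.0),)
    alpha: float = 1.0
    background: Tuple[Tuple[int, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        for n, v, g in tuple(self.terms) + tuple(self.background):
            if int(n) <= 0 or int(n) != n:
                raise ValueError("periodicity must be a positive integer")
            if not (math.isfinite(v) and math.isfinite(g)):
                raise ValueError("amplitude and phase must be finite")

    def scaled(self, alpha: float) -> "TorsionPotential":
        return replace(self, alpha=alpha)


def potential_energy(pot: TorsionPotential, phi) -> np.ndarray | float:
    """Dihedral energy (kcal/mol) at angle(s) phi (degrees)."""
    phi = np.asarray(phi, dtype=float)
    e = np.zeros_like(phi)
    for n, v, g in pot.terms:
        e += pot.alpha * 0.5 * v * (1.0 + np.cos(_DEG * (n * phi - g)))
    for n, v, g in pot.background:
        e += 0.5 * v * (1.0 + np.cos(_DEG * (n * phi - g)))
    return e if e.ndim else float(e)


def potential_gradient(pot: TorsionPotential, phi) -> np.ndarray | float:
    """dV/dphi (kcal mol^-1 deg^-1) at angle(s) phi (degrees)."""
    phi = np.asarray(phi, dtype=float)
    g_tot = np.zeros_like(phi)
    for n, v, g in pot.terms:
        g_tot += -pot.alpha * 0.5 * v * n * _DEG * np.sin(_DEG * (n * phi - g))
    for n, v, g in pot.background:
        g_tot += -0.5 * v * n * _DEG * np.sin(_DEG * (n * phi - g))
    return g_tot if g_tot.ndim else float(g_tot)


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic dihedral restraint 0.5 * k * d(omega, ref)^2."""

    reference_omega: float
    force_constant: float  # kcal mol^-1 deg^-2

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")

    def energy(self, omega) -> np.ndarray | float:
        d = angle_difference(omega, self.reference_omega)
        e = 0.5 * self.force_constant * d**2
        return e if np.ndim(e) else float(e)


@dataclass(frozen=True)
class BrownianConfig:
    """Configuration of the overdamped integrator.

    The per-step RMS displacement sqrt(2 * D * dt) must stay below 1 deg;
    violating the guard raises at construction.
    """

    d_true: float  # deg^2 / s
    timestep: float  # s
    n_steps: int
    save_stride: int = 1
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d_true, self.timestep, self.temperature) <= 0:
            raise ValueError("d_true, timestep and temperature must be positive")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be positive integers")
        if self.rms_step >= 1.0:
            raise ValueError(
                f"per-step RMS displacement sqrt(2 D dt) = {self.rms_step:.3f} deg "
                "must be < 1 deg; reduce the timestep"
            )

    @property
    def rms_step(self) -> float:
        return math.sqrt(2.0 * self.d_true * self.timestep)


@dataclass
class TrajectorySeries:
    """A uniformly sampled omega(t) series with provenance metadata.

    ``omega`` is stored unwrapped (continuous on the real line) so that
    displacement statistics remain meaningful; :meth:`wrapped` maps onto
    the canonical [-90, 270) interval used by histograms and event
    detection.
    """

    times: np.ndarray  # s
    omega: np.ndarray  # degrees, unwrapped
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.times.shape != self.omega.shape or self.times.ndim != 1:
            raise ValueError("times and omega must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise ValueError("a trajectory needs at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def wrapped(self) -> np.ndarray:
        return wrap_angle(self.omega)

    def truncated(self, t_max: float) -> "TrajectorySeries":
        n = int(np.searchsorted(self.times, t_max, side="right"))
        n = max(n, 2)
        return TrajectorySeries(self.times[:n], self.omega[:n], dict(self.metadata))

    # -- delimited-text round trip -------------------------------------
    _HEADER_KEYS = ("alpha", "dt_s", "seed", "restraint_ref_deg", "restraint_k")

    def write(self, path) -> None:
        meta = self.metadata
        restraint = meta.get("restraint")
        lines = [
            f"# alpha {meta.get('alpha', 1.0)}",
            f"# dt_s {self.dt:.16g}",
            f"# seed {meta.get('seed', 0)}",
        ]
        if restraint is not None:
            lines.append(f"# restraint_ref_deg {restraint.reference_omega:.10g}")
            lines.append(f"# restraint_k {restraint.force_constant:.10g}")
        body = io.StringIO()
        np.savetxt(body, np.column_stack([self.times, self.omega]), fmt="%.10g")
        Path(path).write_text("\n".join(lines) + "\n" + body.getvalue())

    @classmethod
    def read(cls, path) -> "TrajectorySeries":
        meta: dict = {}
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] in cls._HEADER_KEYS:
                    meta[parts[0]] = float(parts[1])
                continue
            rows.append([float(x) for x in line.split()])
        arr = np.asarray(rows, dtype=float)
        out_meta = {"alpha": meta.get("alpha", 1.0), "seed": int(meta.get("seed", 0))}
        if "restraint_ref_deg" in meta:
            out_meta["restraint"] = RestraintSpec(
                meta["restraint_ref_deg"], meta.get("restraint_k", 0.0)
            )
        return cls(arr[:, 0], arr[:, 1], out_meta)


def _run_kernel(
    pot: TorsionPotential,
    cfg: BrownianConfig,
    restraint: Optional[RestraintSpec],
    initial_omega: float,
    seed: int,
    reflect_hi: float = math.nan,
    reflect_lo: float = math.nan,
    stop_ts: float = math.nan,
    stop_dir: int = 0,
) -> Tuple[np.ndarray, int]:
    b = _beta(cfg.temperature)
    bddt = b * cfg.d_true * cfg.timestep
    terms = [(n, pot.alpha * v, g) for n, v, g in pot.terms]
    terms += [(n, v, g) for n, v, g in pot.background]
    drift_coef = np.array([bddt * 0.5 * v * n * _DEG for n, v, g in terms])
    term_n = np.array([float(n) for n, _, _ in terms])
    term_phase = np.array([g for _, _, g in terms])
    if restraint is not None and restraint.force_constant > 0:
        r_coef = bddt * restraint.force_constant
        r_ref = restraint.reference_omega
    else:
        r_coef, r_ref = 0.0, 0.0
    n_save = cfg.n_steps // cfg.save_stride
    out = np.empty(n_save + 1)
    n_done = _kernels.em_run(
        float(initial_omega),
        n_save,
        cfg.save_stride,
        drift_coef,
        term_n,
        term_phase,
        r_coef,
        r_ref,
        cfg.rms_step,
        int(seed),
        reflect_hi,
        reflect_lo,
        stop_ts,
        stop_dir,
        out,
    )
    return out[: n_done + 1], n_done


def simulate_overdamped(
    pot: TorsionPotential,
    cfg: BrownianConfig,
    restraint: Optional[RestraintSpec] = None,
    initial_omega: Optional[float] = None,
    reflect_hi: float = math.nan,
    reflect_lo: float = math.nan,
    stop_ts: float = math.nan,
    stop_direction: int = 0,
) -> TrajectorySeries:
    """Integrate the overdamped Langevin equation on the torsion potential.

    Euler-Maruyama update with drift -beta*D*dV/domega*dt and noise
    sqrt(2 D dt); the optional restraint adds its harmonic gradient.  The
    trajectory is reproducible bit-for-bit from ``cfg.seed``.  Optional
    reflecting walls and an early-stop threshold (used by escape replicas)
    act on the evolving angle; stopping is resolved at save resolution.
    """
    if initial_omega is None:
        initial_omega = restraint.reference_omega if restraint is not None else 180.0
    omega, n_done = _run_kernel(
        pot,
        cfg,
        restraint,
        initial_omega,
        cfg.seed,
        reflect_hi=reflect_hi,
        reflect_lo=reflect_lo,
        stop_ts=stop_ts,
        stop_dir=stop_direction,
    )
    dt_save = cfg.timestep * cfg.save_stride
    times = np.arange(n_done + 1) * dt_save
    meta = {
        "alpha": pot.alpha,
        "seed": cfg.seed,
        "dt": dt_save,
        "restraint": restraint,
        "d_true": cfg.d_true,
        "temperature": cfg.temperature,
    }
    return TrajectorySeries(times, omega, meta)


def generate_umbrella_set(
    pot: TorsionPotential,
    cfg: BrownianConfig,
    window_refs: Optional[Sequence[float]] = None,
    k_production: float = DEFAULT_PRODUCTION_K,
) -> List[Tuple[RestraintSpec, TrajectorySeries]]:
    """Chained umbrella-sampling windows along omega.

    One restrained trajectory per reference angle; window i+1 starts from
    the final state of window i, mirroring sequential window generation.
    Defaults: 49 references from -30 to 210 deg in 5 deg steps and a
    production force constant of 0.01 kcal mol^-1 deg^-2.
    """
    if window_refs is None:
        window_refs = DEFAULT_WINDOW_REFS
    if len(window_refs) == 0:
        raise ValueError("window_refs must be nonempty")
    windows = []
    state = float(window_refs[0])
    for i, ref in enumerate(window_refs):
        restraint = RestraintSpec(float(ref), k_production)
        seed_i = derive_seed(cfg.seed, i)
        omega, n_done = _run_kernel(pot, cfg, restraint, state, seed_i)
        dt_save = cfg.timestep * cfg.save_stride
        series = TrajectorySeries(
            np.arange(n_done + 1) * dt_save,
            omega,
            {
                "alpha": pot.alpha,
                "seed": seed_i,
                "dt": dt_save,
                "restraint": restraint,
                "d_true": cfg.d_true,
                "temperature": cfg.temperature,
            },
        )
        windows.append((restraint, series))
        state = float(omega[-1])
    return windows


def generate_escape_replicas(
    pot: TorsionPotential,
    n_replicas: int,
    cfg: BrownianConfig,
    start: float = 180.0,
    omega_ts: float = 90.0,
    direction: str = "trans_to_cis",
    reflect_hi: float = 270.0,
) -> List[TrajectorySeries]:
    """Independent free (unrestrained) replicas started in the trans well.

    Each replica runs until the wrapped angle first crosses ``omega_ts``
    in the requested direction (one event per replica) or until
    ``cfg.n_steps`` (censored).  Per-replica seeds are derived
    independently from ``cfg.seed``.  The default reflecting wall at
    270 deg closes the second, symmetry-equivalent exit of the synthetic
    double well so that escape proceeds over a single saddle, as in the
    modelled single-pathway reaction; pass ``reflect_hi=math.nan`` to
    allow both pathways.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    stop_dir = {"trans_to_cis": 1, "cis_to_trans": -1}[direction]
    replicas = []
    for r in range(n_replicas):
        seed_r = derive_seed(cfg.seed, r)
        cfg_r = replace(cfg, seed=seed_r)
        series = simulate_overdamped(
            pot,
            cfg_r,
            initial_omega=start,
            reflect_hi=reflect_hi,
            stop_ts=omega_ts,
            stop_direction=stop_dir,
        )
        series.metadata["replica_id"] = r
        replicas.append(series)
    return replicas


# ---------------------------------------------------------------------------
# pseudo-structure ensembles with a planted collective mode
# ---------------------------------------------------------------------------


@dataclass
class EnsembleStack:
    """Labelled conformational ensembles pooled across umbrella windows.

    ``coordinates`` has shape (frames, atoms, 3) in Angstrom;
    ``frame_labels`` carries the reference omega of the generating window;
    ``atom_mask`` lists atom indices used for superposition/analysis;
    ``reference_structure`` is a biotite AtomArray.
    """

    coordinates: np.ndarray
    frame_labels: np.ndarray
    atom_mask: np.ndarray
    reference_structure: bst.AtomArray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.frame_labels = np.asarray(self.frame_labels, dtype=float)
        self.atom_mask = np.asarray(self.atom_mask, dtype=int)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if len(self.frame_labels) != self.coordinates.shape[0]:
            raise ValueError("every frame needs a label")
        n_atoms = self.coordinates.shape[1]
        if self.atom_mask.size == 0:
            raise ValueError("atom_mask must be nonempty")
        if self.atom_mask.min() < 0 or self.atom_mask.max() >= n_atoms:
            raise ValueError("atom_mask indices out of bounds")
        if len(np.unique(self.frame_labels)) < 2:
            raise ValueError("need at least two distinct frame labels")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def masked(self) -> np.ndarray:
        """Masked coordinates flattened to (frames, 3*m)."""
        sub = self.coordinates[:, self.atom_mask, :]
        return sub.reshape(self.n_frames, -1)

    def save(self, prefix) -> None:
        """Write coords (.npy), labels (.labels.txt) and reference (.pdb)."""
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.coordinates)
        np.savetxt(
            prefix.with_suffix(".labels.txt"),
            np.column_stack([np.arange(self.n_frames), self.frame_labels]),
            fmt=["%d", "%.6f"],
            header="frame_index omega_ref_deg",
        )
        np.savetxt(prefix.with_suffix(".mask.txt"), self.atom_mask, fmt="%d")
        pdb = PDBFile()
        pdb.set_structure(self.reference_structure)
        pdb.write(str(prefix.with_suffix(".pdb")))

    @classmethod
    def load(cls, prefix) -> "EnsembleStack":
        prefix = Path(prefix)
        coords = np.load(prefix.with_suffix(".npy"))
        labels = np.loadtxt(prefix.with_suffix(".labels.txt"))[:, 1]
        mask = np.loadtxt(prefix.with_suffix(".mask.txt"), dtype=int).reshape(-1)
        ref = PDBFile.read(str(prefix.with_suffix(".pdb"))).get_structure(model=1)
        return cls(coords, labels, mask, ref)


def _synthetic_reference(n_atoms: int, rng: np.random.Generator) -> bst.AtomArray:
    """A synthetic CA-only pseudo-structure (not derived from any real PDB)."""
    atoms = bst.AtomArray(n_atoms)
    radius = 2.0 * n_atoms ** (1.0 / 3.0)
    atoms.coord = rng.normal(scale=radius, size=(n_atoms, 3)).astype(np.float32)
    atoms.chain_id[:] = "A"
    atoms.res_id[:] = np.arange(1, n_atoms + 1)
    atoms.res_name[:] = "GLY"
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    return atoms


def _orthonormal_noise_modes(
    planted: np.ndarray, n_modes: int, rng: np.random.Generator
) -> np.ndarray:
    dim = planted.size
    basis = [planted]
    modes = []
    for _ in range(n_modes):
        v = rng.normal(size=dim)
        for b in basis:
            v -= np.dot(v, b) * b
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError("cannot orthonormalize noise modes against planted mode")
        v /= nv
        basis.append(v)
        modes.append(v)
    return np.array(modes) if modes else np.empty((0, dim))


def generate_mode_ensembles(
    n_atoms: int,
    window_refs: Sequence[float],
    frames_per_window: int,
    planted_mode: Optional[np.ndarray] = None,
    coupling: float = 0.015,
    noise_modes: int = 5,
    noise_sd: float = 1.0,
    jitter_sd: float = 0.1,
    seed: int = 0,
) -> EnsembleStack:
    """Pseudo-structure ensembles with one label-coupled collective mode.

    Each frame is the reference structure displaced by
    ``coupling * (omega_ref - mean(omega_ref))`` along the planted unit
    mode, plus Gaussian random amplitudes along ``noise_modes`` directions
    orthonormal to it (SD ``noise_sd`` Angstrom each), plus isotropic
    per-atom jitter.  Frame labels are the window references.
    """
    rng = np.random.default_rng(seed)
    ref = _synthetic_reference(n_atoms, rng)
    dim = 3 * n_atoms
    if planted_mode is None:
        planted_mode = rng.normal(size=dim)
    planted_mode = np.asarray(planted_mode, dtype=float)
    planted_mode = planted_mode / np.linalg.norm(planted_mode)
    noise = _orthonormal_noise_modes(planted_mode, noise_modes, rng)

    refs = np.asarray(window_refs, dtype=float)
    labels = np.repeat(refs, frames_per_window)
    n_frames = labels.size
    signal = coupling * (labels - labels.mean())
    disp = np.outer(signal, planted_mode)
    if noise_modes:
        amps = rng.normal(scale=noise_sd, size=(n_frames, noise_modes))
        disp += amps @ noise
    disp += rng.normal(scale=jitter_sd, size=(n_frames, dim))
    coords = ref.coord[None, :, :].astype(float) + disp.reshape(n_frames, n_atoms, 3)
    return EnsembleStack(
        coordinates=coords,
        frame_labels=labels,
        atom_mask=np.arange(n_atoms),
        reference_structure=ref,
    )
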