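"""Function-correlated collective motions in pooled conformational ensembles.

Two detectors operate on ensembles pooled over umbrella windows, with each
frame labelled by its window's reference omega:

* multiensemble PCA diagonalizes the pooled Cartesian covariance of the
  masked atoms; the "functional PC" is the component whose per-frame
  projection correlates best (Pearson rho) with omega — not necessarily
  PC1;
* multiensemble PLS-FMA regresses omega on the centered coordinates with
  partial least squares (PLS1); the functional mode is the unit-normalized
  coefficient vector, and the component count is chosen by k-fold
  cross-validation maximizing the test-set correlation.

Frames are first rigid-body superposed (optimal least-squares rotation,
Kabsch) on the masked atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GroupKFold, KFold

from .synthetic_data import EnsembleStack

#: atoms used for superposition and covariance in protein ensembles
DEFAULT_ATOM_NAMES = ("N", "CA", "C", "O", "CB")


@dataclass
class ModeResult:
    """A collective-mode vector with its functional correlation.

    ``vector`` is a unit-norm loading of length 3*m over the masked
    atoms; ``rho`` the Pearson correlation between the per-frame
    projection (PCA) or model prediction (PLS-FMA) and omega; ``sigma``
    the SD of conformations along the mode in Angstrom.
    """

    vector: np.ndarray
    rho: float
    sigma: float
    method: str  # "pca" | "pls_fma"
    variance_fraction: Optional[float] = None
    n_components: Optional[int] = None
    index: Optional[int] = None  # 1-based PC index
    low_signal: bool = False

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        norm = np.linalg.norm(self.vector)
        if not math.isclose(norm, 1.0, rel_tol=1e-8):
            raise ValueError("mode vector must have unit norm")
        if not -1.0 - 1e-9 <= self.rho <= 1.0 + 1e-9:
            raise ValueError("rho must lie in [-1, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def mask_from_atom_names(
    stack: EnsembleStack, names: Sequence[str] = DEFAULT_ATOM_NAMES
) -> np.ndarray:
    """Atom indices whose reference-structure atom name is in ``names``."""
    atom_names = stack.reference_structure.atom_name
    return np.flatnonzero(np.isin(atom_names, list(names)))


def _kabsch_apply(coords: np.ndarray, ref: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Superpose one frame (atoms, 3) onto ref over masked atoms."""
    sub = coords[mask]
    sub_ref = ref[mask]
    c_mob = sub.mean(axis=0)
    c_ref = sub_ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(sub_ref - c_ref, sub - c_mob)
    return rot.apply(coords - c_mob) + c_ref


def superpose_ensemble(
    stack: EnsembleStack, reference: Optional[int] = None, refine: int = 1
) -> EnsembleStack:
    """Rigid-body superpose every frame onto a common reference.

    ``reference`` selects a frame index; the default uses the mean
    structure (frames are first aligned to frame 0, averaged, then
    aligned to that mean, repeated ``refine`` times).  Rotations are the
    optimal least-squares (Kabsch) solutions over the masked atoms and
    are applied to all atoms.
    """
    mask = stack.atom_mask
    first = stack.coordinates[0][mask]
    centered = first - first.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("masked atoms are degenerate (collinear); cannot superpose")

    coords = stack.coordinates
    if reference is not None:
        ref = coords[reference]
        aligned = np.array([_kabsch_apply(f, ref, mask) for f in coords])
    else:
        ref = coords[0]
        aligned = np.array([_kabsch_apply(f, ref, mask) for f in coords])
        for _ in range(refine):
            ref = aligned.mean(axis=0)
            aligned = np.array([_kabsch_apply(f, ref, mask) for f in aligned])
    return EnsembleStack(
        aligned, stack.frame_labels.copy(), mask.copy(), stack.reference_structure
    )


def masked_rmsd(stack: EnsembleStack, reference: np.ndarray) -> np.ndarray:
    """Per-frame RMSD to a reference (atoms, 3) over the masked atoms."""
    d = stack.coordinates[:, stack.atom_mask, :] - reference[stack.atom_mask]
    return np.sqrt((d**2).sum(axis=(1, 2)) / len(stack.atom_mask))


def multiensemble_pca(
    stack: EnsembleStack,
) -> Tuple[List[ModeResult], pd.DataFrame]:
    """Eigen-decomposition of the pooled masked-coordinate covariance.

    Returns modes sorted by descending eigenvalue (each already carrying
    its Pearson correlation with the frame labels) and a scree table.
    Rank-deficient directions (eigenvalue <= 0 within tolerance) are
    truncated.
    """
    x = stack.masked()
    labels = stack.frame_labels
    if x.shape[0] < 2:
        raise ValueError("need at least two frames")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(evals[0], 0) * 1e-12
    n_trunc = int((~keep).sum())
    evals, evecs = evals[keep], evecs[:, keep]
    total = evals.sum()
    modes = []
    for i in range(len(evals)):
        v = evecs[:, i]
        proj = xc @ v
        rho = pearsonr(proj, labels)[0] if np.std(proj) > 0 else 0.0
        modes.append(
            ModeResult(
                vector=v,
                rho=float(rho),
                sigma=float(math.sqrt(max(evals[i], 0.0))),
                method="pca",
                variance_fraction=float(evals[i] / total),
                index=i + 1,
            )
        )
    scree = pd.DataFrame(
        {
            "pc": np.arange(1, len(evals) + 1),
            "eigenvalue": evals,
            "variance_fraction": evals / total,
            "cumulative_fraction": np.cumsum(evals) / total,
        }
    )
    scree.attrs["truncated_directions"] = n_trunc
    return modes, scree


def functional_pc(modes: Sequence[ModeResult], top_n: int = 10) -> ModeResult:
    """The PC among the first ``top_n`` maximizing |rho| with omega."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    pool = modes[: min(top_n, len(modes))]
    best = max(pool, key=lambda m: abs(m.rho))
    if abs(best.rho) < 0.2:
        best = _dc_replace(best, low_signal=True)
    return best


@dataclass
class FmaModel:
    """Fitted multiensemble PLS-FMA model (predicts omega from coordinates)."""

    pls: PLSRegression
    mode: ModeResult

    def predict(self, stack: EnsembleStack) -> np.ndarray:
        return self.pls.predict(stack.masked()).ravel()


def pls_fma(
    stack: EnsembleStack, labels: Optional[np.ndarray] = None, n_components: int = 1
) -> FmaModel:
    """PLS1 regression of omega on the masked coordinates.

    The functional mode is the unit-normalized regression coefficient
    vector mapped back to coordinate space; ``rho`` is the Pearson
    correlation between model predictions and the labels.
    """
    x = stack.masked()
    y = stack.frame_labels if labels is None else np.asarray(labels, dtype=float)
    rank = min(x.shape[0] - 1, x.shape[1])
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(x, y)
    coef = pls.coef_.reshape(-1)
    norm = np.linalg.norm(coef)
    if norm == 0:
        raise ValueError("PLS produced a null coefficient vector")
    vector = coef / norm
    yhat = pls.predict(x).ravel()
    rho = pearsonr(yhat, y)[0] if np.std(yhat) > 0 else 0.0
    xc = x - x.mean(axis=0)
    sigma = float(np.std(xc @ vector))
    mode = ModeResult(
        vector=vector, rho=float(rho), sigma=sigma,
        method="pls_fma", n_components=n_components,
    )
    return FmaModel(pls=pls, mode=mode)


def cross_validate_components(
    stack: EnsembleStack,
    labels: Optional[np.ndarray] = None,
    folds: int = 10,
    n_range: Optional[Sequence[int]] = None,
    seed: int = 0,
    by_window: bool = False,
) -> Tuple[FmaModel, pd.DataFrame]:
    """Choose the PLS component count by k-fold cross-validation.

    For each candidate n the mean test-fold Pearson correlation between
    predicted and reference omega is recorded; the final model is refit
    on all frames with the argmax n.  ``by_window=True`` partitions by
    umbrella window (grouped folds) instead of random frames.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    x = stack.masked()
    y = stack.frame_labels if labels is None else np.asarray(labels, dtype=float)
    n_frames = x.shape[0]
    if n_frames // folds < 2:
        raise ValueError("folds leave fewer than 2 frames per test set")
    max_n = min(n_frames - 1, x.shape[1], 10)
    candidates = list(n_range) if n_range is not None else list(range(1, max_n + 1))

    if by_window:
        splitter = GroupKFold(n_splits=folds)
        split_iter = list(splitter.split(x, y, groups=y))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(x))

    rows = []
    for n in candidates:
        scores = []
        for train, test in split_iter:
            rank = min(len(train) - 1, x.shape[1])
            if n > rank:
                scores.append(np.nan)
                continue
            pls = PLSRegression(n_components=n, scale=False)
            pls.fit(x[train], y[train])
            pred = pls.predict(x[test]).ravel()
            if np.std(pred) == 0 or np.std(y[test]) == 0:
                scores.append(0.0)
            else:
                scores.append(pearsonr(pred, y[test])[0])
        rows.append({"n_components": n, "cv_rho": float(np.nanmean(scores))})
    table = pd.DataFrame(rows)
    best_n = int(table.loc[table["cv_rho"].idxmax(), "n_components"])
    model = pls_fma(stack, y, n_components=best_n)
    model.mode.n_components = best_n
    table.attrs["optimal_n"] = best_n
    table.attrs["cv_rho_at_optimum"] = float(table["cv_rho"].max())
    return model, table


def mode_sigma(stack: EnsembleStack, mode: np.ndarray) -> float:
    """SD (Angstrom) of per-frame scalar projections onto the mode."""
    x = stack.masked()
    xc = x - x.mean(axis=0)
    proj = xc @ (np.asarray(mode, dtype=float))
    return float(np.std(proj))


def export_mode_field(
    mode: ModeResult,
    reference_structure,
    scale: float = 1.0,
    min_arrow: float = 1.0,
    atom_indices: Optional[np.ndarray] = None,
    path=None,
) -> pd.DataFrame:
    """Per-atom displacement arrows for porcupine-style rendering.

    Arrow = scale * per-atom loading; arrows shorter than ``min_arrow``
    Angstrom are omitted.  Records are ``atom_index x y z dx dy dz``.
    """
    disp = scale * mode.vector.reshape(-1, 3)
    coords = reference_structure.coord
    if atom_indices is None:
        atom_indices = np.arange(len(disp))
    if len(atom_indices) != len(disp):
        raise ValueError("atom count does not match mode length")
    origin = np.asarray(coords)[atom_indices]
    lengths = np.linalg.norm(disp, axis=1)
    keep = lengths >= min_arrow
    table = pd.DataFrame(
        {
            "atom_index": np.asarray(atom_indices)[keep],
            "x": origin[keep, 0], "y": origin[keep, 1], "z": origin[keep, 2],
            "dx": disp[keep, 0], "dy": disp[keep, 1], "dz": disp[keep, 2],
        }
    )
    if path is not None:
        table.to_csv(path, sep=" ", index=False)
    return table
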