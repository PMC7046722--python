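"""Correlated-motion statistics: cross-correlation maps and covariance PCA.

The dynamic cross-correlation matrix (DCCM) entry for atoms i, j is

    c_ij = <d_i . d_j> / sqrt(<d_i . d_i> <d_j . d_j>)

where d_i(t) is the vector displacement of atom i from its time-mean
position after superposing every frame onto the iterative mean structure of
the analysis selection, and <.> is the time average.  Entries lie in
[-1, 1] with an exactly unit diagonal.

Essential-dynamics PCA eigendecomposes the 3n x 3n positional covariance of
the same superposed coordinates; the trace (Å²) measures total fluctuation
and leading eigenvectors are the dominant collective motions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import AtomSelection, Structure, Trajectory
from .geometry import ProfileResult, _selection_residue_keys, mean_structure

logger = logging.getLogger(__name__)


@dataclass
class DCCMatrix:
    """Symmetric residue-by-residue correlation matrix with unit diagonal."""

    matrix: np.ndarray
    selection_label: str
    n_frames_used: int
    resids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    missing_mask: np.ndarray | None = None   # True where variance was zero

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PCAResult:
    """Eigendecomposition of the 3n x 3n coordinate covariance matrix."""

    eigenvalues: np.ndarray        # Å², descending, clipped at 0
    eigenvectors: np.ndarray       # columns, orthonormal 3n-vectors
    trace: float                   # Å²
    variance_fractions: np.ndarray
    mean_structure: np.ndarray     # (n_sel, 3)
    selection_label: str = ""

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def _superposed_displacements(traj: Trajectory, selection: AtomSelection,
                              superpose: bool = True,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Frames superposed on the iterative mean; returns (mean, displacements).

    ``superpose=False`` takes the frames as already sharing a common frame
    (the case for generated ensembles with no rigid-body motion): fitting
    onto the mean would otherwise absorb part of the internal fluctuation
    (of order 6/(3n) of the variance, more for spatially localized modes)
    and attenuate planted correlations.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if superpose:
        mean, superposed = mean_structure(traj, selection)
        # re-centre on the mean of the superposed set so <d> = 0 exactly
        mean = superposed.mean(axis=0)
    else:
        superposed = traj.frames[:, selection.indices, :]
        mean = superposed.mean(axis=0)
    return mean, superposed - mean


def dccm(traj: Trajectory, selection: AtomSelection,
         superpose: bool = True) -> DCCMatrix:
    """Dynamic cross-correlation matrix of the selected atoms.

    Zero-variance atoms produce undefined correlations; those rows/columns
    are reported as NaN and flagged in ``missing_mask`` (the diagonal of a
    fluctuating atom is exactly 1).
    """
    _, disp = _superposed_displacements(traj, selection, superpose)
    # <d_i . d_j> over frames
    inner = np.einsum("tix,tjx->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner).copy()
    zero = var <= 0
    if np.any(zero):
        logger.warning("DCCM: %d zero-variance atoms reported as missing",
                       int(zero.sum()))
    denom = np.sqrt(np.outer(np.where(zero, np.nan, var),
                             np.where(zero, np.nan, var)))
    mat = inner / denom
    np.fill_diagonal(mat, np.where(zero, np.nan, 1.0))
    mat = np.clip(mat, -1.0, 1.0, out=mat)
    resids, _ = _selection_residue_keys(traj.topology, selection)
    missing = zero[:, None] | zero[None, :]
    return DCCMatrix(matrix=mat, selection_label=selection.label,
                     n_frames_used=traj.n_frames, resids=resids,
                     missing_mask=missing if np.any(zero) else None)


def dccm_reference_double_loop(traj: Trajectory, selection: AtomSelection,
                               superpose: bool = True) -> np.ndarray:
    """Literal double-loop evaluation of the correlation formula.

    Deliberately naive (explicit loops over atom pairs and frames); kept as
    an independent cross-check of :func:`dccm` on small instances.
    """
    _, disp = _superposed_displacements(traj, selection, superpose)
    n_frames, n, _ = disp.shape
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            num = 0.0
            di2 = 0.0
            dj2 = 0.0
            for t in range(n_frames):
                num += float(np.dot(disp[t, i], disp[t, j]))
                di2 += float(np.dot(disp[t, i], disp[t, i]))
                dj2 += float(np.dot(disp[t, j], disp[t, j]))
            out[i, j] = (num / n_frames) / np.sqrt((di2 / n_frames) * (dj2 / n_frames))
    return out


def pca_covariance(traj: Trajectory, selection: AtomSelection,
                   superpose: bool = True) -> PCAResult:
    """PCA of the 3n-dimensional coordinate covariance (essential dynamics).

    Eigenvalues are clipped at zero (covariance is PSD up to round-off) and
    sorted descending; each eigenvector's largest-magnitude component is
    made positive so outputs are reproducible across LAPACK builds.
    """
    mean, disp = _superposed_displacements(traj, selection, superpose)
    n_frames = disp.shape[0]
    flat = disp.reshape(n_frames, -1)
    cov = flat.T @ flat / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        pivot = np.argmax(np.abs(evecs[:, k]))
        if evecs[pivot, k] < 0:
            evecs[:, k] = -evecs[:, k]
    trace = float(np.trace(cov))
    fractions = evals / evals.sum() if evals.sum() > 0 else np.zeros_like(evals)
    return PCAResult(eigenvalues=evals, eigenvectors=evecs, trace=trace,
                     variance_fractions=fractions, mean_structure=mean,
                     selection_label=selection.label)


def project_onto_pcs(traj: Trajectory, selection: AtomSelection,
                     pca: PCAResult, k: int = 2,
                     superpose: bool = True) -> np.ndarray:
    """Project superposed, mean-centred frames onto the first ``k`` modes.

    Returns an (n_frames, k) array in Å.  On the same data (and the same
    ``superpose`` setting as the fit) the per-mode projection variance
    equals the corresponding eigenvalue.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > pca.n_modes:
        raise ValueError(f"k={k} exceeds {pca.n_modes} available modes")
    from .geometry import superpose_trajectory

    sel = traj.frames[:, selection.indices, :]
    if superpose:
        sel = superpose_trajectory(sel, pca.mean_structure)
    flat = (sel - pca.mean_structure).reshape(traj.n_frames, -1)
    return flat @ pca.eigenvectors[:, :k]


def mode_profile(pca: PCAResult, structure: Structure,
                 selection: AtomSelection, mode: int = 0, scale: float = 2.0,
                 ) -> tuple[ProfileResult, np.ndarray, np.ndarray]:
    """Per-residue displacement magnitude of one PCA mode, plus extremes.

    The profile value for a residue is the Euclidean norm of the mode's
    3-vector at that residue's selected atom; the two returned coordinate
    sets displace the mean structure by ±scale·sqrt(eigenvalue) along the
    mode (the conventional porcupine end-points).
    """
    if mode < 0 or mode >= pca.n_modes:
        raise ValueError(f"mode {mode} out of range")
    vec = pca.eigenvectors[:, mode].reshape(-1, 3)
    mags = np.linalg.norm(vec, axis=1)
    resids, labels = _selection_residue_keys(structure, selection)
    profile = ProfileResult(resids=resids, values=mags, unit="",
                            metric=f"pc{mode + 1}_loading", labels=labels)
    amp = scale * np.sqrt(pca.eigenvalues[mode])
    plus = pca.mean_structure + amp * vec
    minus = pca.mean_structure - amp * vec
    return profile, plus, minus
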