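"""Superposition and per-frame / per-residue structural metrics.

RMSD is reported against a reference after optimal (Kabsch) superposition;
RMSF is measured about the iteratively computed mean structure; Rg is
mass-weighted by default; SASA uses the Shrake-Rupley point-sampling
construction with a deterministic Fibonacci-spiral unit sphere so results
are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import AtomSelection, Structure, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class SeriesResult:
    """Per-frame scalar series (e.g. RMSD(t), Rg(t), total SASA(t))."""

    values: np.ndarray
    unit: str
    metric: str
    selection_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ProfileResult:
    """Per-residue scalars keyed by author residue number."""

    resids: np.ndarray          # author numbering
    values: np.ndarray
    unit: str
    metric: str
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.resids = np.asarray(self.resids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.resids) != len(self.values):
            raise ValueError("resids and values must align")


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where the aligned mobile
    coordinates are ``mobile @ rotation.T + translation`` and ``rmsd`` is the
    weighted least-squares minimum in Å.  The rotation is always proper
    (det = +1): reflections are corrected by flipping the smallest singular
    direction, so a mirror image keeps a nonzero residual RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()

    cm = w @ mobile
    cr = w @ reference
    x = mobile - cm
    y = reference - cr
    if np.allclose(x, 0) and np.allclose(y, 0):
        logger.warning("degenerate superposition: all points coincident")
        return np.eye(3), cr - cm, 0.0

    cov = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    # residual evaluated directly: the singular-value identity loses ~8
    # digits to cancellation for near-exact fits
    resid = x @ rot.T - y
    rmsd = float(np.sqrt(np.sum(w[:, None] * resid ** 2)))
    trans = cr - rot @ cm
    return rot, trans, rmsd


def apply_superposition(coords: np.ndarray, rotation: np.ndarray,
                        translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def superpose_trajectory(traj_frames: np.ndarray, reference: np.ndarray,
                         fit_indices: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame onto ``reference`` (fit on ``fit_indices``)."""
    out = np.empty_like(traj_frames)
    for t in range(traj_frames.shape[0]):
        fit_from = traj_frames[t] if fit_indices is None else traj_frames[t][fit_indices]
        rot, trans, _ = kabsch_superpose(fit_from, reference)
        out[t] = apply_superposition(traj_frames[t], rot, trans)
    return out


def mean_structure(traj: Trajectory, selection: AtomSelection,
                   max_passes: int = 20, tol: float = 1e-10,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Iterative mean of the selected coordinates over frames.

    Pass 1 superposes onto the first frame and averages; each later pass
    re-superposes onto the running mean, until the mean moves by less than
    ``tol`` Å RMS (equilibrium-like ensembles converge in 2-3 passes).  The
    converged mean makes derived quantities (RMSF, DCCM, PCA) independent
    of frame order up to a global rotation.  Returns ``(mean, superposed)``
    where ``superposed`` is (n_frames, n_sel, 3).
    """
    sel = traj.frames[:, selection.indices, :]
    ref = sel[0]
    superposed = sel
    for _ in range(max_passes):
        superposed = superpose_trajectory(sel, ref)
        new_ref = superposed.mean(axis=0)
        shift = np.sqrt(np.mean((new_ref - ref) ** 2))
        ref = new_ref
        if shift < tol:
            break
    return ref, superposed


# ---------------------------------------------------------------------------
# Series metrics
# ---------------------------------------------------------------------------

def rmsd_series(traj: Trajectory, reference: np.ndarray,
                selection: AtomSelection) -> SeriesResult:
    """Per-frame minimum RMSD of the selected atoms against ``reference``."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (len(selection), 3):
        raise ValueError("reference size does not match selection")
    vals = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        _, _, vals[t] = kabsch_superpose(traj.frames[t, selection.indices],
                                         reference)
    return SeriesResult(values=vals, unit="Å", metric="rmsd",
                        selection_label=selection.label)


def rmsf_profile(traj: Trajectory, selection: AtomSelection,
                 superpose: bool = True) -> ProfileResult:
    """Root-mean-square fluctuation of each selected atom about the mean.

    Frames are first superposed onto the two-pass iterative mean structure;
    RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>_t).  One value per selected atom,
    keyed by the atom's author residue number (one atom per residue in the
    usual Cα usage).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if superpose:
        mean, superposed = mean_structure(traj, selection)
    else:
        superposed = traj.frames[:, selection.indices, :]
        mean = superposed.mean(axis=0)
    disp = superposed - superposed.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum(disp ** 2, axis=2), axis=0))
    resids, labels = _selection_residue_keys(traj.topology, selection)
    return ProfileResult(resids=resids, values=rmsf, unit="Å", metric="rmsf",
                         labels=labels)


def _selection_residue_keys(structure: Structure, selection: AtomSelection,
                            ) -> tuple[np.ndarray, list[str]]:
    resids, labels = [], []
    for pos in selection.indices:
        res = structure.residue_of_atom(int(pos))
        resids.append(res[1])
        labels.append(structure.residue_label(res))
    return np.asarray(resids), labels


def rg_series(traj: Trajectory, selection: AtomSelection,
              mass_weighted: bool = True) -> SeriesResult:
    """Radius of gyration per frame, mass-weighted by default.

    Rg(t) = sqrt( sum_i w_i |r_i - r_com|^2 / sum_i w_i ).
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    if mass_weighted:
        w = traj.topology.atom_masses()[selection.indices]
    else:
        w = np.ones(len(selection))
    w = w / w.sum()
    sub = traj.frames[:, selection.indices, :]
    com = np.einsum("i,tij->tj", w, sub)
    d2 = np.sum((sub - com[:, None, :]) ** 2, axis=2)
    vals = np.sqrt(np.einsum("i,ti->t", w, d2))
    return SeriesResult(values=vals, unit="Å", metric="rg",
                        selection_label=selection.label)


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley with deterministic Fibonacci sphere points)
# ---------------------------------------------------------------------------

def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    if n_points < 1:
        raise ValueError("n_points must be positive")
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n_points
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


try:
    from numba import njit as _njit
except ImportError:    # pragma: no cover - numba is an optional accelerator
    _njit = None

if _njit is not None:
    @_njit(cache=True)
    def _sasa_kernel(coords, expanded, sphere, nb_idx, nb_ptr):   # pragma: no cover
        n = coords.shape[0]
        n_points = sphere.shape[0]
        per_atom = np.zeros(n)
        for i in range(n):
            acc = 0
            for k in range(n_points):
                px = coords[i, 0] + expanded[i] * sphere[k, 0]
                py = coords[i, 1] + expanded[i] * sphere[k, 1]
                pz = coords[i, 2] + expanded[i] * sphere[k, 2]
                ok = True
                for p in range(nb_ptr[i], nb_ptr[i + 1]):
                    j = nb_idx[p]
                    dx = px - coords[j, 0]
                    dy = py - coords[j, 1]
                    dz = pz - coords[j, 2]
                    if dx * dx + dy * dy + dz * dz <= expanded[j] * expanded[j]:
                        ok = False
                        break
                if ok:
                    acc += 1
            per_atom[i] = 4.0 * np.pi * expanded[i] ** 2 * acc / n_points
        return per_atom


def sasa(coords: np.ndarray, radii: np.ndarray,
         probe_radius: float = 1.4, n_points: int = 960,
         structure: Structure | None = None,
         ) -> tuple[np.ndarray, ProfileResult | None, float]:
    """Shrake-Rupley solvent-accessible surface area for one frame.

    Each atom's expanded sphere (vdW + probe) is sampled at ``n_points``
    deterministic spiral points; a point is accessible iff it lies outside
    every neighbour's expanded sphere.  Returns per-atom areas (Å²), a
    per-residue profile when a ``structure`` is supplied, and the total.
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60 for a usable sphere sampling")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    expanded = radii + probe_radius
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    if _njit is not None and n > 1:
        # CSR neighbour lists: j can occlude i iff |c_i - c_j| < e_i + e_j,
        # ordered nearest-first so the point loop exits early
        lists = tree.query_ball_point(coords, expanded + max_r)
        nb, ptr = [], [0]
        for i in range(n):
            cand = np.array([j for j in lists[i] if j != i], dtype=np.int64)
            sep = np.linalg.norm(coords[cand] - coords[i], axis=1)
            keep = sep < expanded[i] + expanded[cand]
            cand, sep = cand[keep], sep[keep]
            nb.extend(cand[np.argsort(sep, kind="stable")])
            ptr.append(len(nb))
        per_atom = _sasa_kernel(coords, expanded, sphere,
                                np.array(nb, dtype=np.int64),
                                np.array(ptr, dtype=np.int64))
        return _sasa_package(per_atom, structure)
    per_atom = np.zeros(n)
    for i in range(n):
        neighbours = np.array(
            [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
             if j != i], dtype=int)
        if len(neighbours) == 0:
            per_atom[i] = 4.0 * np.pi * expanded[i] ** 2
            continue
        pts = coords[i] + expanded[i] * sphere
        # nearest occluders first: the surviving point set shrinks fastest
        # and buried atoms terminate after a few neighbours
        sep = np.linalg.norm(coords[neighbours] - coords[i], axis=1)
        neighbours = neighbours[np.argsort(sep, kind="stable")]
        alive = np.arange(n_points)
        for j in neighbours:
            d2 = np.sum((pts[alive] - coords[j]) ** 2, axis=1)
            alive = alive[d2 > expanded[j] ** 2]
            if alive.size == 0:
                break
        per_atom[i] = 4.0 * np.pi * expanded[i] ** 2 * alive.size / n_points
    return _sasa_package(per_atom, structure)


def _sasa_package(per_atom: np.ndarray, structure: Structure | None,
                  ) -> tuple[np.ndarray, ProfileResult | None, float]:
    total = float(per_atom.sum())
    profile = None
    if structure is not None:
        keys, sums, labels = [], {}, {}
        for pos, atom in enumerate(structure.atoms):
            res = structure.residue_of_atom(pos)
            key = (res[3], res[0])
            if key not in sums:
                keys.append(key)
                sums[key] = 0.0
                labels[key] = (res[1], structure.residue_label(res))
            sums[key] += per_atom[pos]
        profile = ProfileResult(
            resids=np.array([labels[k][0] for k in keys]),
            values=np.array([sums[k] for k in keys]),
            unit="Å²", metric="sasa_per_residue",
            labels=[labels[k][1] for k in keys])
    return per_atom, profile, total


def sasa_series(traj: Trajectory, probe_radius: float = 1.4,
                n_points: int = 960) -> SeriesResult:
    """Total SASA per frame."""
    radii = traj.topology.atom_radii()
    vals = np.array([
        sasa(traj.frames[t], radii, probe_radius, n_points)[2]
        for t in range(traj.n_frames)])
    return SeriesResult(values=vals, unit="Å²", metric="sasa_total")


def series_density(series: SeriesResult, n_bins: int = 50,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of a series; densities integrate to 1."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = series.values
    if np.ptp(vals) == 0:
        # constant series: all mass in the central bin of a unit-wide window
        edges = np.linspace(vals[0] - 0.5, vals[0] + 0.5, n_bins + 1)
        density, edges = np.histogram(vals, bins=edges, density=True)
        return edges, density
    density, edges = np.histogram(vals, bins=n_bins, density=True)
    return edges, density
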