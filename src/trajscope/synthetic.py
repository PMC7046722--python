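"""Synthetic structures and trajectories with planted, analytically known
properties.

Each generator is a pure function of its spec and seed: ideal-geometry
backbones (helix, extended, hairpin), stationary Gaussian ensembles with a
planted residue-residue correlation structure, two-state metastable
trajectories with planted basin populations, and a minimal H-bond system
bonded in a prescribed fraction of frames.  Every planted quantity (block
correlation, state populations, bond fraction, fold class) is recoverable
by the corresponding analysis module, which is what the test suite checks.

These are statistical stand-ins for molecular dynamics output: no force
field, no thermostat, no kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Atom, Structure, Trajectory

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.5
_OMEGA = 180.0

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "extended": (-120.0, 120.0),
    "strand": (-139.0, 135.0),
}
# 4-residue chain-reversal turn, tuned once so the flanking strands of the
# hairpin register their backbone hydrogen bonds in the ideal geometry
_HAIRPIN_TURN = [(6.7, 86.7), (82.9, -35.9), (-128.1, 139.0), (-155.3, 180.0)]


def _place_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D after A-B-C."""
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(theta),
                   bond * np.sin(theta) * np.cos(chi),
                   bond * np.sin(theta) * np.sin(chi)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O (+ amide H) coordinates from a dihedral schedule."""
    n_res = len(phi_psi)
    res: list[dict[str, np.ndarray]] = [{} for _ in range(n_res)]
    # seed the first residue in a canonical frame
    res[0]["N"] = np.array([0.0, 0.0, 0.0])
    res[0]["CA"] = np.array([_B_N_CA, 0.0, 0.0])
    th = np.radians(_A_N_CA_C)
    res[0]["C"] = res[0]["CA"] + _B_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i > 0:
            res[i]["N"] = _place_nerf(res[i - 1]["N"], res[i - 1]["CA"],
                                      res[i - 1]["C"], _B_C_N, _A_CA_C_N,
                                      phi_psi[i - 1][1])
            res[i]["CA"] = _place_nerf(res[i - 1]["CA"], res[i - 1]["C"],
                                       res[i]["N"], _B_N_CA, _A_C_N_CA, _OMEGA)
            res[i]["C"] = _place_nerf(res[i - 1]["C"], res[i]["N"],
                                      res[i]["CA"], _B_CA_C, _A_N_CA_C, phi)
        # carbonyl O: anti to the next amide nitrogen (dihedral psi - 180)
        res[i]["O"] = _place_nerf(res[i]["N"], res[i]["CA"], res[i]["C"],
                                  _B_C_O, _A_CA_C_O, psi - 180.0)
    for i in range(1, n_res):
        co = res[i - 1]["C"] - res[i - 1]["O"]
        res[i]["H"] = res[i]["N"] + co / np.linalg.norm(co)
    return res


def make_toy_protein(n_res: int, fold: str = "helix",
                     author_offset: int = 0, chain: str = "A") -> Structure:
    """Ideal-geometry poly-alanine-like backbone (N, CA, C, O, amide H).

    ``fold``: ``helix`` (φ/ψ = −57°/−47°), ``extended`` (−120°/120°), or
    ``hairpin`` (two antiparallel strands joined by a 4-residue turn).
    ``author_offset`` shifts author numbering relative to the 1-based
    sequence index.
    """
    if n_res < 5:
        raise ValueError("need at least 5 residues")
    if fold in ("helix", "extended"):
        schedule = [PHI_PSI[fold]] * n_res
    elif fold == "hairpin":
        if n_res < 10:
            raise ValueError("hairpin needs at least 10 residues")
        n_strand = (n_res - 4) // 2
        schedule = ([PHI_PSI["strand"]] * (n_res - 4 - n_strand)
                    + _HAIRPIN_TURN + [PHI_PSI["strand"]] * n_strand)
    else:
        raise ValueError(f"unknown fold {fold!r}")
    coords = _build_backbone(schedule)
    atoms: list[Atom] = []
    residues = []
    serial = 1
    for i, rec in enumerate(coords, start=1):
        residues.append((i, i + author_offset, "ALA", chain))
        for name in ("N", "H", "CA", "C", "O"):
            if name not in rec:
                continue
            atoms.append(Atom(serial=serial, name=name, element=name[0],
                              residue_index=i, author_resid=i + author_offset,
                              chain=chain, coords=rec[name]))
            serial += 1
    return Structure(atoms=atoms, residues=residues)


@dataclass
class EnsembleSpec:
    """Stationary Gaussian ensemble around a reference structure.

    ``correlation_blocks`` is a list of ``(residues_a, residues_b, rho)``
    (1-based sequence indices): displacements of atoms in ``residues_a``
    correlate with those in ``residues_b`` at ``rho``; within each set the
    correlation is ``|rho|`` so the implied covariance stays positive
    semi-definite.
    """

    reference: Structure
    sigma: float = 0.5                       # Å per coordinate
    correlation_blocks: list[tuple[list[int], list[int], float]] = field(
        default_factory=list)
    n_frames: int = 1000
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        n = self.reference.n_atoms
        res_of = np.array([a.residue_index for a in self.reference.atoms])
        corr = np.eye(n)
        for res_a, res_b, rho in self.correlation_blocks:
            if not -1.0 <= rho <= 1.0:
                raise ValueError("rho must lie in [-1, 1]")
            ia = np.nonzero(np.isin(res_of, list(res_a)))[0]
            ib = np.nonzero(np.isin(res_of, list(res_b)))[0]
            for grp in (ia, ib):
                for x in grp:
                    for y in grp:
                        if x != y:
                            corr[x, y] = abs(rho)
            for x in ia:
                for y in ib:
                    corr[x, y] = corr[y, x] = rho
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError("correlation blocks imply a non-PSD covariance")
        return corr


def make_gaussian_ensemble(spec: EnsembleSpec) -> Trajectory:
    """Frames = reference + correlated Gaussian displacements.

    The planted residue-residue correlation is realized exactly in
    expectation via the Cholesky factor of the implied atom correlation
    matrix, applied identically and independently to x, y and z.  The same
    seed always yields bit-identical frames.
    """
    corr = spec.correlation_matrix()
    # tiny jitter tolerates the PSD boundary (|rho| intra / rho cross)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(corr.shape[0]))
    rng = np.random.default_rng(spec.seed)
    n, t = spec.reference.n_atoms, spec.n_frames
    z = rng.standard_normal((t, 3, n))
    disp = np.einsum("ij,taj->tai", L, z) * spec.sigma
    frames = spec.reference.coords[None, :, :] + np.transpose(disp, (0, 2, 1))
    return Trajectory(topology=spec.reference, frames=frames)


@dataclass
class TwoStateSpec:
    """Two-conformer metastable trajectory with planted populations."""

    conformer_a: np.ndarray
    conformer_b: np.ndarray
    topology: Structure
    p_a: float = 0.7
    jitter: float = 0.1          # Å per coordinate
    n_frames: int = 1000
    seed: int = 0
    assignment: str = "schedule"   # schedule | bernoulli

    def __post_init__(self) -> None:
        self.conformer_a = np.asarray(self.conformer_a, dtype=float)
        self.conformer_b = np.asarray(self.conformer_b, dtype=float)
        if self.conformer_a.shape != self.conformer_b.shape:
            raise ValueError("conformers must have the same atom count")
        if not 0.0 < self.p_a <= 1.0:
            raise ValueError("p_a must be in (0, 1]")
        if self.assignment not in ("schedule", "bernoulli"):
            raise ValueError("assignment must be 'schedule' or 'bernoulli'")


def schedule_mask(n: int, n_on: int) -> np.ndarray:
    """Deterministic, evenly interleaved boolean mask with exactly n_on True."""
    i = np.arange(n)
    return ((i + 1) * n_on) // n - (i * n_on) // n == 1


def make_two_state_trajectory(spec: TwoStateSpec) -> Trajectory:
    """Jittered two-state trajectory.

    Schedule mode visits conformer A in exactly ``round(p_a * n_frames)``
    evenly interleaved frames; Bernoulli mode draws each frame's state
    independently.  Gaussian jitter of ``spec.jitter`` Å per coordinate is
    added in both modes.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    if spec.assignment == "schedule":
        in_a = schedule_mask(n, int(round(spec.p_a * n)))
    else:
        in_a = rng.random(n) < spec.p_a
    frames = np.where(in_a[:, None, None], spec.conformer_a[None],
                      spec.conformer_b[None]).astype(float)
    frames = frames + rng.standard_normal(frames.shape) * spec.jitter
    return Trajectory(topology=spec.topology, frames=frames)


def _hbond_toy_topology() -> Structure:
    atoms = [
        Atom(1, "CA", "C", 1, 1, "A", np.array([-1.2, 0.9, 0.0])),
        Atom(2, "N", "N", 1, 1, "A", np.array([0.0, 0.0, 0.0])),
        Atom(3, "H", "H", 1, 1, "A", np.array([1.0, 0.0, 0.0])),
        Atom(4, "CA", "C", 2, 2, "A", np.array([4.1, 1.5, 0.0])),
        Atom(5, "C", "C", 2, 2, "A", np.array([4.1, 0.6, 0.0])),
        Atom(6, "O", "O", 2, 2, "A", np.array([2.9, 0.0, 0.0])),
    ]
    residues = [(1, 1, "GLY", "A"), (2, 2, "GLY", "A")]
    return Structure(atoms=atoms, residues=residues)


def make_hbond_toy(f: float, n_frames: int, mode: str = "schedule",
                   seed: int = 0) -> Trajectory:
    """Two-residue donor/acceptor system bonded in a fraction f of frames.

    In bonded frames the donor-acceptor (N...O) distance is 2.9 Å with a
    perfectly linear N-H...O arrangement; in unbonded frames the acceptor
    group is displaced to 5.0 Å.  ``schedule`` mode makes the bonded-frame
    count exactly ``round(f * n_frames)``; ``bernoulli`` draws states
    independently with probability f.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if mode not in ("schedule", "bernoulli"):
        raise ValueError("mode must be 'schedule' or 'bernoulli'")
    topo = _hbond_toy_topology()
    base = topo.coords
    if mode == "schedule":
        bonded = schedule_mask(n_frames, int(round(f * n_frames)))
    else:
        bonded = np.random.default_rng(seed).random(n_frames) < f
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    shift = np.array([2.1, 0.0, 0.0])   # moves N...O from 2.9 to 5.0 Å
    frames[~bonded, 3:6, :] += shift    # acceptor-residue atoms CA, C, O
    return Trajectory(topology=topo, frames=frames)
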