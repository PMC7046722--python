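"""Hydrogen bonds, typed non-covalent contacts, and residue interaction networks.

H-bond detection is geometric: donor-acceptor distance plus, when the
hydrogen is present in the topology, the deviation of the D-H...A angle
from linearity.  Defaults (D-A <= 3.0 Å, <= 20° off linear) follow the
common trajectory-analysis convention and are fully configurable.
Hydrogen-free topologies fall back to the distance criterion alone with a
logged warning.

Contacts are typed as van der Waals, salt bridge, pi-pi stacking, or
disulfide using distance rules on the relevant side-chain groups; a
residue interaction network (RIN) aggregates contacts and H-bonds over
trajectory frames into occupancy-weighted edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Structure, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_HBOND_DIST = 3.0      # Å, donor-acceptor
DEFAULT_HBOND_ANGLE = 20.0    # degrees off linear
SALT_BRIDGE_DIST = 4.0        # Å, charged N-O
PIPI_DIST = 6.5               # Å, ring centroids
DISULFIDE_DIST = 2.5          # Å, SG-SG
VDW_SLACK = 0.5               # Å added to r_i + r_j

POSITIVE_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
NEGATIVE_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
AROMATIC_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}


@dataclass
class HBond:
    donor: int            # atom positions (0-based)
    acceptor: int
    hydrogen: int | None
    distance: float       # D-A, Å
    angle: float | None   # D-H...A, degrees


def _attached_hydrogens(structure: Structure, frame: np.ndarray,
                        ) -> dict[int, list[int]]:
    """Map heavy-atom position -> covalently attached hydrogen positions."""
    h_pos = [i for i, a in enumerate(structure.atoms) if a.element.upper() == "H"]
    out: dict[int, list[int]] = {}
    if not h_pos:
        return out
    heavy = [i for i, a in enumerate(structure.atoms)
             if a.element.upper() in ("N", "O")]
    for h in h_pos:
        ah = structure.atoms[h]
        best, best_d = None, 1.25   # covalent X-H upper bound, Å
        for i in heavy:
            ai = structure.atoms[i]
            if ai.chain != ah.chain or ai.residue_index != ah.residue_index:
                continue
            d = float(np.linalg.norm(frame[i] - frame[h]))
            if d < best_d:
                best, best_d = i, d
        if best is not None:
            out.setdefault(best, []).append(h)
    return out


def detect_hbonds(structure: Structure, frame: np.ndarray,
                  dist_cutoff: float = DEFAULT_HBOND_DIST,
                  angle_cutoff: float = DEFAULT_HBOND_ANGLE) -> list[HBond]:
    """Geometric hydrogen bonds in one frame.

    Donors are N/O atoms with an attached hydrogen (all N/O when the
    topology carries no hydrogens at all); acceptors are N/O atoms.
    Intra-residue pairs are excluded.
    """
    frame = np.asarray(frame, dtype=float)
    polar = [i for i, a in enumerate(structure.atoms)
             if a.element.upper() in ("N", "O")]
    if not polar:
        return []
    attached = _attached_hydrogens(structure, frame)
    has_any_h = any(a.element.upper() == "H" for a in structure.atoms)
    if not has_any_h:
        logger.warning("topology has no hydrogens: H-bond angle test skipped")
        donors = polar
    else:
        donors = [i for i in polar if i in attached]
    tree = cKDTree(frame[polar])
    polar_arr = np.asarray(polar)
    bonds = []
    for d in donors:
        ad = structure.atoms[d]
        for k in tree.query_ball_point(frame[d], dist_cutoff):
            a = int(polar_arr[k])
            aa = structure.atoms[a]
            if a == d:
                continue
            if aa.chain == ad.chain and aa.residue_index == ad.residue_index:
                continue
            dist = float(np.linalg.norm(frame[a] - frame[d]))
            if dist > dist_cutoff or dist == 0.0:
                continue
            hyd, angle = None, None
            if has_any_h:
                # best (most linear) attached hydrogen
                best = None
                for h in attached.get(d, []):
                    v1 = frame[d] - frame[h]
                    v2 = frame[a] - frame[h]
                    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
                    if best is None or ang > best[1]:
                        best = (h, ang)
                if best is None:
                    continue
                hyd, angle = best
                if 180.0 - angle > angle_cutoff:
                    continue
            bonds.append(HBond(donor=d, acceptor=a, hydrogen=hyd,
                               distance=dist, angle=angle))
    return bonds


def hbond_occupancy(traj: Trajectory, stride: int = 1,
                    dist_cutoff: float = DEFAULT_HBOND_DIST,
                    angle_cutoff: float = DEFAULT_HBOND_ANGLE,
                    pairs: list[tuple[int, int]] | None = None) -> pd.DataFrame:
    """Per residue-pair H-bond occupancy over the trajectory.

    Occupancy is the percentage of examined frames in which at least one
    H-bond links the donor residue to the acceptor residue (directional:
    donor residue -> acceptor residue).  ``pairs`` optionally restricts the
    output to the given (donor_resid, acceptor_resid) author-number pairs.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    topo = traj.topology
    frames = traj.frames[::stride]
    n_used = frames.shape[0]
    counts: dict[tuple[int, int], int] = {}
    for t in range(n_used):
        seen = set()
        for hb in detect_hbonds(topo, frames[t], dist_cutoff, angle_cutoff):
            dres = topo.atoms[hb.donor].author_resid
            ares = topo.atoms[hb.acceptor].author_resid
            seen.add((dres, ares))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"donor_resid": d, "acceptor_resid": a,
         "occupancy_pct": 100.0 * c / n_used, "n_frames": n_used}
        for (d, a), c in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["donor_resid", "acceptor_resid",
                                     "occupancy_pct", "n_frames"])
    if pairs is not None:
        want = {tuple(p) for p in pairs}
        present = {(r.donor_resid, r.acceptor_resid) for r in df.itertuples()}
        missing = [{"donor_resid": d, "acceptor_resid": a,
                    "occupancy_pct": 0.0, "n_frames": n_used}
                   for d, a in sorted(want - present)]
        df = df[[(d, a) in want for d, a in
                 zip(df.donor_resid, df.acceptor_resid)]]
        if missing:
            df = pd.concat([df, pd.DataFrame(missing)], ignore_index=True)
        df = df.sort_values(["donor_resid", "acceptor_resid"],
                            ignore_index=True)
    return df


@dataclass
class Contact:
    residue_a: tuple[str, int]    # (chain, author_resid)
    residue_b: tuple[str, int]
    kind: str                     # vdw | salt_bridge | pipi | disulfide
    distance: float


def _residue_atom_map(structure: Structure) -> dict[tuple[str, int], list[int]]:
    out: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        out.setdefault((a.chain, a.residue_index), []).append(i)
    return out


def detect_contacts(structure: Structure, frame: np.ndarray,
                    vdw_slack: float = VDW_SLACK,
                    salt_bridge_dist: float = SALT_BRIDGE_DIST,
                    pipi_dist: float = PIPI_DIST,
                    disulfide_dist: float = DISULFIDE_DIST) -> list[Contact]:
    """Typed residue-residue contacts in one frame.

    Rules: vdW — any heavy-atom pair within r_i + r_j + slack between
    sequence-non-adjacent residues; salt bridge — opposite-charge N/O pair
    within 4.0 Å; pi-pi — aromatic ring centroids within 6.5 Å; disulfide —
    cysteine SG-SG within 2.5 Å.  One contact per (pair, type), keyed by
    the closest qualifying distance.
    """
    frame = np.asarray(frame, dtype=float)
    resname_of = {(r[3], r[0]): r[2] for r in structure.residues}
    author_of = {(r[3], r[0]): r[1] for r in structure.residues}
    res_atoms = _residue_atom_map(structure)
    reskeys = list(res_atoms)

    def adjacent(k1, k2):
        return k1[0] == k2[0] and abs(k1[1] - k2[1]) <= 1

    found: dict[tuple[tuple[str, int], tuple[str, int], str], float] = {}

    def record(k1, k2, kind, dist):
        a = (k1[0], author_of[k1])
        b = (k2[0], author_of[k2])
        if b < a:
            a, b = b, a
        key = (a, b, kind)
        if key not in found or dist < found[key]:
            found[key] = dist

    heavy = np.array([i for i, a in enumerate(structure.atoms)
                      if a.element.upper() != "H"])
    radii = np.array([structure.atoms[i].vdw_radius for i in heavy])
    tree = cKDTree(frame[heavy])
    max_cut = 2 * radii.max() + vdw_slack
    for ii, jj in tree.query_pairs(max_cut):
        i, j = int(heavy[ii]), int(heavy[jj])
        ai, aj = structure.atoms[i], structure.atoms[j]
        k1 = (ai.chain, ai.residue_index)
        k2 = (aj.chain, aj.residue_index)
        if k1 == k2 or adjacent(k1, k2):
            continue
        d = float(np.linalg.norm(frame[i] - frame[j]))
        if d <= ai.vdw_radius + aj.vdw_radius + vdw_slack:
            record(k1, k2, "vdw", d)

    charged: list[tuple[tuple[str, int], int, int]] = []   # (reskey, atompos, sign)
    rings: list[tuple[tuple[str, int], np.ndarray]] = []
    sgs: list[tuple[tuple[str, int], int]] = []
    for key in reskeys:
        resname = resname_of[key]
        atoms = res_atoms[key]
        for i in atoms:
            nm = structure.atoms[i].name.upper()
            if nm in POSITIVE_ATOMS.get(resname, ()):
                charged.append((key, i, +1))
            if nm in NEGATIVE_ATOMS.get(resname, ()):
                charged.append((key, i, -1))
            if resname == "CYS" and nm == "SG":
                sgs.append((key, i))
        ring_names = AROMATIC_RING_ATOMS.get(resname)
        if ring_names:
            ring_pos = [i for i in atoms
                        if structure.atoms[i].name.upper() in ring_names]
            if len(ring_pos) >= 5:
                rings.append((key, frame[ring_pos].mean(axis=0)))

    for a in range(len(charged)):
        for b in range(a + 1, len(charged)):
            (k1, i, s1), (k2, j, s2) = charged[a], charged[b]
            if k1 == k2 or s1 * s2 >= 0:
                continue
            d = float(np.linalg.norm(frame[i] - frame[j]))
            if d <= salt_bridge_dist:
                record(k1, k2, "salt_bridge", d)
    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            (k1, c1), (k2, c2) = rings[a], rings[b]
            if k1 == k2:
                continue
            d = float(np.linalg.norm(c1 - c2))
            if d <= pipi_dist:
                record(k1, k2, "pipi", d)
    for a in range(len(sgs)):
        for b in range(a + 1, len(sgs)):
            (k1, i), (k2, j) = sgs[a], sgs[b]
            if k1 == k2:
                continue
            d = float(np.linalg.norm(frame[i] - frame[j]))
            if d <= disulfide_dist:
                record(k1, k2, "disulfide", d)

    return [Contact(residue_a=a, residue_b=b, kind=kind, distance=d)
            for (a, b, kind), d in sorted(found.items())]


def build_rin(traj: Trajectory, occupancy_threshold: float = 10.0,
              stride: int | None = None,
              hbond_dist: float = DEFAULT_HBOND_DIST,
              hbond_angle: float = DEFAULT_HBOND_ANGLE,
              max_frames: int = 1000) -> nx.Graph:
    """Ensemble residue interaction network over strided frames.

    Every residue is a node (label ``CHAIN:RESNAME:AUTHORNUM``) regardless
    of degree; an edge (pair, type) is kept iff its occupancy over the
    examined frames reaches ``occupancy_threshold`` percent, and carries
    that occupancy as its weight.  When ``stride`` is None it is chosen as
    the smallest value examining at most ``max_frames`` representative
    snapshots.
    """
    topo = traj.topology
    if stride is None:
        stride = max(1, int(np.ceil(traj.n_frames / max_frames)))
    frames = traj.frames[::stride]
    n_used = frames.shape[0]

    g = nx.Graph()
    g.graph.update({
        "occupancy_threshold": occupancy_threshold, "stride": stride,
        "n_frames_used": n_used,
        "criteria": (f"hbond D-A<={hbond_dist}A,<= {hbond_angle}deg off linear; "
                     f"salt {SALT_BRIDGE_DIST}A; pipi {PIPI_DIST}A; "
                     f"SS {DISULFIDE_DIST}A; vdw +{VDW_SLACK}A"),
    })
    label_of: dict[tuple[str, int], str] = {}
    for res in topo.residues:
        label = topo.residue_label(res)
        label_of[(res[3], res[1])] = label
        g.add_node(label, chain=res[3], resname=res[2], resid=int(res[1]))

    counts: dict[tuple[tuple[str, int], tuple[str, int], str], int] = {}
    for t in range(n_used):
        seen = set()
        for hb in detect_hbonds(topo, frames[t], hbond_dist, hbond_angle):
            ad, aa = topo.atoms[hb.donor], topo.atoms[hb.acceptor]
            a = (ad.chain, ad.author_resid)
            b = (aa.chain, aa.author_resid)
            if b < a:
                a, b = b, a
            seen.add((a, b, "hbond"))
        for c in detect_contacts(topo, frames[t]):
            seen.add((c.residue_a, c.residue_b, c.kind))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1

    for (a, b, kind), c in sorted(counts.items()):
        occ = 100.0 * c / n_used
        if occ >= occupancy_threshold:
            u, v = label_of[a], label_of[b]
            # one edge per (pair, type); multiple types on a pair keep the
            # strongest occupancy and record all types
            if g.has_edge(u, v):
                g[u][v]["types"] = g[u][v]["types"] + "," + kind
                g[u][v]["weight"] = max(g[u][v]["weight"], occ)
            else:
                g.add_edge(u, v, types=kind, weight=occ)
    return g


def rin_edge_table(g: nx.Graph) -> pd.DataFrame:
    """Edge-list view of a RIN (source, target, type, weight)."""
    rows = [{"source": u, "target": v, "type": d["types"],
             "weight": d["weight"]} for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "type", "weight"])
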