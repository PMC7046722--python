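"""Three-class secondary-structure assignment over trajectories.

Backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
model,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond assigned when E < -0.5 kcal/mol.  Amide hydrogens missing from
the topology are constructed geometrically: 1.0 Å from N, anti-parallel to
the preceding residue's carbonyl C=O direction (proline has no donor).

Labels are a 3-class scheme: H (helix, from consecutive i->i+4 turns, with
3_10/pi turns folded in only when flanked by i->i+4 bonds), E (strand, from
parallel/antiparallel bridge ladders), C (everything else).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Structure, Trajectory

logger = logging.getLogger(__name__)

KS_COUPLING = 0.084 * 332.0   # kcal/mol * Å
KS_CUTOFF = -0.5              # kcal/mol


@dataclass
class SSETimeline:
    """Frame x residue secondary-structure labels plus content summaries."""

    labels: np.ndarray          # (n_frames, n_residues) of 'H'/'E'/'C'
    resids: np.ndarray          # author numbering
    helix_pct: np.ndarray       # per residue, % of frames
    strand_pct: np.ndarray
    global_helix_pct: float
    global_strand_pct: float

    @property
    def total_sse_pct(self) -> float:
        return self.global_helix_pct + self.global_strand_pct

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels,
                            columns=[str(r) for r in self.resids])


def _backbone_positions(structure: Structure, frame: np.ndarray,
                        ) -> tuple[list[dict | None], np.ndarray, list[str]]:
    """Per-residue backbone coordinates with constructed amide H.

    Returns (records, author_resids, resnames); a record is None when N,
    CA or C is missing (that residue is skipped with a warning).
    """
    per_res: dict[tuple[str, int], dict] = {}
    order = [(r[3], r[0]) for r in structure.residues]
    meta = {(r[3], r[0]): r for r in structure.residues}
    for i, atom in enumerate(structure.atoms):
        key = (atom.chain, atom.residue_index)
        nm = atom.name.upper()
        if nm in ("N", "CA", "C", "O", "H", "HN", "H1"):
            per_res.setdefault(key, {})[("H" if nm in ("HN", "H1") else nm)] = frame[i]
    records: list[dict | None] = []
    for k, key in enumerate(order):
        rec = per_res.get(key, {})
        if not all(n in rec for n in ("N", "CA", "C")):
            logger.warning("residue %s missing backbone atoms: skipped",
                           meta[key][1])
            records.append(None)
            continue
        if "O" not in rec:
            records.append(None)
            continue
        records.append(rec)
    # construct missing amide hydrogens (not for chain-start or proline)
    for k, key in enumerate(order):
        rec = records[k]
        if rec is None or "H" in rec:
            continue
        if meta[key][2] == "PRO":
            continue
        if k == 0 or order[k - 1][0] != key[0]:
            continue
        prev = records[k - 1]
        if prev is None:
            continue
        co = prev["C"] - prev["O"]
        norm = np.linalg.norm(co)
        if norm == 0:
            continue
        rec["H"] = rec["N"] + co / norm   # 1.0 Å from N, anti to C=O
    resids = np.array([meta[key][1] for key in order])
    resnames = [meta[key][2] for key in order]
    return records, resids, resnames


def kabsch_sander_energy(donor: dict, acceptor: dict) -> float:
    """Electrostatic H-bond energy of donor N-H with acceptor C=O, kcal/mol.

    ``donor`` needs N (and H when present), ``acceptor`` needs C and O.
    A donor without hydrogen (proline, chain start) never bonds; callers
    should not pass one.
    """
    if "H" not in donor:
        return 0.0
    n, h = donor["N"], donor["H"]
    c, o = acceptor["C"], acceptor["O"]
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9   # colliding atoms: treated as strongly bonded, as in DSSP
    return float(KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def _ks_bond_matrix(records: list[dict | None], chains: list[str],
                    resnames: list[str]) -> np.ndarray:
    """bond[i, j] True iff N-H of residue i donates to C=O of residue j.

    Vectorized evaluation of the electrostatic energy over all residue
    pairs; agrees with :func:`kabsch_sander_energy` pair by pair.
    """
    n = len(records)
    nan3 = np.full(3, np.nan)
    N = np.stack([r["N"] if r else nan3 for r in records])
    H = np.stack([r.get("H", nan3) if r else nan3 for r in records])
    C = np.stack([r["C"] if r else nan3 for r in records])
    O = np.stack([r["O"] if r else nan3 for r in records])

    def dist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)

    r_on = dist(N, O)        # (donor i, acceptor j)
    r_ch = dist(H, C)
    r_oh = dist(H, O)
    r_cn = dist(N, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        E = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    collide = np.fmin(np.fmin(r_on, r_ch), np.fmin(r_oh, r_cn)) < 0.5
    E = np.where(collide, -9.9, E)
    bond = E < KS_CUTOFF
    bond &= ~np.isnan(E)
    no_donor = np.array([r is None or "H" not in r for r in records]) \
        | np.array([rn == "PRO" for rn in resnames])
    bond[no_donor, :] = False
    bond[:, [r is None for r in records]] = False
    same_chain = np.array([[ci == cj for cj in chains] for ci in chains])
    near = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) <= 1
    bond[same_chain & near] = False   # self and peptide-adjacent excluded
    return bond


def assign_sse(structure: Structure, frame: np.ndarray) -> np.ndarray:
    """Per-residue {H, E, C} labels for one frame.

    Helix: residues covered by two consecutive i->i+4 turns (donor i+4 to
    acceptor i); 3_10 / pi turns are folded into H only when flanked by an
    i->i+4 bond.  Strand: residues in Kabsch-Sander parallel or
    antiparallel bridges (|i-j| >= 3).  Helix wins where both apply.
    Chains shorter than 5 residues are all-coil.
    """
    records, _resids, resnames = _backbone_positions(structure, frame)
    chains = [r[3] for r in structure.residues]
    n = len(records)
    labels = np.full(n, "C", dtype="<U1")
    if n < 5:
        return labels
    bond = _ks_bond_matrix(records, chains, resnames)

    def turn(i: int, k: int) -> bool:
        j = i + k
        return (j < n and chains[i] == chains[j] and bond[j, i])

    helix = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        if turn(i, 4) and turn(i + 1, 4):
            helix[i + 1:i + 5] = True
    # relaxed 3_10 / pi turns adjacent to genuine alpha turns
    for i in range(n - 1):
        for k in (3, 5):
            if turn(i, k) and turn(i + 1, k) and \
                    (turn(i - 1, 4) or turn(i, 4) or turn(i + 1, 4)):
                helix[i + 1:i + k + 1] = True

    strand = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 3, n):
            para = (bond[i - 1, j] and bond[j, i + 1] if i >= 1 and i + 1 < n else False) \
                or (bond[j - 1, i] and bond[i, j + 1] if j >= 1 and j + 1 < n else False)
            anti = (bond[i, j] and bond[j, i]) \
                or (bond[i - 1, j + 1] and bond[j - 1, i + 1]
                    if i >= 1 and j + 1 < n else False)
            if para or anti:
                strand[i] = strand[j] = True

    labels[strand] = "E"
    labels[helix] = "H"
    return labels


def sse_statistics(traj: Trajectory) -> SSETimeline:
    """Secondary-structure content over all frames.

    Per-residue helix/strand percentages are fractions of frames; the
    global percentages are over all (frame, residue) labels, so the global
    total equals the mean of per-frame totals.
    """
    topo = traj.topology
    all_labels = np.stack([assign_sse(topo, traj.frames[t])
                           for t in range(traj.n_frames)])
    resids = np.array([r[1] for r in topo.residues])
    helix_pct = 100.0 * (all_labels == "H").mean(axis=0)
    strand_pct = 100.0 * (all_labels == "E").mean(axis=0)
    return SSETimeline(labels=all_labels, resids=resids,
                       helix_pct=helix_pct, strand_pct=strand_pct,
                       global_helix_pct=float(100.0 * (all_labels == "H").mean()),
                       global_strand_pct=float(100.0 * (all_labels == "E").mean()))
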