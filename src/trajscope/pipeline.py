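"""End-to-end orchestration: one config in, a directory of tables out.

A run executes the requested stages in dependency order (superposition →
series metrics → DCCM/PCA → FEL → H-bonds/RIN → SSE), logging every stage
with its parameters, and returns a :class:`RunReport` listing each output
file plus the headline summary statistics.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collective import dccm, mode_profile, pca_covariance, project_onto_pcs
from .core import Structure, Trajectory, read_pdb, read_trajectory, select_atoms
from .geometry import rg_series, rmsd_series, rmsf_profile, sasa, sasa_series
from .interactions import build_rin, hbond_occupancy
from .landscape import compute_fel, locate_minima, representative_frame
from .secondary import sse_statistics
from . import writers
from .core import write_structure

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("rmsd", "rg", "rmsf", "sasa", "dccm", "pca", "fel",
                  "hbonds", "rin", "sse")


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    Exactly one of ``trajectory`` (with optional ``topology``) or
    ``synthetic`` must be given.  ``synthetic`` is a mapping with a
    ``kind`` of ``gaussian`` or ``two_state`` plus the generator's
    parameters.
    """

    output_dir: str
    trajectory: str | None = None
    topology: str | None = None
    synthetic: dict | None = None
    stages: tuple[str, ...] = DEFAULT_STAGES
    seed: int = 0
    selection_rmsd: str = "backbone"
    selection_profile: str = "name CA"
    fel_bins: tuple[int, int] = (50, 50)
    temperature: float = 300.0
    hbond_dist: float = 3.0
    hbond_angle: float = 20.0
    rin_threshold: float = 10.0
    sasa_n_points: int = 960
    sasa_probe: float = 1.4
    stride: int = 1

    def __post_init__(self) -> None:
        if (self.trajectory is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of 'trajectory' or 'synthetic' must be set")
        self.stages = tuple(self.stages)
        self.fel_bins = tuple(self.fel_bins)
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.trajectory is not None and not Path(self.trajectory).exists():
            raise FileNotFoundError(f"trajectory not found: {self.trajectory}")
        if self.topology is not None and not Path(self.topology).exists():
            raise FileNotFoundError(f"topology not found: {self.topology}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        # output_dir does not affect the science; exclude it so reruns into
        # different directories are recognisably the same run
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    files: dict[str, str]
    summary: dict[str, float | int]
    provenance: dict[str, str | int]
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload = {"files": self.files, "summary": self.summary,
                   "provenance": self.provenance}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _load_trajectory(config: RunConfig) -> Trajectory:
    if config.synthetic is not None:
        return _build_synthetic(config)
    topo: Structure | None = None
    if config.topology:
        topo = read_pdb(config.topology)
    return read_trajectory(config.trajectory, topo, stride=config.stride)


def _build_synthetic(config: RunConfig) -> Trajectory:
    from .synthetic import (EnsembleSpec, TwoStateSpec, make_gaussian_ensemble,
                            make_toy_protein, make_two_state_trajectory)

    params = dict(config.synthetic)
    kind = params.pop("kind")
    n_res = params.pop("n_res", 20)
    fold = params.pop("fold", "helix")
    ref = make_toy_protein(n_res, fold)
    if kind == "gaussian":
        blocks = [tuple(b) for b in params.pop("correlation_blocks", [])]
        spec = EnsembleSpec(reference=ref,
                            correlation_blocks=blocks,
                            seed=params.pop("seed", config.seed), **params)
        return make_gaussian_ensemble(spec)
    if kind == "two_state":
        displacement = params.pop("displacement", 3.0)
        coords_a = ref.coords
        coords_b = coords_a.copy()
        # displace the second half of the chain to create a distinct state
        half_atoms = [i for i, a in enumerate(ref.atoms)
                      if a.residue_index > ref.n_residues // 2]
        coords_b[half_atoms] += np.array([displacement, 0.0, 0.0])
        spec = TwoStateSpec(conformer_a=coords_a, conformer_b=coords_b,
                            topology=ref, seed=params.pop("seed", config.seed),
                            **params)
        return make_two_state_trajectory(spec)
    raise ValueError(f"unknown synthetic kind {kind!r}")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and write their tables.

    Returns a report whose ``summary`` holds the headline statistics (mean
    and final RMSD, mean Rg, PCA trace and first-3 variance fractions,
    basin count, RIN edge count, SSE totals) and whose ``files`` maps each
    stage output to its path.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj = _load_trajectory(config)
    logger.info("run %s: %d frames, %d atoms, stages=%s", config.digest(),
                traj.n_frames, traj.n_atoms, ",".join(config.stages))
    files: dict[str, str] = {}
    summary: dict[str, float | int] = {
        "n_frames": traj.n_frames, "n_atoms": traj.n_atoms,
        "n_residues": traj.topology.n_residues,
    }

    sel_bb = select_atoms(traj.topology, config.selection_rmsd)
    sel_ca = select_atoms(traj.topology, config.selection_profile)

    series_cache: dict[str, object] = {}
    if "rmsd" in config.stages or "fel" in config.stages:
        logger.info("stage rmsd: selection=%r", config.selection_rmsd)
        ref = traj.frames[0, sel_bb.indices]
        rmsd = rmsd_series(traj, ref, sel_bb)
        series_cache["rmsd"] = rmsd
        if "rmsd" in config.stages:
            p = out / "rmsd.csv"
            writers.write_series_csv(rmsd, p)
            files["rmsd"] = p.name
            summary["rmsd_mean_A"] = float(rmsd.values.mean())
            summary["rmsd_final_A"] = float(rmsd.values[-1])
    if "rg" in config.stages or "fel" in config.stages:
        logger.info("stage rg: mass-weighted")
        rg = rg_series(traj, sel_bb)
        series_cache["rg"] = rg
        if "rg" in config.stages:
            p = out / "rg.csv"
            writers.write_series_csv(rg, p)
            files["rg"] = p.name
            summary["rg_mean_A"] = float(rg.values.mean())

    profiles: dict[str, pd.DataFrame] = {}
    if "rmsf" in config.stages:
        logger.info("stage rmsf: selection=%r", config.selection_profile)
        prof = rmsf_profile(traj, sel_ca)
        p = out / "rmsf.csv"
        writers.write_profile_csv(prof, p)
        files["rmsf"] = p.name
        summary["rmsf_mean_A"] = float(prof.values.mean())
        profiles["rmsf"] = pd.DataFrame({"resid": prof.resids,
                                         "value": prof.values})
    if "sasa" in config.stages:
        logger.info("stage sasa: probe=%.2f Å, n_points=%d (defaulted "
                    "criteria)", config.sasa_probe, config.sasa_n_points)
        total = sasa_series(traj, config.sasa_probe, config.sasa_n_points)
        p = out / "sasa_total.csv"
        writers.write_series_csv(total, p)
        files["sasa_total"] = p.name
        summary["sasa_mean_A2"] = float(total.values.mean())
        _, prof, _ = sasa(traj.frames[-1], traj.topology.atom_radii(),
                          config.sasa_probe, config.sasa_n_points,
                          structure=traj.topology)
        p2 = out / "sasa_per_residue.csv"
        writers.write_profile_csv(prof, p2)
        files["sasa_per_residue"] = p2.name
        profiles["sasa_per_residue"] = pd.DataFrame(
            {"resid": prof.resids, "value": prof.values})

    if "dccm" in config.stages:
        logger.info("stage dccm: selection=%r", config.selection_profile)
        d = dccm(traj, sel_ca)
        p = out / "dccm.csv"
        writers.write_dccm_csv(d, p)
        files["dccm"] = p.name
    if "pca" in config.stages:
        logger.info("stage pca: covariance of %r", config.selection_profile)
        pca = pca_covariance(traj, sel_ca)
        p = out / "pca_spectrum.csv"
        writers.write_pca_csv(pca, p)
        files["pca_spectrum"] = p.name
        k = min(2, pca.n_modes)
        proj = project_onto_pcs(traj, sel_ca, pca, k=k)
        p2 = out / "pca_projections.csv"
        writers.write_projections_csv(proj, p2)
        files["pca_projections"] = p2.name
        prof, plus, minus = mode_profile(pca, traj.topology, sel_ca, mode=0)
        p3 = out / "pc1_loadings.csv"
        writers.write_profile_csv(prof, p3)
        files["pc1_loadings"] = p3.name
        profiles["pc1_loadings"] = pd.DataFrame({"resid": prof.resids,
                                                 "value": prof.values})
        summary["pca_trace_A2"] = pca.trace
        for i in range(min(3, pca.n_modes)):
            summary[f"pca_var_frac_pc{i + 1}"] = float(pca.variance_fractions[i])
        summary["pca_var_frac_first3"] = float(
            pca.variance_fractions[:3].sum())

    if "fel" in config.stages:
        logger.info("stage fel: bins=%s T=%.0fK (defaulted grid)",
                    config.fel_bins, config.temperature)
        grid = compute_fel(series_cache["rg"], series_cache["rmsd"],
                           n_bins=config.fel_bins,
                           temperature=config.temperature)
        p = out / "fel.csv"
        writers.write_fel_csv(grid, p)
        files["fel"] = p.name
        basins = locate_minima(grid)
        p2 = out / "basins.json"
        writers.write_basins_json(basins, p2)
        files["basins"] = p2.name
        summary["fel_basin_count"] = len(basins)
        rep = representative_frame(traj, series_cache["rg"],
                                   series_cache["rmsd"], grid, basins[0])
        p3 = out / "representative_conformer.pdb"
        write_structure(traj.topology, traj.frames[rep], p3)
        files["representative_conformer"] = p3.name
        summary["representative_frame"] = rep

    if "hbonds" in config.stages:
        logger.info("stage hbonds: D-A<=%.2f Å, <=%.0f° off linear "
                    "(defaulted criteria)", config.hbond_dist,
                    config.hbond_angle)
        occ = hbond_occupancy(traj, dist_cutoff=config.hbond_dist,
                              angle_cutoff=config.hbond_angle)
        p = out / "hbond_occupancy.csv"
        occ.to_csv(p, index=False, float_format="%.6g")
        files["hbond_occupancy"] = p.name
        summary["hbond_pairs"] = int(len(occ))
    if "rin" in config.stages:
        logger.info("stage rin: threshold=%.1f%%", config.rin_threshold)
        g = build_rin(traj, occupancy_threshold=config.rin_threshold,
                      hbond_dist=config.hbond_dist,
                      hbond_angle=config.hbond_angle)
        p = out / "rin.graphml"
        p2 = out / "rin_edges.csv"
        writers.write_rin(g, p, p2)
        files["rin"] = p.name
        files["rin_edges"] = p2.name
        summary["rin_edge_count"] = g.number_of_edges()
    if "sse" in config.stages:
        logger.info("stage sse")
        tl = sse_statistics(traj)
        p = out / "sse_timeline.csv"
        p2 = out / "sse_summary.json"
        writers.write_sse(tl, p, p2)
        files["sse_timeline"] = p.name
        files["sse_summary"] = p2.name
        summary["sse_helix_pct"] = tl.global_helix_pct
        summary["sse_strand_pct"] = tl.global_strand_pct
        summary["sse_total_pct"] = tl.total_sse_pct

    report = RunReport(
        files=files, summary=summary,
        provenance={"config_digest": config.digest(), "seed": config.seed,
                    "package_version": __version__},
        profiles=profiles)
    report.save(out / "report.json")
    files["report"] = "report.json"
    return report


def compare_runs(report_a: RunReport, report_b: RunReport,
                 ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-metric differences between two runs (B minus A).

    Returns a scalar difference table over the shared summary statistics
    and aligned per-residue difference profiles (RMSF, per-residue SASA,
    PC1 loadings) for the profiles present in both reports.
    """
    shared = sorted(set(report_a.summary) & set(report_b.summary))
    if not shared:
        raise ValueError("reports share no metrics")
    scalars = pd.DataFrame({
        "metric": shared,
        "A": [report_a.summary[k] for k in shared],
        "B": [report_b.summary[k] for k in shared],
    })
    scalars["delta"] = scalars["B"] - scalars["A"]
    deltas: dict[str, pd.DataFrame] = {}
    for name in set(report_a.profiles) & set(report_b.profiles):
        pa, pb = report_a.profiles[name], report_b.profiles[name]
        if len(pa) != len(pb) or not np.array_equal(pa.resid.values,
                                                    pb.resid.values):
            raise ValueError(f"profile {name!r} residue sets differ")
        deltas[name] = pd.DataFrame({
            "resid": pa.resid.values,
            "A": pa.value.values, "B": pb.value.values,
            "delta": pb.value.values - pa.value.values})
    return scalars, deltas
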