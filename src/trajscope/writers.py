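"""CSV / JSON / GraphML writers for analysis results.

All writers are deterministic: fixed column orders, fixed float formatting,
sorted keys in JSON — so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .collective import DCCMatrix, PCAResult
from .geometry import ProfileResult, SeriesResult
from .landscape import Basin, FELGrid

_FLOAT_FMT = "%.6g"


def write_series_csv(series: SeriesResult, path: str | Path) -> None:
    df = pd.DataFrame({"frame": np.arange(len(series)),
                       series.metric: series.values})
    with open(path, "w") as fh:
        fh.write(f"# metric={series.metric} unit={series.unit} "
                 f"selection={series.selection_label}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_profile_csv(profile: ProfileResult, path: str | Path) -> None:
    df = pd.DataFrame({"resid": profile.resids, profile.metric: profile.values})
    if profile.labels:
        df.insert(1, "label", profile.labels)
    with open(path, "w") as fh:
        fh.write(f"# metric={profile.metric} unit={profile.unit}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_dccm_csv(d: DCCMatrix, path: str | Path) -> None:
    labels = [str(r) for r in d.resids] if len(d.resids) else \
        [str(i + 1) for i in range(d.n)]
    df = pd.DataFrame(d.matrix, index=labels, columns=labels)
    with open(path, "w") as fh:
        fh.write(f"# dccm selection={d.selection_label} "
                 f"n_frames={d.n_frames_used}\n")
        df.to_csv(fh, float_format=_FLOAT_FMT)


def write_pca_csv(p: PCAResult, path: str | Path) -> None:
    df = pd.DataFrame({
        "mode": np.arange(1, p.n_modes + 1),
        "eigenvalue_A2": p.eigenvalues,
        "variance_fraction": p.variance_fractions,
    })
    with open(path, "w") as fh:
        fh.write(f"# pca trace_A2={p.trace:.6f} "
                 f"selection={p.selection_label}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_projections_csv(proj: np.ndarray, path: str | Path) -> None:
    cols = {f"PC{k + 1}": proj[:, k] for k in range(proj.shape[1])}
    df = pd.DataFrame({"frame": np.arange(proj.shape[0]), **cols})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_fel_csv(grid: FELGrid, path: str | Path) -> None:
    xc, yc = grid.bin_centers()
    rows = []
    for i in range(len(xc)):
        for j in range(len(yc)):
            rows.append({"x_center": xc[i], "y_center": yc[j],
                         "count": int(grid.counts[i, j]),
                         "G_kcal_mol": grid.G[i, j],
                         "empty": int(grid.empty_mask[i, j])})
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# fel x={grid.x_label} y={grid.y_label} "
                 f"T={grid.temperature}K kB={grid.kB}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_basins_json(basins: list[Basin], path: str | Path) -> None:
    payload = []
    for b in basins:
        d = asdict(b)
        d["minimum_bin"] = list(d["minimum_bin"])
        d["member_bins"] = [list(m) for m in d["member_bins"]]
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_rin(graph: nx.Graph, graphml_path: str | Path | None = None,
              edges_csv_path: str | Path | None = None) -> None:
    from .interactions import rin_edge_table

    if graphml_path is not None:
        nx.write_graphml(graph, str(graphml_path))
    if edges_csv_path is not None:
        rin_edge_table(graph).to_csv(edges_csv_path, index=False,
                                     float_format=_FLOAT_FMT)


def write_sse(timeline, csv_path: str | Path | None = None,
              json_path: str | Path | None = None) -> None:
    if csv_path is not None:
        timeline.to_frame().to_csv(csv_path, index_label="frame")
    if json_path is not None:
        payload = {
            "global_helix_pct": timeline.global_helix_pct,
            "global_strand_pct": timeline.global_strand_pct,
            "total_sse_pct": timeline.total_sse_pct,
            "per_residue": {
                str(r): {"helix_pct": float(h), "strand_pct": float(s)}
                for r, h, s in zip(timeline.resids, timeline.helix_pct,
                                   timeline.strand_pct)
            },
        }
        Path(json_path).write_text(json.dumps(payload, indent=1,
                                              sort_keys=True))
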