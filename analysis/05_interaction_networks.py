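#!/usr/bin/env python
"""Hydrogen-bond occupancy recovery and the ensemble residue network.

First recovers planted H-bond occupancies (exact under a deterministic
schedule, within binomial error under Bernoulli planting), then builds an
occupancy-weighted residue interaction network over a helical ensemble:
every residue is a node, and H-bond / van der Waals / salt-bridge / pi-pi
/ disulfide edges are kept when they persist in at least 10% of the
snapshots (at most 1000 representative frames).
"""

import argparse
from pathlib import Path

import pandas as pd

import trajscope as ts
from trajscope import writers
from trajscope.interactions import rin_edge_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/interactions")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for f, mode in ((0.25, "schedule"), (0.1234, "bernoulli"),
                    (0.6, "schedule")):
        traj = ts.make_hbond_toy(f, 2000, mode=mode, seed=args.seed)
        occ = ts.hbond_occupancy(traj)
        got = occ.occupancy_pct.iloc[0] if len(occ) else 0.0
        rows.append({"planted_pct": 100 * f, "mode": mode,
                     "recovered_pct": got})
    recovery = pd.DataFrame(rows)
    recovery.to_csv(out / "occupancy_recovery.csv", index=False,
                    float_format="%.4f")

    ref = ts.make_toy_protein(40, "helix", author_offset=20)
    spec = ts.EnsembleSpec(reference=ref, sigma=0.25, n_frames=400,
                           seed=args.seed)
    traj = ts.make_gaussian_ensemble(spec)
    # the ideal-geometry helix places N...O at 3.09 Å, so the strict
    # 3.0 Å default would miss its i->i+4 ladder; use 3.3 Å here
    occ = ts.hbond_occupancy(traj, stride=2, dist_cutoff=3.3)
    occ.to_csv(out / "hbond_occupancy.csv", index=False,
               float_format="%.4f")
    g = ts.build_rin(traj, occupancy_threshold=10.0, hbond_dist=3.3)
    writers.write_rin(g, out / "rin.graphml", out / "rin_edges.csv")
    edges = rin_edge_table(g)

    print("Planted-occupancy recovery:")
    print(recovery.round(2).to_string(index=False))
    print(f"\nEnsemble network over {g.graph['n_frames_used']} snapshots "
          f"(stride {g.graph['stride']}): {g.number_of_nodes()} residue "
          f"nodes, {g.number_of_edges()} edges at >=10% occupancy "
          f"({(edges.type.str.contains('hbond')).sum()} hydrogen-bonded "
          "pairs; the helical i->i+4 ladder dominates, as it should for "
          "an ideal helix).")


if __name__ == "__main__":
    main()
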