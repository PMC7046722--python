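#!/usr/bin/env python
"""Secondary-structure content over a conformational-remodeling trajectory.

Assigns 3-class (helix/strand/coil) labels per frame from Kabsch-Sander
backbone hydrogen bonds, on a trajectory that interpolates between a
jittered helix and a jittered extended state — emulating the helix
gain/loss a remodeling mutation produces — and reports per-residue and
global secondary-structure percentages.
"""

import argparse
from pathlib import Path

import numpy as np

import trajscope as ts
from trajscope import writers


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/secondary")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    helix = ts.make_toy_protein(15, "helix")
    ext = ts.make_toy_protein(15, "extended")
    spec = ts.TwoStateSpec(conformer_a=helix.coords, conformer_b=ext.coords,
                           topology=helix, p_a=0.6, jitter=0.03,
                           n_frames=200, seed=args.seed)
    traj = ts.make_two_state_trajectory(spec)
    tl = ts.sse_statistics(traj)
    writers.write_sse(tl, out / "sse_timeline.csv", out / "sse_summary.json")

    helix_static = 100.0 * np.mean(ts.assign_sse(helix, helix.coords) == "H")
    print(f"Static ideal helix: {helix_static:.1f}% helical residues; "
          "static extended chain: 0% (all coil).")
    print(f"Mixed 60/40 helix-extended trajectory: {tl.global_helix_pct:.1f}% "
          f"helix, {tl.global_strand_pct:.1f}% strand, total SSE "
          f"{tl.total_sse_pct:.1f}% — close to 0.6 x {helix_static:.1f}% = "
          f"{0.6 * helix_static:.1f}%, the planted expectation.")
    interior = slice(1, -1)
    print(f"Interior residues are helical in "
          f"{tl.helix_pct[interior].mean():.1f}% of frames on average.")


if __name__ == "__main__":
    main()
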