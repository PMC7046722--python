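#!/usr/bin/env python
"""Free-energy landscape over (Rg, RMSD) with planted 70/30 basins.

A two-state trajectory (half the chain displaced in state B, Bernoulli
state assignment at p=0.7/0.3) is projected onto the radius of gyration
and backbone RMSD, binned, and Boltzmann-inverted at 300 K.  The basin
free-energy gap is compared with the planted -kB T ln(0.3/0.7) and the
representative conformer of the dominant basin is exported.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import trajscope as ts
from trajscope import writers
from trajscope.landscape import KB_KCAL


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/landscape")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ref = ts.make_toy_protein(30, "helix", author_offset=20)
    coords_b = ref.coords.copy()
    half = [i for i, a in enumerate(ref.atoms) if a.residue_index > 15]
    coords_b[half] += np.array([5.0, 0.0, 0.0])
    n = 10_000
    spec = ts.TwoStateSpec(conformer_a=ref.coords, conformer_b=coords_b,
                           topology=ref, p_a=0.7, jitter=0.05, n_frames=n,
                           seed=args.seed, assignment="bernoulli")
    traj = ts.make_two_state_trajectory(spec)

    sel = ts.select_atoms(ref, "name CA")
    rmsd = ts.rmsd_series(traj, ref.coords[sel.indices], sel)
    rg = ts.rg_series(traj, sel)
    grid = ts.compute_fel(rg, rmsd, n_bins=(20, 20), temperature=300.0)
    writers.write_fel_csv(grid, out / "fel.csv")

    basins = ts.locate_minima(grid)
    writers.write_basins_json(basins, out / "basins.json")
    deep = sorted(basins, key=lambda b: -b.population_fraction)[:2]
    gap = abs(deep[0].g_min - deep[1].g_min)
    expected = -KB_KCAL * 300.0 * np.log(0.3 / 0.7)

    rep = ts.representative_frame(traj, rg, rmsd, grid, deep[0])
    ts.write_structure(ref, traj.frames[rep],
                       out / "representative_conformer.pdb")

    pd.DataFrame([{
        "n_frames": n, "n_basins_total": len(basins),
        "pop_major": deep[0].population_fraction,
        "pop_minor": deep[1].population_fraction,
        "delta_g_kcal_mol": gap, "delta_g_expected_kcal_mol": expected,
        "representative_frame": rep,
    }]).to_csv(out / "summary.csv", index=False, float_format="%.4f")

    print(f"Two dominant basins with populations "
          f"{deep[0].population_fraction:.3f} / "
          f"{deep[1].population_fraction:.3f} (planted 0.70/0.30).")
    print(f"Basin free-energy gap {gap:.3f} kcal/mol vs the Boltzmann "
          f"expectation -kB*300K*ln(0.3/0.7) = {expected:.3f} kcal/mol.")
    print(f"Representative conformer of the dominant basin: frame {rep}, "
          "exported as PDB. Empty bins carry the artificial barrier "
          f"G = {grid.barrier:.3f} kcal/mol.")


if __name__ == "__main__":
    main()
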