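#!/usr/bin/env python
"""Stability metrics: baseline vs loop-destabilized ensemble.

Emulates the wild-type-versus-variant comparison: a baseline Gaussian
ensemble around the 60-residue reference, and a "variant" ensemble with
extra fluctuation planted in the CDR1-like window (author residues 37-47).
Computes RMSD/Rg/total-SASA series with their densities and per-residue
RMSF / SASA profiles, then localizes the perturbation via the RMSF
difference profile.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import trajscope as ts
from trajscope import writers


def build_ensembles(seed: int, n_frames: int = 800):
    ref = ts.make_toy_protein(60, "helix", author_offset=20)
    spec = ts.EnsembleSpec(reference=ref, sigma=0.3, n_frames=n_frames,
                           seed=seed)
    wt = ts.make_gaussian_ensemble(spec)
    var = ts.make_gaussian_ensemble(spec)
    loop = ts.select_atoms(ref, "resid 37:47").indices
    extra = np.random.default_rng(seed + 1).standard_normal(
        (n_frames, len(loop), 3)) * 0.45
    var.frames[:, loop, :] += extra
    return ref, wt, var


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/stability")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ref, wt, var = build_ensembles(args.seed)
    bb = ts.select_atoms(ref, "backbone")
    ca = ts.select_atoms(ref, "name CA")
    ref_bb = ref.coords[bb.indices]

    rows = []
    profiles = {}
    for label, traj in (("baseline", wt), ("loop_variant", var)):
        rmsd = ts.rmsd_series(traj, ref_bb, bb)
        rg = ts.rg_series(traj, bb)
        writers.write_series_csv(rmsd, out / f"rmsd_{label}.csv")
        writers.write_series_csv(rg, out / f"rg_{label}.csv")
        edges, dens = ts.series_density(rmsd, n_bins=40)
        pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                      "density": dens}).to_csv(
            out / f"rmsd_density_{label}.csv", index=False)
        rmsf = ts.rmsf_profile(traj, ca, superpose=False)
        writers.write_profile_csv(rmsf, out / f"rmsf_{label}.csv")
        profiles[label] = rmsf
        _, sasa_prof, sasa_tot = ts.sasa(traj.frames[-1], ref.atom_radii(),
                                         structure=ref)
        writers.write_profile_csv(sasa_prof,
                                  out / f"sasa_per_residue_{label}.csv")
        rows.append({"system": label,
                     "rmsd_mean_A": rmsd.values.mean(),
                     "rmsd_final_A": rmsd.values[-1],
                     "rg_mean_A": rg.values.mean(),
                     "rmsf_mean_A": rmsf.values.mean(),
                     "sasa_final_A2": sasa_tot})
    summary = pd.DataFrame(rows).set_index("system")
    summary.to_csv(out / "summary.csv", float_format="%.4f")

    delta = profiles["loop_variant"].values - profiles["baseline"].values
    resids = profiles["baseline"].resids
    pd.DataFrame({"resid": resids, "delta_rmsf_A": delta}).to_csv(
        out / "delta_rmsf.csv", index=False, float_format="%.4f")
    peak = resids[int(np.argmax(delta))]
    in_window = delta[(resids >= 37) & (resids <= 47)].mean()
    outside = delta[(resids < 37) | (resids > 47)].mean()

    print(summary.round(3).to_string())
    print(f"\nThe RMSF difference peaks at author residue {peak} "
          f"(planted window 37-47): mean delta inside the window "
          f"{in_window:.3f} Å vs {outside:.3f} Å outside. The planted "
          "loop destabilization is localized by the per-residue "
          "fluctuation profile, as expected for a CDR-loop-remodeling "
          "variant.")


if __name__ == "__main__":
    main()
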