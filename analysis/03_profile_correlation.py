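"""Pearson correlation of censored binding-energy profiles; kinome disk plot.

Transforms the affinity panel to log10(nM) with the 10 µM censoring ceiling
at 5, computes the full correlation matrix, and renders the disk plot of
one reference target's profile on the toy kinome layout.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from kinoprofile.affinity_io import read_affinity_table, to_binding_energy
from kinoprofile.profile_similarity import (
    correlation_matrix,
    kinome_disk_plot,
    profile_correlation,
    read_layout,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--inputs", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/correlation"))
    ap.add_argument("--reference", default=None)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    m = read_affinity_table(args.inputs / "affinity.csv")
    family = pd.read_csv(args.inputs / "families.csv", index_col=0)["family"]
    e = to_binding_energy(m)
    corr = correlation_matrix(e)
    corr.to_csv(args.out / "correlation_matrix.csv", index_label="target")

    ref = args.reference or m.target_ids[0]
    prof = profile_correlation(e, ref)
    kinome_disk_plot(prof, read_layout(args.inputs / "layout.csv"), args.out / "disk_plot.png")

    fam = family.reindex(corr.index).to_numpy()
    same = fam[:, None] == fam[None, :]
    off = ~np.eye(len(fam), dtype=bool)
    vals = corr.to_numpy()
    print(f"mean r within families {np.nanmean(vals[same & off]):.3f} "
          f"vs between {np.nanmean(vals[~same]):.3f}")
    top = prof.r.drop(ref).sort_values(ascending=False).head(3)
    partners = ", ".join(f"{t} (r={v:.2f})" for t, v in top.items())
    print(f"top partners of {ref}: {partners}")
    print(f"artifacts in {args.out}")


if __name__ == "__main__":
    main()
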