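"""Anchored superposition of a synthetic kinase-domain ensemble.

Generates an ensemble of rigidly displaced, noise-perturbed copies of a
reference coordinate set with two planted aromatic-ring sites, writes PDB
fixtures, superposes every member onto the reference on the hinge +
αF-helix anchors, and clusters the ring centroids across the superposed
ensemble.
"""

import argparse
from pathlib import Path

import numpy as np

from kinoprofile.structure_superpose import (
    AnchorSpec,
    aromatic_centroids,
    centroid_clusters,
    ensemble_rmsd,
    write_pdb,
)
from kinoprofile.synthetic_data import simulate_superposition_set


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/superposition"))
    ap.add_argument("--noise-sd", type=float, default=0.1, help="coordinate noise, Å")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    anchors = AnchorSpec((1, 4), (10, 30))
    sites = [np.array([0.0, 0.0, 0.0]), np.array([10.0, 0.0, 0.0])]
    ref, members, _ = simulate_superposition_set(
        n_structures=10, n_atoms=50, noise_sd=args.noise_sd,
        planted_centroid_sites=sites, seed=args.seed,
    )
    write_pdb(ref, args.out / "reference.pdb")
    table, mean_rmsd, superposed = ensemble_rmsd(members, ref, anchors)
    table.to_csv(args.out / "rmsd.csv", index=False)
    for mono in superposed:
        write_pdb(mono, args.out / f"superposed_{mono.source_id}.pdb")

    cents = aromatic_centroids([ref] + superposed, [1000, 1001])
    cents.to_csv(args.out / "centroids.csv", index=False)
    labels = centroid_clusters(cents[["x", "y", "z"]].to_numpy(), cutoff=2.0)
    cents.assign(cluster=labels).to_csv(args.out / "centroid_clusters.csv", index=False)

    print(f"mean anchor Cα RMSD {mean_rmsd:.3f} Å over {len(table)} members "
          f"(coordinate noise {args.noise_sd} Å)")
    print(f"ring centroids form {len(set(labels))} clusters at a 2 Å cutoff "
          f"({len(sites)} sites planted)")
    print(f"artifacts in {args.out}")


if __name__ == "__main__":
    main()
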