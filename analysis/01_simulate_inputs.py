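"""Generate the synthetic study inputs shared by the downstream analyses.

Writes the censored affinity panel (4 target families x 5 members against
60 inhibitors, last family selectivity-orthogonal with 8 dedicated
inhibitors), the family ground truth, a toy kinome layout, and the
two-class geometric descriptor table under results/synthetic/.
"""

import argparse
from pathlib import Path

from kinoprofile.affinity_io import write_affinity_table
from kinoprofile.activity_state_pls import write_descriptor_table
from kinoprofile.synthetic_data import (
    SimulationConfig,
    simulate_affinity_matrix,
    simulate_descriptors,
    toy_kinome_layout,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    matrix, truth = simulate_affinity_matrix(cfg)
    write_affinity_table(matrix, args.out / "affinity.csv")
    truth.family.rename("family").to_csv(args.out / "families.csv", index_label="target")
    toy_kinome_layout(matrix.target_ids, truth.family, seed=args.seed).to_csv(
        args.out / "layout.csv", index=False
    )
    desc = simulate_descriptors(seed=args.seed)
    write_descriptor_table(desc, args.out / "descriptors.csv")

    frac = matrix.censored.to_numpy().mean()
    print(f"affinity panel: {matrix.shape[0]} targets x {matrix.shape[1]} inhibitors, "
          f"{100 * frac:.1f}% censored at {cfg.censor_limit_nM:g} nM")
    print(f"outlier family: {truth.outlier_family} with dedicated inhibitors "
          f"{truth.dedicated_inhibitors[:3]}...")
    print(f"descriptors: {desc.X.shape[0]} structures x {desc.X.shape[1]} parameters")
    print(f"wrote inputs to {args.out}")


if __name__ == "__main__":
    main()
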