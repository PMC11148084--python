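#!/usr/bin/env python
"""Score and grade the screened genotypes.

At the screening dose, rescales each trait's STI across genotypes to [0, 1]
by the fuzzy membership function, averages to a per-genotype mean MFV, and
grades genotypes into five tolerance classes (HST..HSS) by furthest-
neighbour hierarchical clustering of the scores.
"""

import argparse
from pathlib import Path

import saltscreen as ss


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--screen", type=Path, default=Path("results/data/screen.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--clusters", type=int, default=5)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    table = ss.read_trait_table(args.screen)
    index = ss.build_index_table(table)
    ss.write_table(index, args.out_dir / "screen_indices.csv")

    mfv, scores, report = ss.evaluate_tolerance(index, k=args.clusters)
    ss.write_table(mfv.table, args.out_dir / "mfv_table.csv")
    ss.write_report(report, args.out_dir / "tolerance_report.csv")

    print(f"graded {len(report.table)} genotypes at "
          f"{index['concentration'].iloc[0]:g} mM/L")
    print("grade counts:", report.grade_counts)
    print(f"mean MFV range: {scores.min():.3f} .. {scores.max():.3f}")
    top = report.table.sort_values("mean_mfv", ascending=False).head(4)
    print("most tolerant genotypes:")
    print(top.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
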