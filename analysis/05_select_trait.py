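#!/usr/bin/env python
"""Identify the most reliable single screening trait.

Computes the Pearson correlation matrix among trait STIs at the screening
dose, regresses mean MFV on each trait's STI, and ranks traits by R^2; the
top-ranked trait is the recommended single-trait screen.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import saltscreen as ss
from saltscreen import data_io, indices, tolerance_eval, trait_selector


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indices", type=Path,
                    default=Path("results/screen_indices.csv"))
    ap.add_argument("--model", type=Path, default=Path("results/model.json"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    index = pd.read_csv(args.indices)
    mfv = tolerance_eval.build_mfv_table(index)
    scores = tolerance_eval.mean_mfv(mfv)
    sti = trait_selector.sti_pivot(indices.apply_undefined_policy(index))
    model = data_io.read_model(args.model) if args.model.exists() else None

    report = ss.build_reliability_report(sti, scores, model)
    report.correlation_matrix.round(3).to_csv(args.out_dir / "sti_correlations.csv")
    ss.write_table(report.per_trait_fit.round(4), args.out_dir / "trait_fits.csv")
    (args.out_dir / "selected_trait.json").write_text(
        json.dumps(report.rationale, indent=2), encoding="utf-8")

    print("STI correlation matrix:")
    print(report.correlation_matrix.round(3).to_string())
    print("\nper-trait fit of mean MFV on STI:")
    print(report.per_trait_fit.round(4).to_string(index=False))
    print(f"\nranking: {' > '.join(report.ranked_traits)}")
    print(f"selected screening trait: {report.selected_trait} "
          f"(R^2 = {report.rationale['r_squared']:.3f})")


if __name__ == "__main__":
    main()
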