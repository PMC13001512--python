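#!/usr/bin/env python
"""Concordance of the ATAC and G4 differential contrasts.

Joins the two chromatin contrasts over promoter-linked genes (the shared
feature universe), tabulates the signed quadrants, tests each against its
hypergeometric expectation, and reports direction-stratified fractions.
Writes <results>/concordance/*.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from g4chromatin.concordance import (
    direction_fractions,
    hypergeom_tests,
    quadrant_counts,
)
from g4chromatin.simulate import read_study


def per_gene(results: pd.DataFrame, links: dict[str, str]) -> pd.DataFrame:
    """Re-key a peak-level result table by promoter-linked gene."""
    sub = results[results["feature_id"].isin(links)].copy()
    sub["feature_id"] = sub["feature_id"].map(links)
    return sub.drop_duplicates("feature_id", keep="first")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = read_study(args.results / "study")
    outdir = args.results / "concordance"
    outdir.mkdir(parents=True, exist_ok=True)

    diff = {
        m: pd.read_csv(args.results / "differential" / f"{m}.tsv", sep="\t")
        for m in ("atac", "g4")
    }
    links = {
        m: dict(
            zip(truth_df.loc[truth_df["promoter_gene"] != "", "name"],
                truth_df.loc[truth_df["promoter_gene"] != "", "promoter_gene"])
        )
        for m, truth_df in (("atac", bundle.truth.atac), ("g4", bundle.truth.g4))
    }
    a = per_gene(diff["atac"], links["atac"])
    b = per_gene(diff["g4"], links["g4"])

    table = quadrant_counts(a, b)
    print(f"shared universe {table.n_universe} genes; "
          f"{table.n_double_differential} differential in both contrasts")
    for quad in ("++", "--", "+-", "-+"):
        print(f"  {quad}: {table.counts[quad]} "
              f"({100 * table.fractions[quad]:.1f}% of doubly-differential)")

    hyper = pd.DataFrame(
        [
            {"quadrant": r.quadrant, "observed": r.observed,
             "expected": r.expected, "fold": r.fold,
             "p_enrichment": r.p_upper, "p_depletion": r.p_lower}
            for r in hypergeom_tests(table)
        ]
    )
    hyper.to_csv(outdir / "hypergeometric.tsv", sep="\t", index=False)
    concordant = hyper[hyper["quadrant"].isin(["++", "--"])]
    print("same-sign quadrants vs hypergeometric expectation:")
    print(concordant.to_string(index=False))

    fractions = direction_fractions(a, b)
    fractions.to_csv(outdir / "direction_fractions.tsv", sep="\t")
    print("G4 status distribution within ATAC strata (rows sum to 1):")
    print(fractions.round(3).to_string())

    counts_df = pd.DataFrame(
        [{"quadrant": q, "count": c, "fraction": table.fractions[q]}
         for q, c in table.counts.items()]
    )
    counts_df.to_csv(outdir / "quadrants.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
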