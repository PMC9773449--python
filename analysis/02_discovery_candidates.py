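#!/usr/bin/env python
"""Discovery-phase analysis: summarize, normalize, filter, test, select.

Reads the simulated discovery peptide table, builds the protein matrix by
top-three-peptide averaging, equalises sample medians, keeps proteins
quantified in at least 4 of 7 patients per group, runs Welch tests with
Benjamini-Hochberg adjustment for all three pairwise group comparisons, and
assembles the candidate set (q < 0.05 plus presence/absence criteria plus a
literature list).  Writes per-comparison tables and candidates.tsv under
results/discovery/.
"""

import argparse
from pathlib import Path

import pandas as pd

from chemosig import discovery

ROOT = Path(__file__).resolve().parents[1]
LITERATURE = ["CT45", "CDK1", "CLDN3"]


def main() -> None:
    data = ROOT / "results" / "data"
    out = ROOT / "results" / "discovery"
    out.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(data / "discovery_peptides.csv")
    groups = pd.read_csv(data / "discovery_groups.csv").set_index("sample")["group"]

    matrix = discovery.top3_summarize(table, groups)
    matrix = discovery.equalize_median_normalize(matrix)
    filtered, removed = discovery.presence_filter(matrix, min_present=4)
    print(f"quantified {matrix.values.shape[0]} proteins; "
          f"{filtered.values.shape[0]} pass the 4-of-7 presence filter "
          f"({len(removed)} removed)")

    names = sorted(groups.unique())
    diffs = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = discovery.differential_test(filtered, (a, b))
            diffs.append(d)
            n_sig = int(d.table["significant"].sum())
            d.table.to_csv(out / f"diff_{a}_vs_{b}.tsv", sep="\t", index=False)
            print(f"  {a} vs {b}: {n_sig} proteins at q < 0.05")

    cand = discovery.select_candidates(diffs, matrix, LITERATURE)
    pd.DataFrame(
        {
            "protein": cand.proteins,
            "reasons": [";".join(cand.reasons[p]) for p in cand.proteins],
            "warning": [cand.warnings.get(p, "") for p in cand.proteins],
        }
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    by_reason = {
        r: len(cand.with_reason(r))
        for r in ("differential", "criterion_a", "criterion_b", "literature")
    }
    print(f"candidate set: {len(cand.proteins)} proteins {by_reason}")


if __name__ == "__main__":
    argparse.ArgumentParser().parse_args()
    main()
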