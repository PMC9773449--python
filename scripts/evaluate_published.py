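#!/usr/bin/env python
"""Evaluate a protein signature on externally supplied per-patient tables.

This is the integration path for real verification-cohort data, which is
not bundled with the package: supply (a) a quantitative matrix of log2
protein abundances with proteins as rows and patient ids as columns
(TSV/CSV, first column = protein id), and (b) a clinical CSV in the
package dialect (patient_id, age, menopausal_status [pre|post], stage,
ca125, treatment [surgery|neoadjuvant], tfip_months, status). Columns with
other names can be adapted with --rename OLD=NEW pairs for the clinical
file.

The script fits and compares whole-cohort logistic models for the given
protein combination alone, the four clinical covariates alone, and both
combined, and repeats the protein evaluation on the chemoresistant vs
partially chemosensitive (TFIp 6-12 months) subgroup.

Example:
    python scripts/evaluate_published.py \
        --matrix tableS5_log2_areas.tsv --clinical tableS2_clinical.csv \
        --proteins TKT,LAMC1,FUCO --out results/published_eval.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from chemosig import io, roc, selection
from chemosig.clinical import CHEMORESISTANT, CHEMOSENSITIVE, cohort_frame


def main() -> None:
    ap = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    ap.add_argument("--matrix", required=True,
                    help="proteins x patients log2 abundance table (TSV/CSV)")
    ap.add_argument("--clinical", required=True, help="clinical CSV")
    ap.add_argument("--proteins", required=True,
                    help="comma-separated protein ids forming the signature")
    ap.add_argument("--rename", nargs="*", default=[],
                    metavar="OLD=NEW", help="clinical column renames")
    ap.add_argument("--out", default=None, help="optional JSON output path")
    args = ap.parse_args()

    sep = "\t" if args.matrix.endswith((".tsv", ".txt")) else ","
    matrix = pd.read_csv(args.matrix, sep=sep, index_col=0)

    clinical_csv = args.clinical
    if args.rename:
        renames = dict(pair.split("=", 1) for pair in args.rename)
        df = pd.read_csv(args.clinical).rename(columns=renames)
        clinical_csv = Path(args.clinical).with_suffix(".renamed.csv")
        df.to_csv(clinical_csv, index=False)
    records, errors = io.read_clinical(clinical_csv)
    if errors:
        print(f"warning: {len(errors)} clinical rows failed validation")
    clinical = cohort_frame(records)

    proteins = args.proteins.split(",")
    missing = [p for p in proteins if p not in matrix.index]
    if missing:
        raise SystemExit(f"proteins not in matrix: {missing}")
    common = matrix.columns.intersection(clinical.index)
    two_group = clinical.loc[common, "group"].isin(
        [CHEMORESISTANT, CHEMOSENSITIVE]
    )
    ids = common[two_group.to_numpy()]
    features = matrix.loc[proteins, ids].T
    labels = (clinical.loc[ids, "group"] == CHEMORESISTANT).rename("resistant")

    ev = selection.evaluate_with_clinical(features, clinical.loc[ids], labels)
    print(f"n = {ev.n_used} ({len(ev.excluded)} excluded for missing covariates)")
    for name, s in (("proteins", ev.proteins), ("clinical", ev.clinical),
                    ("combined", ev.combined)):
        print(f"  {name}: AUC {s.auc:.2f} (95% CI {s.ci_low:.2f}-{s.ci_high:.2f})")
    print(f"  paired proteins vs combined: p = {ev.p_proteins_vs_combined:.2f}")

    partial_ids = selection.partial_sensitivity_subset(clinical.loc[ids])
    sub = features.index.intersection(partial_ids)
    ps = roc.summarize(
        selection.fit_logistic(
            features.loc[sub].to_numpy(float),
            labels.loc[sub].to_numpy(),
            tuple(proteins),
        ).scores,
        labels.loc[sub].to_numpy(),
    )
    print(f"partial-sensitivity subgroup (n={len(sub)}): "
          f"AUC {ps.auc:.2f} (95% CI {ps.ci_low:.2f}-{ps.ci_high:.2f})")

    if args.out:
        out = Path(args.out)
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(
            {
                "proteins": {"auc": ev.proteins.auc,
                             "ci": [ev.proteins.ci_low, ev.proteins.ci_high]},
                "clinical": {"auc": ev.clinical.auc,
                             "ci": [ev.clinical.ci_low, ev.clinical.ci_high]},
                "combined": {"auc": ev.combined.auc,
                             "ci": [ev.combined.ci_low, ev.combined.ci_high]},
                "p_proteins_vs_combined": ev.p_proteins_vs_combined,
                "partial_sensitivity": {"auc": ps.auc,
                                        "ci": [ps.ci_low, ps.ci_high],
                                        "n": int(len(sub))},
            },
            indent=2, sort_keys=True,
        ))


if __name__ == "__main__":
    main()
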