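#!/usr/bin/env python
"""Clinical covariates and the partial-chemosensitivity subgroup.

Whole-cohort logistic models for the consensus proteins alone, the four
clinical covariates alone (age, menopausal status, log CA125, primary
treatment), and their combination, each summarized by ROC with 95% CI plus
a paired test comparing the proteins-only and combined curves.  The same
evaluation is repeated on the chemoresistant vs partially chemosensitive
(TFIp 6-12 months) subgroup.  Writes evaluation.json under
results/clinical/.
"""

import argparse
import json
from pathlib import Path

from chemosig import io, selection
from chemosig.clinical import CHEMORESISTANT, CHEMOSENSITIVE, cohort_frame

ROOT = Path(__file__).resolve().parents[1]


def _fmt(name, s):
    return (f"  {name}: AUC {s.auc:.3f} (95% CI {s.ci_low:.3f}-{s.ci_high:.3f}),"
            f" sens/spec at Youden {s.sensitivity_at_youden:.2f}/"
            f"{s.specificity_at_youden:.2f}")


def main() -> None:
    out = ROOT / "results" / "clinical"
    out.mkdir(parents=True, exist_ok=True)

    records, _ = io.read_clinical(ROOT / "results" / "data" / "cohort.csv")
    clinical = cohort_frame(records)
    consensus = json.loads(
        (ROOT / "results" / "selection" / "consensus.json").read_text()
    )
    pm = io.read_matrix(ROOT / "results" / "prm" / "protein_matrix.tsv",
                        clinical["group"])
    keep = pm.groups.isin([CHEMORESISTANT, CHEMOSENSITIVE])
    features = pm.values.T[keep.to_numpy()][consensus["features"]]
    labels = (pm.groups[keep] == CHEMORESISTANT).rename("resistant")

    ev = selection.evaluate_with_clinical(
        features, clinical.loc[features.index], labels
    )
    print(f"whole cohort (n={ev.n_used}, {len(ev.excluded)} excluded for "
          f"incomplete covariates):")
    print(_fmt("proteins " + "+".join(consensus["features"]), ev.proteins))
    print(_fmt("clinical only", ev.clinical))
    print(_fmt("combined", ev.combined))
    print(f"  paired ROC comparison (proteins vs combined): "
          f"p = {ev.p_proteins_vs_combined:.3f}")

    partial_ids = selection.partial_sensitivity_subset(
        clinical.loc[features.index]
    )
    pe = selection.evaluate_with_clinical(
        features.loc[features.index.intersection(partial_ids)],
        clinical.loc[clinical.index.intersection(partial_ids)],
        labels.loc[labels.index.intersection(partial_ids)],
    )
    print(f"chemoresistant vs partially chemosensitive (TFIp 6-12 months, "
          f"n={pe.n_used}):")
    print(_fmt("proteins", pe.proteins))
    print(_fmt("combined", pe.combined))

    def roc_dict(s):
        return {"auc": s.auc, "ci": [s.ci_low, s.ci_high],
                "youden_threshold": s.youden_threshold,
                "sensitivity": s.sensitivity_at_youden,
                "specificity": s.specificity_at_youden}

    (out / "evaluation.json").write_text(json.dumps(
        {
            "features": consensus["features"],
            "n_used": ev.n_used,
            "n_excluded": len(ev.excluded),
            "proteins": roc_dict(ev.proteins),
            "clinical": roc_dict(ev.clinical),
            "combined": roc_dict(ev.combined),
            "p_proteins_vs_combined": ev.p_proteins_vs_combined,
            "partial_sensitivity": {
                "n_used": pe.n_used,
                "proteins": roc_dict(pe.proteins),
                "combined": roc_dict(pe.combined),
            },
        },
        indent=2, sort_keys=True,
    ))


if __name__ == "__main__":
    argparse.ArgumentParser().parse_args()
    main()
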