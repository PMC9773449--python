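#!/usr/bin/env python
"""Simulate the study cohorts and raw quantitative datasets.

Writes, under results/data/:
  - discovery_peptides.csv + discovery_groups.csv — a 3 x 7 discovery cohort
    at the peptide level, with two planted abundance effects and one
    presence/absence protein;
  - cohort.csv — an 88-patient verification cohort (25 chemoresistant /
    63 chemosensitive) with correlated clinical covariates;
  - transitions.csv — the PRM transition table for a 29-protein panel with
    three signal proteins (log2 effect 1.5), per-run scale biases,
    intensity-dependent dropout and occasional interfered transitions;
  - replicate_transitions.csv — a 10-patient, 3-replicate assay-evaluation
    subset used for technical-CV reporting.
"""

import argparse
from pathlib import Path

from chemosig import io, synth

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)

    disc = synth.DiscoverySimSpec(
        n_proteins=120,
        presence_absence_proteins=("PROT10",),
        effect_proteins=("PROT01", "PROT02"),
        effect_log2=1.5,
        seed=seed,
    )
    table, groups = synth.generate_discovery_dataset(disc)
    table.to_csv(out / "discovery_peptides.csv", index=False)
    groups.rename("group").to_csv(out / "discovery_groups.csv")
    print(f"discovery: {groups.size} samples x {disc.n_proteins} proteins "
          f"({len(table)} peptide measurements)")

    cohort_spec = synth.CohortSpec(seed=seed + 1)
    records = synth.generate_cohort(cohort_spec)
    io.write_cohort(records, out / "cohort.csv")
    print(f"verification cohort: {len(records)} patients "
          f"({cohort_spec.n_resistant} chemoresistant)")

    prm_spec = synth.PrmSimSpec(seed=seed + 2)
    transitions = synth.generate_prm_dataset(records, prm_spec)
    io.write_transitions(transitions, out / "transitions.csv")
    print(f"PRM: {len(transitions)} transition rows, "
          f"{transitions['peptide'].nunique()} peptides, "
          f"{prm_spec.n_proteins} proteins, signal = "
          f"{'+'.join(prm_spec.signal_proteins)}")

    rep_spec = synth.PrmSimSpec(seed=seed + 3, replicates=3)
    rep_table = synth.generate_prm_dataset(records[:10], rep_spec)
    io.write_transitions(rep_table, out / "replicate_transitions.csv")
    print(f"replicate assay subset: {rep_table['run_id'].nunique()} runs "
          f"over 10 patients")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    main(ap.parse_args().seed)
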