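"""CSV dialects, configuration, and the end-to-end pipeline driver.

All tables are comma-separated UTF-8 with a required header and dot
decimals.  The transition dialect is
``run_id,patient_id,protein,peptide,fragment,channel,area,rt`` with channel
in {endogenous, standard}; a column/token mapping adapts foreign exports
(e.g. Skyline transition reports using light/heavy channel labels).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import prm, roc, selection, synth
from .clinical import CHEMORESISTANT, CHEMOSENSITIVE, COHORT_COLUMNS, ClinicalRecord, cohort_frame
from .matrix import ProteinMatrix

#: accepted channel spellings -> canonical channel
CHANNEL_TOKENS = {
    "endogenous": prm.ENDOGENOUS,
    "endo": prm.ENDOGENOUS,
    "light": prm.ENDOGENOUS,
    "standard": prm.STANDARD,
    "heavy": prm.STANDARD,
    "internal_standard": prm.STANDARD,
}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_cohort(records: list[ClinicalRecord], path) -> None:
    df = cohort_frame(records).reset_index()[list(COHORT_COLUMNS)]
    df.to_csv(path, index=False)


def read_clinical(path) -> tuple[list[ClinicalRecord], list[dict]]:
    """Typed clinical records plus a per-row error report.

    Rows failing validation are collected, not silently dropped.  A TFIp of
    exactly 6 months is a hard error: the boundary belongs to neither
    response group.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical CSV missing columns {sorted(missing)}")
    records: list[ClinicalRecord] = []
    errors: list[dict] = []
    for i, row in df.iterrows():
        tfip = row["tfip_months"]
        tfip = None if pd.isna(tfip) else float(tfip)
        if tfip == 6.0:
            raise ValueError(
                f"row {i}: TFIp of exactly 6 months belongs to neither group"
            )
        ca125 = row["ca125"]
        try:
            records.append(
                ClinicalRecord(
                    patient_id=str(row["patient_id"]),
                    age=float(row["age"]),
                    menopausal_status=str(row["menopausal_status"]),
                    stage=str(row["stage"]),
                    ca125=None if pd.isna(ca125) else float(ca125),
                    treatment=str(row["treatment"]),
                    tfip_months=tfip,
                    status=str(row["status"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append({"row": int(i), "patient_id": str(row["patient_id"]),
                           "error": str(exc)})
    return records, errors


def write_transitions(table: pd.DataFrame, path) -> None:
    table[list(synth.TRANSITION_COLUMNS)].to_csv(path, index=False)


def read_transitions(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Validated long-format transition table.

    ``column_map`` renames foreign headers to the canonical dialect before
    validation.  Channel tokens are normalized; unknown tokens, duplicate
    (run, peptide, fragment, channel) rows and negative areas are errors.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if column_map:
        df = df.rename(columns={k.lower(): v for k, v in column_map.items()})
    missing = set(synth.TRANSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transition CSV missing columns {sorted(missing)}")
    df = df[list(synth.TRANSITION_COLUMNS)].copy()
    if df.empty:
        return df
    channel = df["channel"].astype(str).str.strip().str.lower()
    unknown = sorted(set(channel) - set(CHANNEL_TOKENS))
    if unknown:
        raise ValueError(f"unknown channel tokens: {unknown}")
    df["channel"] = channel.map(CHANNEL_TOKENS)
    neg = df.index[df["area"].astype(float) < 0]
    if len(neg):
        raise ValueError(f"negative area at row {int(neg[0])}")
    dup = df.duplicated(["run_id", "peptide", "fragment", "channel"])
    if dup.any():
        raise ValueError(
            f"duplicate (run, peptide, fragment, channel) rows, first at "
            f"row {int(df.index[dup][0])}"
        )
    return df


def write_matrix(matrix: ProteinMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t")


def read_matrix(path, groups: pd.Series | None = None) -> ProteinMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ProteinMatrix(values=values, groups=groups)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class PipelineConfig(BaseModel):
    """Everything a verification-phase run needs, thresholds included.

    The seed is mandatory: a run without an explicit seed is not
    reproducible and is refused.  A frozen copy of the resolved config is
    written beside the outputs.
    """

    seed: int
    out_dir: str
    clinical_csv: Optional[str] = None   # simulate a cohort when absent
    transitions_csv: Optional[str] = None
    cohort: synth.CohortSpec | None = None
    prm_sim: synth.PrmSimSpec | None = None
    prm_params: prm.PrmParams = Field(default_factory=prm.PrmParams)
    n_repeats: int = 500
    delta_auc: float = 0.02
    split_ratio: tuple[int, int] = (8, 10)
    stratified: bool = True
    max_features: Optional[int] = None
    partial_window: tuple[float, float] = (6.0, 12.0)
    ci_level: float = 0.95


def _stage(log: list[str], msg: str) -> None:
    log.append(msg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Quantify -> select -> consensus -> clinical/partial evaluation.

    Writes, under ``out_dir``: the input tables (when simulated), the
    normalized protein matrix, a QC report, the repeats and combination
    frequency tables, the consensus model JSON, ROC point tables, a frozen
    config copy, and a manifest with input checksums.  Returns the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # --- inputs ------------------------------------------------------------
    if config.clinical_csv:
        records, errors = read_clinical(config.clinical_csv)
        if errors:
            _stage(log, f"clinical: {len(errors)} invalid rows reported")
        clinical_path = Path(config.clinical_csv)
    else:
        spec = config.cohort or synth.CohortSpec(seed=config.seed)
        spec = spec.model_copy(update={"seed": spec.seed})
        records = synth.generate_cohort(spec)
        clinical_path = out / "cohort.csv"
        write_cohort(records, clinical_path)
    clinical = cohort_frame(records)
    _stage(log, f"cohort: {len(records)} patients "
                f"({(clinical['group'] == CHEMORESISTANT).sum()} resistant, "
                f"{(clinical['group'] == CHEMOSENSITIVE).sum()} sensitive)")

    prm_params = config.prm_params
    if config.transitions_csv:
        table = read_transitions(config.transitions_csv)
        transitions_path = Path(config.transitions_csv)
    else:
        sim = config.prm_sim or synth.PrmSimSpec(seed=config.seed + 1)
        table = synth.generate_prm_dataset(records, sim)
        transitions_path = out / "transitions.csv"
        write_transitions(table, transitions_path)
        if prm_params.background_floor is None:
            # the simulated assay's detection floor is the background estimate
            prm_params = prm_params.model_copy(update={"background_floor": sim.lod})
    _stage(log, f"transitions: {len(table)} rows, "
                f"{table['peptide'].nunique()} peptides")

    # --- quantification ----------------------------------------------------
    groups = clinical["group"]
    result = prm.quantify(table, prm_params, groups=groups)
    _stage(log, f"quantify: {result.report['n_proteins']} proteins x "
                f"{result.report['n_samples']} samples; dropped "
                f"{result.report['n_peptides_dropped']} peptides, "
                f"{result.report['n_runs_dropped']} runs")
    write_matrix(result.protein_matrix, out / "protein_matrix.tsv")
    (out / "qc_report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True)
    )

    # --- signature selection ----------------------------------------------
    pm = result.protein_matrix
    keep = pm.groups.isin([CHEMORESISTANT, CHEMOSENSITIVE])
    features = pm.values.T[keep.to_numpy()]
    labels = (pm.groups[keep] == CHEMORESISTANT).rename("resistant")
    sel_cfg = selection.SelectionConfig(
        n_repeats=config.n_repeats,
        delta_auc=config.delta_auc,
        split_ratio=config.split_ratio,
        stratified=config.stratified,
        max_features=config.max_features,
        seed=config.seed + 2,
    )
    repeats = selection.run_repeats(features, labels, sel_cfg)
    n_failed = sum(r.failed for r in repeats)
    _stage(log, f"selection: {len(repeats)} repeats, {n_failed} failed")
    pd.DataFrame(
        {
            "repeat": [r.index for r in repeats],
            "combination": ["+".join(r.combination) for r in repeats],
            "n_proteins": [len(r.combination) for r in repeats],
            "validation_auc": [r.val_auc for r in repeats],
            "failed": [r.failed for r in repeats],
        }
    ).to_csv(out / "repeats.tsv", sep="\t", index=False)

    cons = selection.consensus(repeats, features, labels, config.ci_level)
    cons.frequency_table.to_csv(out / "combination_frequency.tsv", sep="\t",
                                index=False)
    _stage(log, f"consensus: {'+'.join(cons.features)} "
                f"(selected {cons.frequency}/{cons.n_repeats}), "
                f"whole-cohort AUC {cons.roc_summary.auc:.3f}")

    # --- clinical combination & partial-sensitivity subgroup ---------------
    evaluation = selection.evaluate_with_clinical(
        features[list(cons.features)], clinical.loc[features.index], labels,
        config.ci_level,
    )
    _stage(log, f"clinical: combined AUC {evaluation.combined.auc:.3f} "
                f"(proteins {evaluation.proteins.auc:.3f}, "
                f"clinical {evaluation.clinical.auc:.3f}, "
                f"p={evaluation.p_proteins_vs_combined:.3f})")
    partial_ids = selection.partial_sensitivity_subset(
        clinical.loc[features.index], config.partial_window
    )
    partial_eval = selection.evaluate_with_clinical(
        features.loc[features.index.intersection(partial_ids), list(cons.features)],
        clinical.loc[clinical.index.intersection(partial_ids)],
        labels.loc[labels.index.intersection(partial_ids)],
        config.ci_level,
    )
    _stage(log, f"partial-sensitivity subgroup: n={len(partial_ids)}, "
                f"proteins AUC {partial_eval.proteins.auc:.3f}")

    consensus_json = {
        "features": list(cons.features),
        "frequency": cons.frequency,
        "n_repeats": cons.n_repeats,
        "coefficients": dict(zip(cons.model.feature_names,
                                 [float(c) for c in cons.model.coef])),
        "intercept": float(cons.model.intercept),
        "auc": cons.roc_summary.auc,
        "ci": [cons.roc_summary.ci_low, cons.roc_summary.ci_high],
        "youden_threshold": cons.roc_summary.youden_threshold,
        "sensitivity": cons.roc_summary.sensitivity_at_youden,
        "specificity": cons.roc_summary.specificity_at_youden,
        "clinical_combined_auc": evaluation.combined.auc,
        "clinical_combined_ci": [evaluation.combined.ci_low,
                                 evaluation.combined.ci_high],
        "clinical_only_auc": evaluation.clinical.auc,
        "p_proteins_vs_combined": evaluation.p_proteins_vs_combined,
        "partial_sensitivity_auc": partial_eval.proteins.auc,
        "partial_sensitivity_n": len(partial_ids),
    }
    (out / "consensus.json").write_text(
        json.dumps(consensus_json, indent=2, sort_keys=True)
    )
    cons.roc_summary.points.to_csv(out / "roc_points_proteins.tsv", sep="\t",
                                   index=False)
    evaluation.combined.points.to_csv(out / "roc_points_combined.tsv", sep="\t",
                                      index=False)

    # --- frozen config + manifest ------------------------------------------
    frozen = config.model_dump(mode="json")
    (out / "config.frozen.yaml").write_text(yaml.safe_dump(frozen, sort_keys=True))
    manifest = {
        "config": frozen,
        "seed": config.seed,
        "inputs": {
            "clinical": {"path": str(clinical_path), "sha256": _sha256(clinical_path)},
            "transitions": {"path": str(transitions_path),
                            "sha256": _sha256(transitions_path)},
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
        "log": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
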