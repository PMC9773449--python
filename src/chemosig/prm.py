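"""Verification-phase targeted (PRM) quantification.

Transition QC replaces the expert chromatogram review of a targeted assay
with explicit numeric surrogates: a product ion is rejected when its removal
materially improves the correlation between the endogenous and the
internal-standard fragment-intensity patterns (interference), or when its
endogenous and standard retention times disagree; a peptide fails when too
few traces survive.  Quantification then proceeds by summing accepted
fragment areas, replacing sub-LOD values with a background estimate,
equalising internal-standard medians across runs, dropping failing peptides
and low-quality samples, rolling up the best peptide per protein, and
imputing remaining gaps with the per-protein minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .matrix import ProteinMatrix

ENDOGENOUS = "endogenous"
STANDARD = "standard"


class PrmParams(BaseModel):
    """Thresholds for transition QC and downstream quantification."""

    min_fragments: int = Field(3, ge=1)
    interference_margin: float = Field(0.1, gt=0.0)
    rt_window_min: float = Field(1.0, gt=0.0)
    background_quantile: float = Field(0.05, ge=0.0, le=0.5)
    background_floor: Optional[float] = None  # fixed linear-area floor, if any
    peptide_fail_threshold: float = Field(0.5, ge=0.0, le=1.0)
    sample_missing_threshold: float = Field(0.5, ge=0.0, le=1.0)
    best_peptide_rule: str = "lowest_cv"  # or "max_abundance"


@dataclass
class QcVerdict:
    """Accepted/rejected fragments for one (run, peptide)."""

    run_id: str
    peptide: str
    accepted: tuple[str, ...]
    rejected: dict[str, str]  # fragment -> reason
    passed: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 1.0  # flat pattern: no interference evidence either way
    return float(np.corrcoef(x, y)[0, 1])


def qc_transitions(
    table: pd.DataFrame, params: PrmParams | None = None
) -> dict[tuple[str, str], QcVerdict]:
    """Evaluate product-ion traces per (run, peptide).

    Rejection reasons: ``rt_outlier`` when |rt_endogenous - rt_standard|
    exceeds the window; ``interference`` when leave-one-fragment-out removal
    improves the endogenous/standard intensity-pattern correlation by more
    than the margin (assessed only while >= 4 detected fragments remain,
    below which the leave-one-out correlation is degenerate); and
    ``too_few_traces`` for undetected endogenous fragments.  A peptide passes
    when at least ``min_fragments`` fragments are accepted.
    """
    params = params or PrmParams()
    wide = table.pivot_table(
        index=["run_id", "peptide", "fragment"],
        columns="channel",
        values=["area", "rt"],
        aggfunc="first",
    )
    if ("area", STANDARD) not in wide.columns:
        raise ValueError("no internal-standard rows in transition table")
    verdicts: dict[tuple[str, str], QcVerdict] = {}
    for (run, pep), sub in wide.groupby(level=[0, 1], sort=True):
        frags = sub.index.get_level_values("fragment").to_numpy()
        e_area = sub[("area", ENDOGENOUS)].to_numpy(dtype=float) \
            if ("area", ENDOGENOUS) in sub.columns else np.full(len(frags), np.nan)
        s_area = sub[("area", STANDARD)].to_numpy(dtype=float)
        e_rt = sub[("rt", ENDOGENOUS)].to_numpy(dtype=float) \
            if ("rt", ENDOGENOUS) in sub.columns else np.full(len(frags), np.nan)
        s_rt = sub[("rt", STANDARD)].to_numpy(dtype=float)
        if np.isnan(s_area).all():
            raise ValueError(f"peptide {pep!r} has no standard rows in run {run!r}")
        rejected: dict[str, str] = {}
        detected = ~np.isnan(e_area)
        for f in frags[~detected]:
            rejected[str(f)] = "too_few_traces"
        # retention-time co-elution of endogenous and standard traces
        rt_bad = detected & (np.abs(e_rt - s_rt) > params.rt_window_min)
        for f in frags[rt_bad]:
            rejected[str(f)] = "rt_outlier"
        live = detected & ~rt_bad
        # leave-one-out interference screen on the intensity patterns
        while live.sum() >= 4:
            idx = np.nonzero(live)[0]
            e, s = e_area[idx], s_area[idx]
            base = _pearson(e, s)
            best_gain, best_i = 0.0, -1
            for k in range(len(idx)):
                mask = np.ones(len(idx), dtype=bool)
                mask[k] = False
                gain = _pearson(e[mask], s[mask]) - base
                if gain > best_gain:
                    best_gain, best_i = gain, k
            if best_gain > params.interference_margin:
                bad = idx[best_i]
                rejected[str(frags[bad])] = "interference"
                live[bad] = False
            else:
                break
        accepted = tuple(str(f) for f in frags[live])
        verdicts[(str(run), str(pep))] = QcVerdict(
            run_id=str(run),
            peptide=str(pep),
            accepted=accepted,
            rejected=rejected,
            passed=len(accepted) >= params.min_fragments,
        )
    return verdicts


def sum_peptide_area(
    table: pd.DataFrame, verdicts: dict[tuple[str, str], QcVerdict]
) -> pd.DataFrame:
    """Sum accepted fragment areas per (run, peptide, channel).

    Peptides failing QC in a run yield no value for that run.  The result is
    wide on channel: columns run_id, patient_id, protein, peptide,
    endogenous, standard.
    """
    keep_keys = set()
    for (run, pep), v in verdicts.items():
        if v.passed:
            for f in v.accepted:
                keep_keys.add((run, pep, f))
    key = list(zip(table["run_id"], table["peptide"], table["fragment"]))
    mask = np.fromiter((k in keep_keys for k in key), dtype=bool, count=len(key))
    sub = table[mask]
    agg = (
        sub.groupby(["run_id", "patient_id", "protein", "peptide", "channel"])["area"]
        .sum()
        .unstack("channel")
        .reset_index()
    )
    for ch in (ENDOGENOUS, STANDARD):
        if ch not in agg.columns:
            agg[ch] = np.nan
    return agg[["run_id", "patient_id", "protein", "peptide", ENDOGENOUS, STANDARD]]


def estimate_background(
    areas: pd.DataFrame, params: PrmParams | None = None
) -> pd.Series:
    """Per-peptide background estimate from the observed endogenous areas.

    A low quantile of each peptide's endogenous distribution, optionally
    raised to a fixed floor.
    """
    params = params or PrmParams()
    bg = areas.groupby("peptide")[ENDOGENOUS].quantile(params.background_quantile)
    if params.background_floor is not None:
        bg = bg.clip(lower=params.background_floor)
    return bg


def replace_below_lod(
    areas: pd.DataFrame, background: pd.Series | float
) -> pd.DataFrame:
    """Replace sub-LOD endogenous areas with the background estimate.

    Endogenous areas below the peptide's background are set to that
    background and flagged ``below_lod``.
    """
    out = areas.copy()
    if np.isscalar(background):
        bg = pd.Series(float(background), index=out["peptide"].unique())
    else:
        bg = background.astype(float)
    if (bg <= 0).any():
        raise ValueError("background estimates must be positive")
    per_row = out["peptide"].map(bg)
    if per_row.isna().any():
        missing = sorted(out.loc[per_row.isna(), "peptide"].unique())
        raise ValueError(f"no background estimate for peptides {missing[:5]}")
    below = out[ENDOGENOUS].notna() & (out[ENDOGENOUS] < per_row)
    out.loc[below, ENDOGENOUS] = per_row[below]
    out["below_lod"] = below
    return out


@dataclass
class PeptideQuantMatrix:
    """Peptide x run log2 matrices after internal-standard normalization."""

    endogenous: pd.DataFrame  # log2, peptides x runs, NaN = missing
    standard: pd.DataFrame
    shifts: pd.Series  # per-run log2 shift that was applied
    flags: dict[str, pd.DataFrame] = field(default_factory=dict)


def normalize_by_standards(
    areas: pd.DataFrame,
    target: float | None = 0.0,
    reference: pd.DataFrame | None = None,
) -> PeptideQuantMatrix:
    """Equalise internal-standard medians across runs on the log2 scale.

    Per run, the shift is the target minus that run's median standard log2
    area; the same shift is added to every endogenous and standard value of
    the run, so endogenous/standard ratios are untouched and multiplicative
    run biases cancel exactly.  The default target of 0 expresses abundances
    as log2 ratios to the run's internal-standard median — the natural scale
    for stable-isotope-anchored quantification, and one on which the
    normalized output is fully independent of per-run scale biases.
    ``target=None`` uses the median of run medians instead, preserving the
    raw abundance scale at the cost of a bias-dependent global offset.

    ``reference`` optionally supplies the standard areas used for the run
    medians as a long table (run_id, peptide, area) — e.g. peptide-level
    standard sums over *all* fragments.  The spiked channel is complete by
    design, so anchoring the medians on the full standard signal keeps the
    per-run shifts independent of which endogenous fragments happened to
    survive QC in a given run.
    """
    endo = np.log2(
        areas.pivot_table(index="peptide", columns="run_id", values=ENDOGENOUS,
                          aggfunc="first")
    )
    std = np.log2(
        areas.pivot_table(index="peptide", columns="run_id", values=STANDARD,
                          aggfunc="first")
    )
    std = std.reindex(index=endo.index, columns=endo.columns)
    if reference is not None:
        ref = np.log2(
            reference.pivot_table(index="peptide", columns="run_id",
                                  values="area", aggfunc="first")
        ).reindex(columns=endo.columns)
        run_medians = ref.median(axis=0, skipna=True)
    else:
        run_medians = std.median(axis=0, skipna=True)
    if run_medians.isna().any():
        bad = list(run_medians.index[run_medians.isna()])
        raise ValueError(f"runs with no standard values: {bad}")
    if target is None:
        target = float(run_medians.median())
    shifts = target - run_medians
    flags = {}
    if "below_lod" in areas.columns:
        flags["below_lod"] = (
            areas.pivot_table(index="peptide", columns="run_id",
                              values="below_lod", aggfunc="first")
            .reindex(index=endo.index, columns=endo.columns)
            .eq(True)
        )
    return PeptideQuantMatrix(
        endogenous=endo.add(shifts, axis=1),
        standard=std.add(shifts, axis=1),
        shifts=shifts,
        flags=flags,
    )


def compute_cv(
    areas: pd.DataFrame,
    *,
    value_col: str = ENDOGENOUS,
    sample_col: str = "patient_id",
    replicate_col: str = "run_id",
) -> pd.Series:
    """Percent technical CV per peptide from replicate linear-scale areas.

    For each (peptide, sample) with >= 2 replicate measurements the CV is
    sample standard deviation / mean x 100; the per-peptide value is the
    median over samples.  Zero-mean replicate sets are undefined and skipped.
    """
    def _cv(v: pd.Series) -> float:
        v = v.dropna()
        if len(v) < 2:
            return np.nan
        m = v.mean()
        if m == 0:
            return np.nan
        return float(v.std(ddof=1) / m * 100.0)

    per_sample = areas.groupby(["peptide", sample_col])[value_col].apply(_cv)
    return per_sample.groupby("peptide").median().rename("cv_percent")


def replicate_cv(
    table: pd.DataFrame,
    verdicts: dict[tuple[str, str], QcVerdict],
    shifts: pd.Series,
    run_patient: pd.Series,
) -> pd.Series:
    """Technical CV per peptide from replicate injections.

    Per (patient, peptide), areas are summed over the fragments accepted in
    *every* replicate run (so the replicates quantify the same ions) and
    multiplied by the run's internal-standard normalization factor (so
    per-run loading biases cancel); the CV is then sd/mean x 100 over
    replicates, medianed over patients.
    """
    endo = table[table["channel"] == ENDOGENOUS]
    factor = np.exp2(shifts)
    rows = []
    for (patient, pep), sub in endo.groupby(["patient_id", "peptide"]):
        runs = sub["run_id"].unique()
        if len(runs) < 2:
            continue
        accepted = [set(verdicts[(r, pep)].accepted)
                    for r in runs if (r, pep) in verdicts]
        if len(accepted) < len(runs):
            continue
        shared = set.intersection(*accepted)
        if not shared:
            continue
        use = sub[sub["fragment"].isin(shared)]
        per_run = use.groupby("run_id")["area"].sum() * factor.reindex(runs)
        rows.append((pep, patient, per_run.to_numpy()))
    records = []
    for pep, patient, areas in rows:
        m = areas.mean()
        if m > 0 and len(areas) >= 2:
            records.append((pep, float(np.std(areas, ddof=1) / m * 100.0)))
    per = pd.DataFrame(records, columns=["peptide", "cv"])
    return per.groupby("peptide")["cv"].median().rename("cv_percent")


def drop_failed(
    pq: PeptideQuantMatrix,
    verdicts: dict[tuple[str, str], QcVerdict],
    params: PrmParams | None = None,
) -> tuple[PeptideQuantMatrix, list[str], list[str]]:
    """Remove peptides failing QC too often and low-quality runs.

    A peptide is dropped when it fails QC in more than
    ``peptide_fail_threshold`` of the runs; a run is dropped when, after
    peptide removal, more than ``sample_missing_threshold`` of its peptide
    values are missing.
    """
    params = params or PrmParams()
    runs = list(pq.endogenous.columns)
    peptides = list(pq.endogenous.index)
    run_pos = {r: j for j, r in enumerate(runs)}
    pep_pos = {p: i for i, p in enumerate(peptides)}
    # a peptide absent from a run's verdicts never ran there; count as failed
    fail = np.ones((len(peptides), len(runs)), dtype=bool)
    for (run, pep), v in verdicts.items():
        i, j = pep_pos.get(pep), run_pos.get(run)
        if i is not None and j is not None and v.passed:
            fail[i, j] = False
    frac_fail = pd.Series(fail.mean(axis=1), index=pd.Index(peptides, name="peptide"))
    dropped_peptides = list(frac_fail.index[frac_fail > params.peptide_fail_threshold])
    endo = pq.endogenous.drop(index=dropped_peptides)
    missing_frac = endo.isna().mean(axis=0)
    dropped_runs = list(missing_frac.index[missing_frac > params.sample_missing_threshold])
    if len(dropped_runs) == len(runs):
        raise ValueError("sample-quality rule removed every run")
    endo = endo.drop(columns=dropped_runs)
    out = PeptideQuantMatrix(
        endogenous=endo,
        standard=pq.standard.reindex(index=endo.index, columns=endo.columns),
        shifts=pq.shifts.drop(index=dropped_runs),
        flags={k: v.reindex(index=endo.index, columns=endo.columns)
               for k, v in pq.flags.items()},
    )
    return out, dropped_peptides, dropped_runs


def best_peptide_rollup(
    pq: PeptideQuantMatrix,
    peptide_protein: pd.Series,
    *,
    cvs: pd.Series | None = None,
    run_patient: pd.Series | None = None,
    groups: pd.Series | None = None,
    rule: str = "lowest_cv",
) -> tuple[ProteinMatrix, dict[str, str], list[str]]:
    """One representative peptide per protein.

    Under ``lowest_cv`` the peptide with the smallest technical CV wins,
    tie-broken by fewer missing values, higher mean abundance, then peptide
    id; without CVs (single-injection designs) the same tie-break chain
    applies directly.  Returns the protein matrix (columns collapsed to
    patients when ``run_patient`` is given), the chosen peptide per protein,
    and proteins excluded for lack of a surviving peptide.
    """
    endo = pq.endogenous
    excluded = [
        p for p in peptide_protein.unique()
        if not any(pep in endo.index for pep in
                   peptide_protein.index[peptide_protein == p])
    ]
    chosen: dict[str, str] = {}
    for prot in peptide_protein.unique():
        peps = [pep for pep in peptide_protein.index[peptide_protein == prot]
                if pep in endo.index]
        if not peps:
            continue

        def rank(pep: str):
            cv = np.inf
            if rule == "lowest_cv" and cvs is not None and pep in cvs.index \
                    and np.isfinite(cvs[pep]):
                cv = float(cvs[pep])
            row = endo.loc[pep]
            return (cv, int(row.isna().sum()), -float(row.mean(skipna=True)), pep)

        chosen[prot] = min(peps, key=rank)
    values = endo.loc[[chosen[p] for p in chosen]]
    values.index = pd.Index(list(chosen), name="protein")
    flags = {
        k: v.loc[[chosen[p] for p in chosen]].set_axis(list(chosen), axis=0)
        for k, v in pq.flags.items()
    }
    if run_patient is not None:
        # collapse technical replicate runs to one column per patient
        pat = values.columns.map(run_patient)
        values = values.T.groupby(pat).median().T
        flags = {k: v.T.groupby(pat).any().T for k, v in flags.items()}
    pm = ProteinMatrix(
        values=values,
        groups=groups.reindex(values.columns) if groups is not None else None,
        flags=flags,
    )
    return pm, chosen, excluded


def impute_min(matrix: ProteinMatrix) -> ProteinMatrix:
    """Fill missing values with each protein's minimum observed log2 value."""
    values = matrix.values
    fully_missing = values.isna().all(axis=1)
    if fully_missing.any():
        raise ValueError(
            f"proteins with no observed value: {list(values.index[fully_missing])[:5]}"
        )
    mins = values.min(axis=1, skipna=True)
    imputed_mask = values.isna()
    out = matrix.copy()
    out.values = values.T.fillna(mins).T
    out.flags = dict(matrix.flags)
    out.flags["imputed"] = imputed_mask
    return out


@dataclass
class QuantifyResult:
    """End-to-end PRM quantification outputs."""

    protein_matrix: ProteinMatrix
    peptide_matrix: PeptideQuantMatrix
    verdicts: dict[tuple[str, str], QcVerdict]
    cvs: pd.Series | None
    chosen_peptides: dict[str, str]
    dropped_peptides: list[str]
    dropped_runs: list[str]
    excluded_proteins: list[str]
    report: dict


def quantify(
    table: pd.DataFrame,
    params: PrmParams | None = None,
    *,
    groups: pd.Series | None = None,
    impute: bool = True,
) -> QuantifyResult:
    """Full PRM pipeline: QC -> sum -> LOD -> normalize -> drop -> rollup -> impute."""
    params = params or PrmParams()
    verdicts = qc_transitions(table, params)
    areas = sum_peptide_area(table, verdicts)
    bg = estimate_background(areas, params)
    areas = replace_below_lod(areas, bg)
    run_patient = (
        areas.drop_duplicates("run_id").set_index("run_id")["patient_id"]
    )
    replicated = run_patient.groupby(run_patient).size().max() > 1
    std_full = (
        table[table["channel"] == STANDARD]
        .groupby(["run_id", "peptide"], as_index=False)["area"]
        .sum()
    )
    pq = normalize_by_standards(areas, reference=std_full)
    cvs = (
        replicate_cv(table, verdicts, pq.shifts, run_patient)
        if replicated
        else None
    )
    pq, dropped_peptides, dropped_runs = drop_failed(pq, verdicts, params)
    peptide_protein = (
        table.drop_duplicates("peptide").set_index("peptide")["protein"]
    )
    pm, chosen, excluded = best_peptide_rollup(
        pq,
        peptide_protein,
        cvs=cvs,
        run_patient=run_patient if replicated else None,
        groups=None,
        rule=params.best_peptide_rule,
    )
    if not replicated:
        # runs are samples: relabel columns with patient ids
        cols = pm.values.columns.map(run_patient)
        pm.values.columns = cols
        pm.flags = {k: v.set_axis(cols, axis=1) for k, v in pm.flags.items()}
    if groups is not None:
        pm = ProteinMatrix(values=pm.values,
                           groups=groups.reindex(pm.values.columns),
                           flags=pm.flags)
    if impute:
        pm = impute_min(pm)
    n_pass = sum(v.passed for v in verdicts.values())
    report = {
        "n_transitions": int(len(table)),
        "n_run_peptides": len(verdicts),
        "n_run_peptides_passed": int(n_pass),
        "n_peptides_dropped": len(dropped_peptides),
        "dropped_peptides": dropped_peptides,
        "n_runs_dropped": len(dropped_runs),
        "dropped_runs": dropped_runs,
        "n_proteins": int(pm.values.shape[0]),
        "n_samples": int(pm.values.shape[1]),
        "excluded_proteins": excluded,
        "median_cv_percent": None if cvs is None else float(cvs.median()),
        "params": params.model_dump(),
    }
    return QuantifyResult(
        protein_matrix=pm,
        peptide_matrix=pq,
        verdicts=verdicts,
        cvs=cvs,
        chosen_peptides=chosen,
        dropped_peptides=dropped_peptides,
        dropped_runs=dropped_runs,
        excluded_proteins=excluded,
        report=report,
    )
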