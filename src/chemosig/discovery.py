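"""Discovery-phase quantitative analysis.

Top-three peptide summarization, equalised-median normalization, per-group
presence filtering, differential testing with multiple-testing adjustment,
and candidate selection by the three auxiliary criteria:

(a) present in at least ``min_present`` patients of one group and completely
    absent in a comparison group;
(b) completely present or completely absent in the chemoresistant group;
(c) supplied explicitly from the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clinical import CHEMORESISTANT
from .matrix import ProteinMatrix

REASON_DIFFERENTIAL = "differential"
REASON_A = "criterion_a"
REASON_B = "criterion_b"
REASON_LITERATURE = "literature"


def top3_summarize(
    peptide_table: pd.DataFrame, groups: pd.Series | None = None
) -> ProteinMatrix:
    """Protein abundance = mean of the three most intense peptides.

    ``peptide_table`` is long-format with columns protein, peptide, sample and
    linear-scale area.  Proteins with fewer than three observed peptides in a
    sample use the mean of those observed; proteins with no observed peptide
    are missing there.  The result is log2-transformed.
    """
    required = {"protein", "peptide", "sample", "area"}
    missing_cols = required - set(peptide_table.columns)
    if missing_cols:
        raise ValueError(f"peptide table missing columns {sorted(missing_cols)}")
    areas = peptide_table["area"].to_numpy(dtype=float)
    if (areas < 0).any():
        raise ValueError("negative peptide areas")
    obs = peptide_table[areas > 0]  # zero-area rows carry no quantification
    top3 = (
        obs.sort_values("area", ascending=False, kind="mergesort")
        .groupby(["protein", "sample"], sort=True)["area"]
        .apply(lambda v: float(v.iloc[:3].mean()))
    )
    values = np.log2(top3).unstack("sample")
    if groups is not None:
        values = values.reindex(columns=groups.index)
    return ProteinMatrix(values=values, groups=groups)


def equalize_median_normalize(matrix: ProteinMatrix) -> ProteinMatrix:
    """Shift each sample so all per-sample medians equal a common constant.

    The target is the median of the pre-normalization column medians, which
    preserves the overall abundance scale and makes the operation idempotent.
    """
    medians = matrix.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"samples with no present values: {bad}")
    target = float(medians.median())
    out = matrix.copy()
    out.values = matrix.values.add(target - medians, axis=1)
    return out


def presence_filter(
    matrix: ProteinMatrix, min_present: int = 4, groups: list[str] | None = None
) -> tuple[ProteinMatrix, list[str]]:
    """Keep proteins with >= ``min_present`` present values in every group.

    Returns the retained submatrix and the list of removed proteins.
    """
    if matrix.groups is None:
        raise ValueError("presence filtering requires group labels")
    use_groups = groups if groups is not None else sorted(matrix.groups.unique())
    present = matrix.present
    keep = pd.Series(True, index=matrix.proteins)
    for g in use_groups:
        cols = matrix.group_columns(g)
        if min_present > len(cols):
            raise ValueError(
                f"min_present={min_present} exceeds size of group {g!r} ({len(cols)})"
            )
        keep &= present[cols].sum(axis=1) >= min_present
    removed = list(matrix.proteins[~keep])
    return matrix.subset(proteins=matrix.proteins[keep]), removed


@dataclass
class DiffTestResult:
    """Per-protein differential statistics for one two-group comparison."""

    comparison: tuple[str, str]
    table: pd.DataFrame  # protein, log2_fc, t, p, q, significant, n_a, n_b
    skipped: list[tuple[str, str]]  # (protein, reason)


def differential_test(
    matrix: ProteinMatrix,
    comparison: tuple[str, str],
    *,
    equal_var: bool = False,
    adjust: str = "fdr_bh",
    alpha: float = 0.05,
) -> DiffTestResult:
    """Two-sided two-sample t test per protein with adjustment across proteins.

    Welch's unequal-variance t is the default; the pooled-variance test is
    available via ``equal_var``.  Adjusted values ("q") use Benjamini-Hochberg
    by default.  Proteins with fewer than two present values in either group
    are skipped with a recorded reason.
    """
    g1, g2 = comparison
    a = matrix.values[matrix.group_columns(g1)]
    b = matrix.values[matrix.group_columns(g2)]
    n_a = a.notna().sum(axis=1)
    n_b = b.notna().sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    skipped = [
        (p, f"fewer than 2 present values in {g1 if n_a[p] < 2 else g2}")
        for p in matrix.proteins[~testable]
    ]
    a_t = a.loc[testable].to_numpy(dtype=float)
    b_t = b.loc[testable].to_numpy(dtype=float)
    if a_t.shape[0]:
        res = stats.ttest_ind(
            a_t, b_t, axis=1, equal_var=equal_var, nan_policy="omit"
        )
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        t = np.empty(0)
        p = np.empty(0)
    fc = np.nanmean(a_t, axis=1) - np.nanmean(b_t, axis=1) if a_t.shape[0] else np.empty(0)
    # zero-variance degeneracies: equal constants -> no evidence; distinct
    # constants -> unbounded evidence
    bad = ~np.isfinite(t)
    t[bad & (fc == 0)] = 0.0
    p[bad & (fc == 0)] = 1.0
    t[bad & (fc != 0)] = np.sign(fc[bad & (fc != 0)]) * np.inf
    p[bad & (fc != 0)] = 0.0
    q = multipletests(p, method=adjust)[1] if len(p) else np.empty(0)
    table = pd.DataFrame(
        {
            "protein": matrix.proteins[testable],
            "log2_fc": fc,
            "t": t,
            "p": p,
            "q": q,
            "significant": q < alpha,
            "n_a": n_a[testable].to_numpy(),
            "n_b": n_b[testable].to_numpy(),
        }
    ).reset_index(drop=True)
    return DiffTestResult(comparison=comparison, table=table, skipped=skipped)


@dataclass
class CandidateSet:
    """Selected biomarker candidates with per-protein selection reasons."""

    proteins: list[str]
    reasons: dict[str, tuple[str, ...]] = field(default_factory=dict)
    warnings: dict[str, str] = field(default_factory=dict)

    def with_reason(self, reason: str) -> list[str]:
        return [p for p in self.proteins if reason in self.reasons[p]]


def select_candidates(
    diff: DiffTestResult | list[DiffTestResult],
    matrix: ProteinMatrix,
    literature: list[str] | None = None,
    *,
    min_present: int = 4,
    q_threshold: float = 0.05,
    resistant_group: str = CHEMORESISTANT,
) -> CandidateSet:
    """Union of significant proteins, criteria (a)/(b) and literature picks.

    A protein satisfying several criteria keeps every tag.  Literature ids
    absent from the quantified panel are retained with a warning flag, since
    externally motivated targets may not appear in the discovery data at all.
    """
    diffs = diff if isinstance(diff, list) else [diff]
    literature = literature or []
    reasons: dict[str, set[str]] = {}

    def tag(protein: str, reason: str) -> None:
        reasons.setdefault(protein, set()).add(reason)

    for d in diffs:
        for prot in d.table.loc[d.table["q"] < q_threshold, "protein"]:
            tag(prot, REASON_DIFFERENTIAL)

    if matrix.groups is None:
        raise ValueError("candidate selection requires group labels")
    present = matrix.present
    group_names = sorted(matrix.groups.unique())
    counts = {g: present[matrix.group_columns(g)].sum(axis=1) for g in group_names}
    sizes = {g: len(matrix.group_columns(g)) for g in group_names}

    for prot in matrix.proteins:
        # (a): >= min_present in one group, completely absent in another
        for g1 in group_names:
            if counts[g1][prot] < min_present:
                continue
            if any(counts[g2][prot] == 0 for g2 in group_names if g2 != g1):
                tag(prot, REASON_A)
                break
        # (b): all-or-none in the chemoresistant group
        if resistant_group in counts:
            c = counts[resistant_group][prot]
            if c == 0 or c == sizes[resistant_group]:
                tag(prot, REASON_B)

    warnings: dict[str, str] = {}
    panel = set(matrix.proteins)
    for prot in literature:
        tag(prot, REASON_LITERATURE)
        if prot not in panel:
            warnings[prot] = "literature candidate not in quantified panel"

    proteins = sorted(reasons)
    return CandidateSet(
        proteins=proteins,
        reasons={p: tuple(sorted(reasons[p])) for p in proteins},
        warnings=warnings,
    )
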