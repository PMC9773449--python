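"""Resampled AUC-forward logistic signature selection.

The predictive analysis repeatedly splits the cohort into a training and a
validation part in an 8:10 ratio, greedily builds a logistic classifier on
the training part — starting from the single protein with the highest
training AUC and adding the best remaining protein only while the training
AUC improves by more than ``delta_auc`` — evaluates the final combination on
the validation part, and after ``n_repeats`` such rounds takes the most
frequently selected protein combination as the consensus signature.  The
consensus is refitted on the whole cohort and summarized by ROC, alone and
combined with clinical covariates (age, menopausal status, log CA125,
primary treatment).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import roc
from .clinical import CHEMORESISTANT, CHEMOSENSITIVE
from .logistic import (
    RIDGE_FALLBACK,
    LogisticModel,
    batch_newton,
    fit_logistic,
)


class SelectionConfig(BaseModel):
    """Resampling and forward-selection settings."""

    n_repeats: int = Field(500, ge=1)
    delta_auc: float = Field(0.02, gt=0.0, lt=1.0)
    split_ratio: tuple[int, int] = (8, 10)  # (training, validation)
    max_features: int | None = None
    seed: int
    stratified: bool = True

    @model_validator(mode="after")
    def _ratio(self) -> "SelectionConfig":
        a, b = self.split_ratio
        if a <= 0 or b <= 0:
            raise ValueError("split ratio parts must be positive")
        return self

    @property
    def train_fraction(self) -> float:
        a, b = self.split_ratio
        return a / (a + b)


def _auc_fast(scores: np.ndarray, y: np.ndarray, n1: int, n0: int) -> float:
    # ordinal ranks: logistic scores on continuous features are tie-free
    order = np.argsort(scores, kind="stable")
    r = np.empty(len(scores))
    r[order] = np.arange(1.0, len(scores) + 1.0)
    return (r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _apportion(counts: np.ndarray, total: int, frac: float) -> np.ndarray:
    """Per-class training counts by largest remainder, matching the overall
    round(n * frac) total; each class keeps at least one sample per part."""
    quota = counts * frac
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    for k in order[:short]:
        base[k] += 1
    return np.clip(base, 1, counts - 1)


def _split_indices(
    y: np.ndarray, frac: float, rng: np.random.Generator, stratified: bool
) -> tuple[np.ndarray, np.ndarray]:
    n = len(y)
    n_train = int(np.rint(n * frac))
    n_train = min(max(n_train, 1), n - 1)
    if stratified:
        classes, inv = np.unique(y, return_inverse=True)
        counts = np.bincount(inv)
        per_class = _apportion(counts, n_train, frac)
        train_parts, val_parts = [], []
        for c in range(len(classes)):
            idx = rng.permutation(np.nonzero(inv == c)[0])
            train_parts.append(idx[: per_class[c]])
            val_parts.append(idx[per_class[c]:])
        train = np.sort(np.concatenate(train_parts))
        val = np.sort(np.concatenate(val_parts))
    else:
        idx = rng.permutation(n)
        train, val = np.sort(idx[:n_train]), np.sort(idx[n_train:])
        for part in (train, val):
            if len(np.unique(y[part])) < 2:
                raise ValueError(
                    "unstratified split produced a single-class part; "
                    "use stratified splitting"
                )
    return train, val


def split_cohort(
    labels: pd.Series, config: SelectionConfig, rng: np.random.Generator
) -> tuple[list, list]:
    """Split sample ids into training and validation parts.

    Sizes follow the configured ratio with the training part rounded to the
    nearest integer of n * train_fraction and the remainder going to
    validation; stratified splits preserve class proportions per part.
    """
    y = labels.to_numpy()
    if min(np.bincount(pd.factorize(y)[0])) < 2:
        raise ValueError("need >= 2 samples per class")
    train, val = _split_indices(y, config.train_fraction, rng, config.stratified)
    ids = labels.index.to_numpy()
    return list(ids[train]), list(ids[val])


@dataclass
class SelectionPath:
    """Greedy forward-selection result on one training set."""

    features: tuple[str, ...]  # in order of addition
    train_aucs: tuple[float, ...]  # training AUC after each accepted step


def _candidate_aucs(
    Z: np.ndarray, y: np.ndarray, current: list[int], cands: list[int]
) -> np.ndarray:
    """Training AUC of the refitted model for every candidate addition.

    One batched Newton pass over all candidate designs; candidates whose
    unpenalized fit has no finite maximizer are refit with the small ridge
    fallback.  Irrecoverable fits yield NaN.
    """
    n = Z.shape[0]
    k = len(current)
    C = len(cands)
    Xs = np.empty((C, n, k + 2))
    Xs[:, :, 0] = 1.0
    if k:
        Xs[:, :, 1 : k + 1] = Z[:, current]
    Xs[:, :, k + 1] = Z[:, cands].T
    betas, conv = batch_newton(Xs, y, 0.0)
    if not conv.all():
        bad = np.nonzero(~conv)[0]
        betas_r, conv_r = batch_newton(Xs[bad], y, RIDGE_FALLBACK, max_iter=40)
        betas[bad] = betas_r
        conv[bad] = conv_r
    scores = np.einsum("cnp,cp->cn", Xs, betas)
    ybool = y.astype(bool)
    n1 = int(ybool.sum())
    n0 = n - n1
    order = np.argsort(scores, axis=1, kind="stable")
    ranks = np.empty_like(scores)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(1.0, n + 1.0), (C, n)), axis=1
    )
    aucs = (ranks[:, ybool].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    aucs[~conv] = np.nan
    return aucs


def _forward_select_std(
    Z: np.ndarray,
    y: np.ndarray,
    names: list[str],
    delta_auc: float,
    max_features: int | None,
) -> SelectionPath:
    """Forward selection on an already-standardized design (hot path)."""
    p = Z.shape[1]
    order = sorted(range(p), key=lambda j: names[j])  # ties -> smallest name
    current: list[int] = []
    aucs: list[float] = []
    incumbent = -np.inf
    while True:
        if max_features is not None and len(current) >= max_features:
            break
        cands = [j for j in order if j not in current]
        if not cands:
            break
        cand_aucs = _candidate_aucs(Z, y, current, cands)
        if np.isnan(cand_aucs).all():
            break
        best = int(np.nanargmax(cand_aucs))  # first index wins ties -> smallest name
        best_auc = float(cand_aucs[best])
        if current and best_auc - incumbent <= delta_auc:
            break
        current.append(cands[best])
        aucs.append(best_auc)
        incumbent = best_auc
    return SelectionPath(
        features=tuple(names[j] for j in current), train_aucs=tuple(aucs)
    )


def forward_select(
    features: pd.DataFrame, labels: pd.Series, config: SelectionConfig
) -> SelectionPath:
    """AUC-gain greedy forward selection of a protein combination.

    Step 0 picks the single feature with the highest training AUC of its
    logistic score; each later step adds the best remaining feature only if
    the refitted combination's training AUC exceeds the incumbent by more
    than ``delta_auc``.  A single-feature result is valid.
    """
    if features.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    X = features.to_numpy(dtype=float)
    y = labels.reindex(features.index).to_numpy().astype(bool).astype(float)
    sd = X.std(axis=0)
    usable = sd > 0
    Z = np.zeros_like(X)
    Z[:, usable] = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    names = list(features.columns)
    if not usable.all():
        # constant features can never be selected; keep them out of the race
        Z = Z[:, usable]
        names = [nm for nm, u in zip(names, usable) if u]
    return _forward_select_std(Z, y, names, config.delta_auc, config.max_features)


@dataclass
class RepeatResult:
    """One resampling round: split, selected combination, validation AUC."""

    index: int
    train_ids: tuple
    val_ids: tuple
    combination: tuple[str, ...]
    train_aucs: tuple[float, ...]
    val_auc: float
    failed: bool = False
    note: str = ""


def run_repeats(
    features: pd.DataFrame, labels: pd.Series, config: SelectionConfig
) -> list[RepeatResult]:
    """Repeat split -> forward-select -> validate, ``n_repeats`` times.

    Per-repeat randomness is spawned deterministically from the master seed,
    so the full result list is reproducible bit for bit.  Per-repeat failures
    are recorded as flagged results, never raised.
    """
    X = features.to_numpy(dtype=float)
    y = labels.reindex(features.index).to_numpy().astype(bool)
    ids = features.index.to_numpy()
    names = list(features.columns)
    children = np.random.SeedSequence(config.seed).spawn(config.n_repeats)
    results: list[RepeatResult] = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            tr, va = _split_indices(y, config.train_fraction, rng, config.stratified)
            Xtr, ytr = X[tr], y[tr]
            sd = Xtr.std(axis=0)
            usable = sd > 0
            mu = Xtr.mean(axis=0)
            sd_safe = np.where(usable, sd, 1.0)
            Ztr = (Xtr - mu) / sd_safe
            use_names = [nm for nm, u in zip(names, usable) if u]
            path = _forward_select_std(
                Ztr[:, usable], ytr.astype(float), use_names,
                config.delta_auc, config.max_features,
            )
            Zva = (X[va] - mu) / sd_safe
            n1 = int(y[va].sum())
            n0 = len(va) - n1
            # refit coefficients on training, apply to validation
            beta_scores = _validation_scores(
                Ztr[:, usable], ytr.astype(float),
                [use_names.index(f) for f in path.features],
                Zva[:, usable],
            )
            if beta_scores is None:
                raise RuntimeError("validation fit failed")
            val_auc = _auc_fast(beta_scores, y[va], n1, n0)
            results.append(
                RepeatResult(
                    index=r,
                    train_ids=tuple(ids[tr]),
                    val_ids=tuple(ids[va]),
                    combination=path.features,
                    train_aucs=path.train_aucs,
                    val_auc=float(val_auc),
                )
            )
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            results.append(
                RepeatResult(
                    index=r, train_ids=(), val_ids=(), combination=(),
                    train_aucs=(), val_auc=float("nan"), failed=True,
                    note=str(exc),
                )
            )
    return results


def _validation_scores(Ztr, ytr, cols, Zva):
    from .logistic import _newton  # local import keeps the hot path together

    X1 = np.column_stack([np.ones(len(ytr)), Ztr[:, cols]])
    beta, conv = _newton(X1, ytr, 0.0, max_iter=25, tol=1e-8)
    if not conv:
        beta, conv = _newton(X1, ytr, 1e-4, max_iter=40, tol=1e-8)
        if not conv:
            return None
    return np.column_stack([np.ones(Zva.shape[0]), Zva[:, cols]]) @ beta


@dataclass
class ConsensusModel:
    """Most frequent combination across repeats, refit on the whole cohort."""

    features: tuple[str, ...]
    frequency: int
    n_repeats: int
    frequency_table: pd.DataFrame  # combination, count
    model: LogisticModel
    roc_summary: roc.RocSummary


def tally_combinations(repeats: list[RepeatResult]) -> pd.DataFrame:
    """Count selected combinations as unordered sets, most frequent first."""
    counter: Counter = Counter(
        frozenset(r.combination) for r in repeats if not r.failed and r.combination
    )
    rows = sorted(
        counter.items(), key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0])))
    )
    return pd.DataFrame(
        {
            "combination": ["+".join(sorted(k)) for k, _ in rows],
            "n_proteins": [len(k) for k, _ in rows],
            "count": [c for _, c in rows],
        }
    )


def consensus(
    repeats: list[RepeatResult],
    features: pd.DataFrame,
    labels: pd.Series,
    level: float = 0.95,
) -> ConsensusModel:
    """Pick the most frequent combination and evaluate it on the whole cohort.

    Ties break toward the smaller combination, then lexicographically.  The
    winner is refit by maximum likelihood on all samples and summarized with
    ROC, AUC confidence interval and the Youden-optimal operating point.
    """
    ok = [r for r in repeats if not r.failed and r.combination]
    if not ok:
        raise ValueError("no successful repeats to form a consensus")
    table = tally_combinations(repeats)
    winner = tuple(table.iloc[0]["combination"].split("+"))
    y = labels.reindex(features.index).to_numpy().astype(bool)
    model = fit_logistic(
        features[list(winner)].to_numpy(dtype=float), y, feature_names=winner
    )
    summary = roc.summarize(model.scores, y, level)
    return ConsensusModel(
        features=winner,
        frequency=int(table.iloc[0]["count"]),
        n_repeats=len(repeats),
        frequency_table=table,
        model=model,
        roc_summary=summary,
    )


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

CLINICAL_COVARIATES = ("age", "postmenopausal", "log_ca125", "neoadjuvant")


def encode_clinical(clinical: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Numeric design from clinical records.

    Encodings: age in years; menopausal status post=1; natural-log serum
    CA125 (spanning orders of magnitude untransformed); neoadjuvant
    treatment=1.  Samples missing any covariate are excluded and returned.
    """
    design = pd.DataFrame(index=clinical.index)
    design["age"] = pd.to_numeric(clinical["age"], errors="coerce")
    design["postmenopausal"] = clinical["menopausal_status"].map(
        {"post": 1.0, "pre": 0.0}
    )
    ca125 = pd.to_numeric(clinical["ca125"], errors="coerce")
    design["log_ca125"] = np.log(ca125.where(ca125 > 0))
    design["neoadjuvant"] = clinical["treatment"].map(
        {"neoadjuvant": 1.0, "surgery": 0.0}
    )
    complete = design.notna().all(axis=1)
    excluded = list(design.index[~complete])
    return design[complete], excluded


@dataclass
class ClinicalEvaluation:
    """Whole-cohort ROC for proteins alone, clinical alone, and combined."""

    proteins: roc.RocSummary
    clinical: roc.RocSummary
    combined: roc.RocSummary
    p_proteins_vs_combined: float
    n_used: int
    excluded: list


def evaluate_with_clinical(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    labels: pd.Series,
    level: float = 0.95,
) -> ClinicalEvaluation:
    """Fit and compare proteins-only, clinical-only and combined models.

    All three logistic models are fit on the samples with complete clinical
    covariates so the paired ROC comparison is well defined.
    """
    design, excluded = encode_clinical(clinical)
    common = features.index.intersection(design.index)
    if len(common) < 4:
        raise ValueError("too few samples with complete covariates")
    Xp = features.loc[common]
    Xc = design.loc[common]
    y = labels.reindex(common).to_numpy().astype(bool)
    m_prot = fit_logistic(Xp.to_numpy(float), y, tuple(Xp.columns))
    m_clin = fit_logistic(Xc.to_numpy(float), y, tuple(Xc.columns))
    Xb = pd.concat([Xp, Xc], axis=1)
    m_comb = fit_logistic(Xb.to_numpy(float), y, tuple(Xb.columns))
    return ClinicalEvaluation(
        proteins=roc.summarize(m_prot.scores, y, level),
        clinical=roc.summarize(m_clin.scores, y, level),
        combined=roc.summarize(m_comb.scores, y, level),
        p_proteins_vs_combined=roc.compare_roc(m_prot.scores, m_comb.scores, y),
        n_used=int(len(common)),
        excluded=excluded,
    )


def partial_sensitivity_subset(
    clinical: pd.DataFrame, window: tuple[float, float] = (6.0, 12.0)
) -> list:
    """Chemoresistant patients plus chemosensitive ones recurring in (lo, hi].

    The "partially chemosensitive" contrast keeps every chemoresistant
    patient and only those chemosensitive patients whose TFIp falls in the
    half-open window (boundary months belong to the partial group).
    """
    lo, hi = window
    group = clinical["group"]
    tfip = pd.to_numeric(clinical["tfip_months"], errors="coerce")
    resistant = group == CHEMORESISTANT
    sensitive = group == CHEMOSENSITIVE
    if sensitive.any() and tfip[sensitive].isna().any():
        raise ValueError("chemosensitive patients with unknown TFIp")
    partial = sensitive & (tfip > lo) & (tfip <= hi)
    if not partial.any():
        raise ValueError(f"no chemosensitive patients with TFIp in ({lo}, {hi}]")
    return list(clinical.index[resistant | partial])
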