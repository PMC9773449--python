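"""ROC curves, AUC with confidence intervals, paired comparison, Youden cutoff.

Orientation is fixed throughout the package: higher score means the positive
(chemoresistant) class.  The AUC is computed as the Mann-Whitney pair
statistic (ties counted one half), confidence intervals and the paired
two-curve test use the asymptotic covariance of placement values, and the
Youden-optimal cutoff scans midpoints between consecutive distinct scores.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y.astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and aligned")
    if not np.isfinite(s).all():
        raise ValueError("non-finite scores")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return s, y


def auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties: 1/2)."""
    s, y = _validate(scores, labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    r = rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _placements(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation placement values whose means both equal the AUC."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    r_all = rankdata(s)
    r_pos = rankdata(s[y])
    r_neg = rankdata(s[~y])
    v10 = (r_all[y] - r_pos) / n0            # positives vs the negative sample
    v01 = (n1 - (r_all[~y] - r_neg)) / n1    # negatives vs the positive sample
    return v10, v01


def auc_ci(
    scores,
    labels,
    level: float = 0.95,
    *,
    method: str = "delong",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
    return_info: bool = False,
):
    """Confidence interval for the AUC, truncated to [0, 1].

    The default is the asymptotic interval from the variance of placement
    values; ``method="bootstrap"`` resamples within class.  When the
    asymptotic variance degenerates (e.g. AUC = 1 at tiny n) the bootstrap is
    used automatically and flagged in the info dict.
    """
    s, y = _validate(scores, labels)
    if min(int(y.sum()), int((~y).sum())) < 2:
        raise ValueError("need >= 2 samples per class for an interval")
    a = auc(s, y)
    used = method
    if method == "delong":
        v10, v01 = _placements(s, y)
        var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
        if var > 0:
            z = stats.norm.ppf(0.5 + level / 2.0)
            half = z * np.sqrt(var)
            low, high = float(max(0.0, a - half)), float(min(1.0, a + half))
        else:
            used = "bootstrap_fallback"
    if used in ("bootstrap", "bootstrap_fallback"):
        rng = rng or np.random.default_rng(0)
        pos, neg = s[y], s[~y]
        draws = np.empty(n_boot)
        for b in range(n_boot):
            bs = np.concatenate(
                [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
            )
            by = np.concatenate(
                [np.ones(len(pos), dtype=bool), np.zeros(len(neg), dtype=bool)]
            )
            draws[b] = auc(bs, by)
        alpha = (1.0 - level) / 2.0
        low, high = float(np.quantile(draws, alpha)), float(np.quantile(draws, 1 - alpha))
        low, high = max(0.0, min(low, a)), min(1.0, max(high, a))
    if return_info:
        return (low, high), {"method": used, "auc": a, "level": level}
    return (low, high)


def compare_roc(scores_a, scores_b, labels) -> float:
    """Two-sided paired test of equal AUCs for two scores on the same samples.

    Uses the covariance of the two curves' placement values; returns the
    p value.  Identical score vectors give p = 1.
    """
    sa, y = _validate(scores_a, labels)
    sb, yb = _validate(scores_b, labels)
    if not np.array_equal(y, yb):
        raise ValueError("paired comparison requires identical labels")
    if len(sa) != len(sb):
        raise ValueError("paired comparison requires aligned score vectors")
    delta = auc(sa, y) - auc(sb, y)
    va10, va01 = _placements(sa, y)
    vb10, vb01 = _placements(sb, y)
    n1, n0 = len(va10), len(va01)
    s10 = np.cov(va10, vb10, ddof=1)
    s01 = np.cov(va01, vb01, ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    if var <= 0:
        return 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def _threshold_grid(s: np.ndarray) -> np.ndarray:
    u = np.unique(s)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC points (threshold, sensitivity, specificity).

    A sample is called positive when its score exceeds the threshold; the
    grid is the midpoints between consecutive distinct scores plus +-inf
    sentinels, so the step curve's trapezoidal area equals the pair
    statistic exactly.
    """
    s, y = _validate(scores, labels)
    thr = _threshold_grid(s)
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    sens = 1.0 - np.searchsorted(pos, thr, side="right") / len(pos)
    spec = np.searchsorted(neg, thr, side="right") / len(neg)
    return pd.DataFrame({"threshold": thr, "sensitivity": sens, "specificity": spec})


def youden_optimal(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are resolved toward higher specificity (the larger threshold).
    Returns (threshold, sensitivity, specificity) at the optimum.
    """
    pts = roc_points(scores, labels)
    j = pts["sensitivity"] + pts["specificity"] - 1.0
    best = j.max()
    idx = j.index[np.isclose(j, best)].max()  # largest threshold among ties
    row = pts.loc[idx]
    return float(row["threshold"]), float(row["sensitivity"]), float(row["specificity"])


@dataclass
class RocSummary:
    """Whole-curve summary: points, AUC with CI, Youden-optimal operating point."""

    auc: float
    ci_low: float
    ci_high: float
    level: float
    youden_threshold: float
    sensitivity_at_youden: float
    specificity_at_youden: float
    n_positive: int
    n_negative: int
    points: pd.DataFrame

    def to_dict(self) -> dict:
        d = asdict(self)
        d["points"] = self.points.to_dict(orient="list")
        return d


def summarize(scores, labels, level: float = 0.95) -> RocSummary:
    s, y = _validate(scores, labels)
    (low, high) = auc_ci(s, y, level)
    thr, sens, spec = youden_optimal(s, y)
    return RocSummary(
        auc=auc(s, y),
        ci_low=low,
        ci_high=high,
        level=level,
        youden_threshold=thr,
        sensitivity_at_youden=sens,
        specificity_at_youden=spec,
        n_positive=int(y.sum()),
        n_negative=int((~y).sum()),
        points=roc_points(s, y),
    )
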