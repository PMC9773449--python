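"""Reproducible simulation studies over the pipeline.

Each study is a seeded, self-contained experiment returning plain numbers:
calibration of the differential tests and AUC confidence intervals,
analytic recovery of planted effects through the PRM quantification chain,
exactness of internal-standard normalization, stability of the resampled
signature selection, and its behaviour under label permutation.  The
analysis drivers, the test suite and the acceptance script all call these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import prm, roc, selection, synth
from .clinical import CHEMORESISTANT, cohort_frame
from .discovery import differential_test
from .matrix import ProteinMatrix

TRIO = ("PROT01", "PROT02", "PROT03")


def planted_features(
    seed: int,
    n_resistant: int = 25,
    n_sensitive: int = 63,
    n_features: int = 29,
    n_planted: int = 3,
    effect: float = 1.5,
    sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Protein panel with the first ``n_planted`` features shifted by
    ``effect`` (log2, in units of the residual sd) in the resistant class."""
    rng = np.random.default_rng(seed)
    n = n_resistant + n_sensitive
    y = np.array([True] * n_resistant + [False] * n_sensitive)
    X = rng.normal(0.0, sd, (n, n_features))
    X[:, :n_planted] += effect * y[:, None]
    ids = pd.Index([f"P{i:03d}" for i in range(n)], name="sample")
    names = [f"PROT{j + 1:02d}" for j in range(n_features)]
    return pd.DataFrame(X, index=ids, columns=names), pd.Series(y, index=ids)


def planted_auc_study(
    delta: float, seed: int, n_per_group: int = 500
) -> dict:
    """Whole-cohort AUC of one planted protein vs the binormal closed form.

    A two-group cohort of ``n_per_group`` per class is simulated with a
    single signal protein at log2 effect ``delta`` (residual sd 1), run
    biases on, dropout and interference off; the full PRM quantification
    chain (QC, summing, normalization, rollup) is run and the protein's
    whole-cohort AUC compared with Phi(delta / sqrt(2)).
    """
    records = synth.generate_cohort(
        synth.CohortSpec(
            n_resistant=n_per_group, n_sensitive=n_per_group, seed=seed
        )
    )
    spec = synth.PrmSimSpec(
        n_proteins=2,
        peptides_per_protein=1,
        fragments_per_peptide=3,
        signal_proteins=("PROT01",),
        effect_size=delta,
        residual_sd=1.0,
        missing_rate=0.0,
        interference_rate=0.0,
        seed=seed + 1,
    )
    table = synth.generate_prm_dataset(records, spec)
    groups = cohort_frame(records)["group"]
    result = prm.quantify(
        table, prm.PrmParams(background_quantile=0.0), groups=groups
    )
    y = (groups == CHEMORESISTANT).to_numpy()
    a = roc.auc(result.protein_matrix.values.loc["PROT01", groups.index], y)
    expected = float(stats.norm.cdf(delta / np.sqrt(2.0)))
    return {
        "auc": a,
        "expected": expected,
        "abs_err": abs(a - expected),
        "n": 2 * n_per_group,
    }


def _null_matrix(rng, n_proteins: int, n_per_group: int) -> ProteinMatrix:
    cols = [f"a{i}" for i in range(n_per_group)] + [
        f"b{i}" for i in range(n_per_group)
    ]
    values = pd.DataFrame(
        rng.normal(20.0, 1.0, (n_proteins, 2 * n_per_group)),
        index=[f"p{i}" for i in range(n_proteins)],
        columns=cols,
    )
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=cols)
    return ProteinMatrix(values=values, groups=groups)


def type_i_error_study(
    seed: int, n_proteins: int = 10_000, n_per_group: int = 7
) -> dict:
    """Size and p-value uniformity of the per-protein Welch test under the null."""
    rng = np.random.default_rng(seed)
    matrix = _null_matrix(rng, n_proteins, n_per_group)
    res = differential_test(matrix, ("A", "B"))
    p = res.table["p"].to_numpy()
    ks = stats.kstest(p, "uniform")
    return {
        "fraction_p_below_0.05": float((p < 0.05).mean()),
        "ks_pvalue": float(ks.pvalue),
        "n": n_proteins,
    }


def fdr_study(
    seed: int,
    n_sims: int = 20,
    n_proteins: int = 2_000,
    frac_effect: float = 0.10,
    effect: float = 2.0,
    n_per_group: int = 7,
) -> dict:
    """Empirical FDR of BH-adjusted discovery with a minority of true effects."""
    rng = np.random.default_rng(seed)
    n_true = int(n_proteins * frac_effect)
    fdps = []
    for _ in range(n_sims):
        matrix = _null_matrix(rng, n_proteins, n_per_group)
        matrix.values.iloc[:n_true, :n_per_group] += effect
        res = differential_test(matrix, ("A", "B"))
        sig = res.table.loc[res.table["q"] < 0.05, "protein"]
        false = sum(int(s[1:]) >= n_true for s in sig)
        fdps.append(false / max(len(sig), 1))
    return {"empirical_fdr": float(np.mean(fdps)), "n": n_sims}


def normalization_study(seed: int) -> dict:
    """Exactness of internal-standard normalization.

    The same dataset is generated with and without per-run biases (identical
    random streams); after the quantification chain, the two protein
    matrices must agree and the standard-channel run medians must be equal.
    """
    records = synth.generate_cohort(
        synth.CohortSpec(n_resistant=10, n_sensitive=20, seed=seed)
    )
    common = dict(
        n_proteins=5,
        peptides_per_protein=1,
        signal_proteins=("PROT01",),
        missing_rate=0.0,
        interference_rate=0.0,
        seed=seed + 1,
    )
    params = prm.PrmParams(background_quantile=0.0)
    biased = prm.quantify(
        synth.generate_prm_dataset(
            records, synth.PrmSimSpec(**common, run_bias_sd=0.5)
        ),
        params,
    )
    unbiased = prm.quantify(
        synth.generate_prm_dataset(
            records, synth.PrmSimSpec(**common, run_bias_sd=0.0)
        ),
        params,
    )
    med = biased.peptide_matrix.standard.median(axis=0)
    diff = (
        (biased.protein_matrix.values - unbiased.protein_matrix.values)
        .abs()
        .max()
        .max()
    )
    return {
        "standard_median_spread": float(med.max() - med.min()),
        "bias_removal_max_abs_diff": float(diff),
        "n": int(biased.protein_matrix.values.size),
    }


def recovery_study(
    seed: int,
    n_master_seeds: int = 20,
    n_repeats: int = 500,
    effect: float = 1.5,
) -> dict:
    """Planted-signature recovery of the resampled forward selection.

    For each master seed a fresh 25/63 cohort of 29 proteins with three
    planted at ``effect`` (in residual-sd units) is drawn; the full
    500-repeat selection runs at default settings and the consensus
    combination is compared with the planted trio.  Also reports the mean
    validation AUC across repeats and how often consensus sets stay inside
    the planted trio (contamination check).
    """
    ss = np.random.SeedSequence(seed).spawn(n_master_seeds)
    hits = 0
    subset_hits = 0
    val_aucs = []
    sizes = []
    for k, child in enumerate(ss):
        data_seed = int(child.generate_state(1)[0] % (2**31))
        X, y = planted_features(data_seed, effect=effect)
        cfg = selection.SelectionConfig(seed=data_seed + 1, n_repeats=n_repeats)
        reps = selection.run_repeats(X, y, cfg)
        cons = selection.consensus(reps, X, y)
        hits += set(cons.features) == set(TRIO)
        subset_hits += set(cons.features) <= set(TRIO)
        val_aucs.append(np.nanmean([r.val_auc for r in reps if not r.failed]))
        sizes.append(len(cons.features))
    return {
        "recovery_rate": hits / n_master_seeds,
        "consensus_within_planted_rate": subset_hits / n_master_seeds,
        "mean_validation_auc": float(np.mean(val_aucs)),
        "mean_consensus_size": float(np.mean(sizes)),
        "n": n_master_seeds,
    }


def permutation_study(
    seed: int,
    n_repeats: int = 500,
    n_permutations: int = 50,
    permutation_repeats: int = 60,
) -> dict:
    """Selection behaviour when labels carry no signal.

    One full ``n_repeats`` run on permuted labels yields the mean validation
    AUC (expected 1/2).  Then ``n_permutations`` independent permutations,
    each with a reduced ``permutation_repeats`` resampling, record the
    consensus model's whole-cohort (in-sample, refit) AUC distribution.
    """
    rng = np.random.default_rng(seed)
    X, y = planted_features(int(rng.integers(2**31)))
    y_perm = pd.Series(
        rng.permutation(y.to_numpy()), index=y.index, name=y.name
    )
    cfg = selection.SelectionConfig(
        seed=int(rng.integers(2**31)), n_repeats=n_repeats
    )
    reps = selection.run_repeats(X, y_perm, cfg)
    mean_val = float(np.nanmean([r.val_auc for r in reps if not r.failed]))

    consensus_aucs = []
    for k in range(n_permutations):
        yk = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        cfg_k = selection.SelectionConfig(
            seed=int(rng.integers(2**31)), n_repeats=permutation_repeats
        )
        reps_k = selection.run_repeats(X, yk, cfg_k)
        cons = selection.consensus(reps_k, X, yk)
        consensus_aucs.append(cons.roc_summary.auc)
    return {
        "mean_validation_auc": mean_val,
        "consensus_insample_auc_mean": float(np.mean(consensus_aucs)),
        "consensus_insample_auc_sd": float(np.std(consensus_aucs)),
        "n": n_repeats,
        "n_permutations": n_permutations,
    }


def ci_coverage_study(
    seed: int,
    n_sims: int = 2_000,
    n_per_group: int = 30,
    true_auc: float = 0.75,
) -> dict:
    """Coverage of the asymptotic AUC interval at a known true AUC.

    Scores are binormal with separation chosen so the population AUC equals
    ``true_auc``; coverage is the fraction of simulated cohorts whose 95%
    interval contains it.
    """
    delta = float(np.sqrt(2.0) * stats.norm.ppf(true_auc))
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n_per_group), np.zeros(n_per_group)].astype(bool)
    covered = 0
    for _ in range(n_sims):
        s = rng.normal(0.0, 1.0, 2 * n_per_group)
        s[:n_per_group] += delta
        low, high = roc.auc_ci(s, y)
        covered += low <= true_auc <= high
    return {"coverage": covered / n_sims, "level": 0.95, "n": n_sims}
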