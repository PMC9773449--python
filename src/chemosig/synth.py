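"""Synthetic cohorts and proteomic datasets.

The generators emulate the statistical structure of an FFPE tumour study of
platinum response in high-grade serous ovarian carcinoma: a small three-group
discovery cohort profiled at the peptide level, and a larger two-group
verification cohort measured by parallel reaction monitoring (PRM) with
endogenous and heavy-isotope internal-standard channels, per-run scale
biases, intensity-dependent missingness, below-LOD censoring, and occasional
interfered transitions.

All abundances are generated log-normally: log2 area = protein baseline +
peptide offset + fragment share + group effect + run bias + residual noise.
Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .clinical import CHEMORESISTANT, CHEMOSENSITIVE, NO_RECURRENCE, ClinicalRecord

# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

# Baseline covariate distributions (chemosensitive group); group differences
# are expressed as shifts in ClinicalEffects.  Values loosely mirror the
# verification-cohort summary table of the study design being emulated.
AGE_BASE_YEARS = 59.0
AGE_SD_YEARS = 8.0
AGE_RANGE = (35.0, 85.0)
LN_CA125_BASE = 6.6   # exp(6.6) ~ 735 U/mL
LN_CA125_SD = 1.1

STAGES = ("IIIA", "IIIB", "IIIC", "IVA", "IVB")
STAGE_P_RESISTANT = (0.00, 0.04, 0.64, 0.12, 0.20)
STAGE_P_SENSITIVE = (0.03, 0.10, 0.71, 0.06, 0.10)
P_ALIVE_SENSITIVE = 0.49


class ClinicalEffects(BaseModel):
    """Per-covariate group differences (chemoresistant vs chemosensitive)."""

    age_shift_years: float = 4.0
    p_postmenopausal: tuple[float, float] = (0.96, 0.71)  # (resistant, sensitive)
    log_ca125_shift: float = 0.5  # natural-log units added in the resistant group
    p_neoadjuvant: tuple[float, float] = (0.72, 0.30)

    @field_validator("p_postmenopausal", "p_neoadjuvant")
    @classmethod
    def _probs(cls, v):
        for p in v:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        return v


class CohortSpec(BaseModel):
    """Cohort sizes, per-group TFIp ranges and covariate effects."""

    n_resistant: int = Field(25, ge=2)
    n_sensitive: int = Field(63, ge=2)
    tfip_resistant_range: tuple[float, float] = (1.0, 5.0)
    tfip_sensitive_range: tuple[float, float] = (6.5, 63.0)
    clinical_effects: ClinicalEffects = ClinicalEffects()
    seed: int

    @model_validator(mode="after")
    def _ranges(self) -> "CohortSpec":
        lo, hi = self.tfip_resistant_range
        if not (0.0 < lo < hi < 6.0):
            raise ValueError(
                f"tfip_resistant_range {self.tfip_resistant_range} must lie inside (0, 6)"
            )
        lo, hi = self.tfip_sensitive_range
        if not (6.0 < lo < hi):
            raise ValueError(
                f"tfip_sensitive_range {self.tfip_sensitive_range} must lie inside (6, inf)"
            )
        return self


def _group_params(spec: CohortSpec) -> dict[str, dict]:
    """Resolved per-group covariate parameters (resistant/sensitive)."""
    eff = spec.clinical_effects
    return {
        CHEMORESISTANT: dict(
            age_mean=AGE_BASE_YEARS + eff.age_shift_years,
            p_post=eff.p_postmenopausal[0],
            ln_ca125_mean=LN_CA125_BASE + eff.log_ca125_shift,
            p_neoadj=eff.p_neoadjuvant[0],
            stage_p=STAGE_P_RESISTANT,
            p_alive=0.0,
            tfip_range=spec.tfip_resistant_range,
        ),
        CHEMOSENSITIVE: dict(
            age_mean=AGE_BASE_YEARS,
            p_post=eff.p_postmenopausal[1],
            ln_ca125_mean=LN_CA125_BASE,
            p_neoadj=eff.p_neoadjuvant[1],
            stage_p=STAGE_P_SENSITIVE,
            p_alive=P_ALIVE_SENSITIVE,
            tfip_range=spec.tfip_sensitive_range,
        ),
    }


def generate_cohort(spec: CohortSpec) -> list[ClinicalRecord]:
    """Draw a two-group verification-style cohort.

    Chemoresistant TFIp is uniform inside its range; chemosensitive TFIp is
    right-skewed (scaled Beta(1, 4)) so that a realistic fraction of patients
    recur within the 6-12 month "partially chemosensitive" window.
    """
    rng = np.random.default_rng(spec.seed)
    params = _group_params(spec)
    records: list[ClinicalRecord] = []
    for prefix, group, n in (
        ("R", CHEMORESISTANT, spec.n_resistant),
        ("S", CHEMOSENSITIVE, spec.n_sensitive),
    ):
        p = params[group]
        lo, hi = p["tfip_range"]
        if group == CHEMORESISTANT:
            tfip = rng.uniform(lo, hi, n)
        else:
            tfip = lo + (hi - lo) * rng.beta(1.0, 4.0, n)
        age = np.clip(rng.normal(p["age_mean"], AGE_SD_YEARS, n), *AGE_RANGE)
        post = rng.random(n) < p["p_post"]
        ca125 = np.exp(rng.normal(p["ln_ca125_mean"], LN_CA125_SD, n))
        neoadj = rng.random(n) < p["p_neoadj"]
        stage = rng.choice(STAGES, size=n, p=p["stage_p"])
        alive = rng.random(n) < p["p_alive"]
        width = len(str(n))
        for i in range(n):
            records.append(
                ClinicalRecord(
                    patient_id=f"{prefix}{i + 1:0{width}d}",
                    age=round(float(age[i]), 1),
                    menopausal_status="post" if post[i] else "pre",
                    stage=str(stage[i]),
                    ca125=round(float(ca125[i]), 1),
                    treatment="neoadjuvant" if neoadj[i] else "surgery",
                    tfip_months=round(float(tfip[i]), 2),
                    status="alive" if alive[i] else "dead",
                )
            )
    return records


# ---------------------------------------------------------------------------
# PRM verification dataset
# ---------------------------------------------------------------------------

TRANSITION_COLUMNS = (
    "run_id",
    "patient_id",
    "protein",
    "peptide",
    "fragment",
    "channel",
    "area",
    "rt",
)


def _protein_names(n: int) -> list[str]:
    return [f"PROT{i + 1:02d}" for i in range(n)]


class PrmSimSpec(BaseModel):
    """Structure and noise model of the simulated PRM panel.

    Defaults mirror the verification assay being emulated: ~29 proteins with
    1-2 peptides each and >=3 product-ion traces per peptide, measured in an
    endogenous and a spiked heavy-standard channel that share each run's
    multiplicative scale bias.
    """

    n_proteins: int = Field(29, ge=1)
    peptides_per_protein: int = Field(2, ge=1, le=2)
    fragments_per_peptide: int = Field(5, ge=3)
    signal_proteins: tuple[str, ...] = ("PROT01", "PROT02", "PROT03")
    effect_size: float = 1.5          # log2 shift in the chemoresistant group
    residual_sd: float = Field(1.0, gt=0.0)  # biological + preparative noise, log2
    run_bias_sd: float = 0.3          # per-run multiplicative bias, log2
    missing_rate: float = Field(0.05, ge=0.0, le=1.0)
    lod: float = Field(3000.0, gt=0.0)  # linear-area detection floor
    interference_rate: float = Field(0.02, ge=0.0, le=1.0)
    replicates: int = Field(1, ge=1)  # technical replicate runs per sample
    tech_sd: float = Field(0.04, ge=0.0)  # run-to-run technical noise, log2
    trace_sd: float = Field(0.02, ge=0.0)  # per-fragment integration noise, log2
    seed: int

    @model_validator(mode="after")
    def _signal_subset(self) -> "PrmSimSpec":
        panel = set(_protein_names(self.n_proteins))
        unknown = [p for p in self.signal_proteins if p not in panel]
        if unknown:
            raise ValueError(f"signal proteins not in panel: {unknown}")
        return self

    @property
    def proteins(self) -> list[str]:
        return _protein_names(self.n_proteins)


def generate_prm_dataset(
    cohort: list[ClinicalRecord], spec: PrmSimSpec
) -> pd.DataFrame:
    """Simulate a long-format transition table for a PRM verification run.

    Each (run, peptide, fragment) yields an endogenous and an internal-standard
    row.  Standard areas share the run bias but never the biological effect;
    signal proteins' endogenous abundances are shifted by ``effect_size`` (log2)
    in the chemoresistant group.  Endogenous fragments are dropped with a
    probability inversely related to their intensity (LOD-style censoring),
    and a random subset of endogenous transitions receives an additive
    interfering area.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rng = np.random.default_rng(spec.seed)

    patients = [r.patient_id for r in cohort]
    resistant = np.array([r.group == CHEMORESISTANT for r in cohort])
    n_pat = len(patients)

    proteins = spec.proteins
    pep_protein: list[str] = []
    peptides: list[str] = []
    for prot in proteins:
        for k in range(spec.peptides_per_protein):
            pep_protein.append(prot)
            peptides.append(f"{prot}.pep{k + 1}")
    n_pep = len(peptides)
    n_frag = spec.fragments_per_peptide
    fragments = [f"y{i + 3}" for i in range(n_frag)]

    # protein baselines and peptide offsets, drawn once per panel
    base = rng.uniform(14.0, 20.0, len(proteins))
    base_by_pep = np.repeat(base, spec.peptides_per_protein)
    pep_offset = rng.normal(0.0, 0.5, n_pep)
    effect = np.array(
        [spec.effect_size if p in spec.signal_proteins else 0.0 for p in pep_protein]
    )
    # fragment relative intensities, fixed per peptide
    shares = rng.uniform(0.2, 1.0, (n_pep, n_frag))
    shares /= shares.sum(axis=1, keepdims=True)
    log2_share = np.log2(shares)
    pep_rt = rng.uniform(10.0, 100.0, n_pep)

    # biology: one latent abundance per (patient, peptide)
    bio = rng.normal(0.0, spec.residual_sd, (n_pat, n_pep))
    endo_pep_patient = (
        base_by_pep[None, :]
        + pep_offset[None, :]
        + effect[None, :] * resistant[:, None]
        + bio
    )
    std_pep = base_by_pep + pep_offset  # fixed spike level per peptide

    n_rep = spec.replicates
    n_runs = n_pat * n_rep
    run_ids = []
    run_patient_idx = np.repeat(np.arange(n_pat), n_rep)
    for i in range(n_pat):
        for j in range(n_rep):
            run_ids.append(patients[i] if n_rep == 1 else f"{patients[i]}-r{j + 1}")
    run_bias = rng.normal(0.0, spec.run_bias_sd, n_runs)

    tech = rng.normal(0.0, spec.tech_sd, (n_runs, n_pep))
    endo_pep_run = endo_pep_patient[run_patient_idx] + run_bias[:, None] + tech
    std_pep_run = (
        std_pep[None, :]
        + run_bias[:, None]
        + rng.normal(0.0, spec.tech_sd, (n_runs, n_pep))
    )

    # fragment-level areas (runs x peptides x fragments), small trace noise
    trace_sd = spec.trace_sd
    endo_log2 = (
        endo_pep_run[:, :, None]
        + log2_share[None, :, :]
        + rng.normal(0.0, trace_sd, (n_runs, n_pep, n_frag))
    )
    std_log2 = (
        std_pep_run[:, :, None]
        + log2_share[None, :, :]
        + rng.normal(0.0, trace_sd, (n_runs, n_pep, n_frag))
    )
    endo_area = np.exp2(endo_log2)
    std_area = np.exp2(std_log2)

    # interference: additive contaminating area on flagged endogenous transitions
    interfered = rng.random((n_runs, n_pep, n_frag)) < spec.interference_rate
    endo_area = endo_area * np.where(
        interfered, 1.0 + rng.uniform(2.0, 8.0, interfered.shape), 1.0
    )

    # intensity-dependent dropout of endogenous fragments
    flat = endo_area.ravel()
    order = flat.argsort().argsort()  # ascending intensity rank
    u = order / max(len(flat) - 1, 1)
    p_miss = np.clip(2.0 * spec.missing_rate * (1.0 - u), 0.0, 1.0)
    dropped = (rng.random(len(flat)) < p_miss).reshape(endo_area.shape)

    rt_endo = pep_rt[None, :, None] + rng.normal(0.0, 0.03, endo_area.shape)
    rt_std = pep_rt[None, :, None] + rng.normal(0.0, 0.03, endo_area.shape)

    keep = ~dropped
    run_idx, pep_idx, frag_idx = np.nonzero(keep)
    all_run, all_pep, all_frag = np.nonzero(np.ones_like(keep, dtype=bool))

    run_arr = np.asarray(run_ids)
    pat_arr = np.asarray(patients)
    pep_arr = np.asarray(peptides)
    prot_arr = np.asarray(pep_protein)
    frag_arr = np.asarray(fragments)

    endo_df = pd.DataFrame(
        {
            "run_id": run_arr[run_idx],
            "patient_id": pat_arr[run_patient_idx[run_idx]],
            "protein": prot_arr[pep_idx],
            "peptide": pep_arr[pep_idx],
            "fragment": frag_arr[frag_idx],
            "channel": "endogenous",
            "area": endo_area[run_idx, pep_idx, frag_idx],
            "rt": rt_endo[run_idx, pep_idx, frag_idx],
        }
    )
    std_df = pd.DataFrame(
        {
            "run_id": run_arr[all_run],
            "patient_id": pat_arr[run_patient_idx[all_run]],
            "protein": prot_arr[all_pep],
            "peptide": pep_arr[all_pep],
            "fragment": frag_arr[all_frag],
            "channel": "standard",
            "area": std_area[all_run, all_pep, all_frag],
            "rt": rt_std[all_run, all_pep, all_frag],
        }
    )
    table = pd.concat([endo_df, std_df], ignore_index=True)
    table["area"] = table["area"].round(6)
    table["rt"] = table["rt"].round(4)
    table = table.sort_values(
        ["run_id", "protein", "peptide", "fragment", "channel"], kind="mergesort"
    ).reset_index(drop=True)
    return table[list(TRANSITION_COLUMNS)]


# ---------------------------------------------------------------------------
# discovery dataset
# ---------------------------------------------------------------------------

DISCOVERY_GROUPS = (CHEMORESISTANT, CHEMOSENSITIVE, NO_RECURRENCE)
_GROUP_PREFIX = {CHEMORESISTANT: "CR", CHEMOSENSITIVE: "CS", NO_RECURRENCE: "NR"}


class DiscoverySimSpec(BaseModel):
    """Three-group discovery cohort at the peptide level."""

    n_per_group: int = Field(7, ge=4)
    n_proteins: int = Field(120, ge=1)
    peptides_per_protein: int = Field(3, ge=1)
    presence_absence_proteins: tuple[str, ...] = ()
    absent_group: str = CHEMORESISTANT
    effect_proteins: tuple[str, ...] = ()
    effect_log2: float = 1.0
    effect_group: str = CHEMORESISTANT
    residual_sd: float = Field(0.6, gt=0.0)
    missing_rate: float = Field(0.05, ge=0.0, le=1.0)
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "DiscoverySimSpec":
        panel = set(_protein_names(self.n_proteins))
        for name, subset in (
            ("presence_absence_proteins", self.presence_absence_proteins),
            ("effect_proteins", self.effect_proteins),
        ):
            unknown = [p for p in subset if p not in panel]
            if unknown:
                raise ValueError(f"{name} not in panel: {unknown}")
        overlap = set(self.presence_absence_proteins) & set(self.effect_proteins)
        if overlap:
            raise ValueError(
                f"presence/absence and effect subsets overlap: {sorted(overlap)}"
            )
        if self.absent_group not in DISCOVERY_GROUPS:
            raise ValueError(f"unknown absent_group {self.absent_group!r}")
        if self.effect_group not in DISCOVERY_GROUPS:
            raise ValueError(f"unknown effect_group {self.effect_group!r}")
        return self

    @property
    def proteins(self) -> list[str]:
        return _protein_names(self.n_proteins)


def generate_discovery_dataset(
    spec: DiscoverySimSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Peptide-level discovery table plus sample -> group labels.

    Presence/absence proteins are fully missing in their designated group and
    guaranteed present in every sample of the other groups; effect proteins
    get a mean log2 shift in the designated group.
    """
    rng = np.random.default_rng(spec.seed)
    samples, labels = [], []
    for g in DISCOVERY_GROUPS:
        for i in range(spec.n_per_group):
            samples.append(f"{_GROUP_PREFIX[g]}{i + 1}")
            labels.append(g)
    groups = pd.Series(labels, index=pd.Index(samples, name="sample"), name="group")
    n_samp = len(samples)
    group_idx = {g: np.array([lab == g for lab in labels]) for g in DISCOVERY_GROUPS}

    proteins = spec.proteins
    n_pep = spec.n_proteins * spec.peptides_per_protein
    pep_protein = np.repeat(proteins, spec.peptides_per_protein)
    peptides = np.array(
        [f"{p}.pep{k + 1}" for p in proteins for k in range(spec.peptides_per_protein)]
    )

    base = rng.uniform(16.0, 24.0, spec.n_proteins)
    base_by_pep = np.repeat(base, spec.peptides_per_protein)
    pep_offset = rng.normal(0.0, 0.5, n_pep)
    effect = np.array(
        [spec.effect_log2 if p in spec.effect_proteins else 0.0 for p in pep_protein]
    )
    log2 = (
        base_by_pep[None, :]
        + pep_offset[None, :]
        + effect[None, :] * group_idx[spec.effect_group][:, None]
        + rng.normal(0.0, spec.residual_sd, (n_samp, n_pep))
    )
    area = np.exp2(log2)

    pa = np.array([p in spec.presence_absence_proteins for p in pep_protein])
    # dropout, intensity-dependent, never applied to presence/absence proteins
    flat = area.ravel()
    u = flat.argsort().argsort() / max(len(flat) - 1, 1)
    p_miss = np.clip(2.0 * spec.missing_rate * (1.0 - u), 0.0, 1.0)
    dropped = (rng.random(len(flat)) < p_miss).reshape(area.shape)
    dropped[:, pa] = False
    dropped[group_idx[spec.absent_group]] |= pa[None, :]

    keep = ~dropped
    s_idx, p_idx = np.nonzero(keep)
    table = pd.DataFrame(
        {
            "protein": pep_protein[p_idx],
            "peptide": peptides[p_idx],
            "sample": np.asarray(samples)[s_idx],
            "area": np.round(area[s_idx, p_idx], 2),
        }
    ).sort_values(["protein", "peptide", "sample"], kind="mergesort").reset_index(
        drop=True
    )
    return table, groups
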