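"""Clinical records for platinum-response cohorts.

Patients with advanced high-grade serous ovarian carcinoma (HGSC) are
classified by their treatment-free interval to platinum (TFIp): recurrence
under 6 months defines chemoresistance, over 6 months chemosensitivity, and
patients who never recurred carry no TFIp.  A TFIp of exactly 6 months is
assigned to neither group and is rejected rather than silently binned.
"""

from __future__ import annotations

from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

CHEMORESISTANT = "chemoresistant"
CHEMOSENSITIVE = "chemosensitive"
NO_RECURRENCE = "chemosensitive_no_recurrence"

#: TFIp cutoff (months) separating chemoresistant from chemosensitive disease.
TFIP_CUTOFF_MONTHS = 6.0


def derive_group(tfip_months: Optional[float]) -> str:
    """Response group implied by the treatment-free interval to platinum."""
    if tfip_months is None:
        return NO_RECURRENCE
    if tfip_months == TFIP_CUTOFF_MONTHS:
        raise ValueError(
            f"TFIp of exactly {TFIP_CUTOFF_MONTHS} months is assigned to "
            "neither response group; refusing to guess"
        )
    return CHEMORESISTANT if tfip_months < TFIP_CUTOFF_MONTHS else CHEMOSENSITIVE


class ClinicalRecord(BaseModel):
    """One patient's covariates and derived platinum-response group.

    ``ca125`` (serum, U/mL) may be missing; such records stay in the
    proteomic analysis but are excluded from clinical-covariate models.
    """

    patient_id: str
    age: float
    menopausal_status: Literal["pre", "post"]
    stage: str
    ca125: Optional[float] = None
    treatment: Literal["surgery", "neoadjuvant"]
    tfip_months: Optional[float] = None
    status: Literal["alive", "dead"]
    group: str = ""

    @field_validator("age")
    @classmethod
    def _age_plausible(cls, v: float) -> float:
        if not 18 <= v <= 110:
            raise ValueError(f"implausible age {v}")
        return v

    @field_validator("ca125")
    @classmethod
    def _ca125_positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError(f"CA125 must be positive, got {v}")
        return v

    @field_validator("tfip_months")
    @classmethod
    def _tfip_positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError(f"TFIp must be positive, got {v}")
        return v

    @model_validator(mode="after")
    def _derive_group(self) -> "ClinicalRecord":
        expected = derive_group(self.tfip_months)
        if self.group and self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with TFIp {self.tfip_months}"
            )
        object.__setattr__(self, "group", expected)
        return self


COHORT_COLUMNS = (
    "patient_id",
    "age",
    "menopausal_status",
    "stage",
    "ca125",
    "treatment",
    "tfip_months",
    "status",
)


def cohort_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Tabulate records (one row per patient, indexed by patient id)."""
    rows = [r.model_dump() for r in records]
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS) + ["group"])
    return df.set_index("patient_id")
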