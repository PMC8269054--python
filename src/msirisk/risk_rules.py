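"""Deterministic neuroblastoma treatment-risk classification.

European-style INSS/INRG risk grouping from stage, age at diagnosis, MYCN
amplification status and chromosome-1p status. MYCN amplification forces the
high-risk group at every stage; disseminated (stage 4) disease at or beyond
18 months of age is high risk regardless of MYCN. Where the rule grid
branches on 1p status and that status is not available, the classifier
returns an explicit ``indeterminate`` outcome rather than guessing.

Ages are carried in years (as in patient tables) and compared against rule
thresholds defined in months (18 and 24 months); the conversion factor is
fixed at 12.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

LOW = "low"
INTERMEDIATE = "intermediate"
HIGH = "high"
INDETERMINATE = "indeterminate"

STAGES = ("1", "2", "3", "4", "4s")
MYCN_STATES = ("amplified", "not_amplified", "mosaic")
CHR1P_STATES = ("normal", "deletion_imbalance", "unknown")

MONTHS_PER_YEAR = 12.0
STAGE3_AGE_MONTHS = 24.0
STAGE4_AGE_MONTHS = 18.0


@dataclass
class PatientRecord:
    id: str
    sex: str
    age_years: float
    inss_stage: str
    mycn: str
    chr1p: str = "unknown"

    def __post_init__(self) -> None:
        self.inss_stage = normalize_stage(self.inss_stage)
        if self.age_years < 0:
            raise ValueError("age must be non-negative")
        if self.mycn not in MYCN_STATES:
            raise ValueError(f"mycn must be one of {MYCN_STATES}, got {self.mycn!r}")
        if self.chr1p not in CHR1P_STATES:
            raise ValueError(f"chr1p must be one of {CHR1P_STATES}, got {self.chr1p!r}")


_STAGE_ALIASES = {"4/m": "4", "m": "4", "4s/ms": "4s", "ms": "4s"}


def normalize_stage(stage: str) -> str:
    """Map staging synonyms ('4/M', '4s/MS', 'MS', integer 4) onto {1,2,3,4,4s}."""
    s = str(stage).strip().lower()
    s = _STAGE_ALIASES.get(s, s)
    if s not in STAGES:
        raise ValueError(f"unknown INSS stage {stage!r}")
    return s


def classify(record: PatientRecord) -> str:
    """Assign the treatment risk group for one patient.

    Returns one of ``low``, ``intermediate``, ``high`` or ``indeterminate``
    (the latter when a needed 1p branch is unavailable or the rule grid has
    no row for the input combination).
    """
    mycn = record.mycn
    if mycn == "amplified":
        return HIGH
    if mycn == "mosaic":
        warnings.warn(
            f"patient {record.id}: mosaic MYCN treated as not amplified",
            stacklevel=2,
        )
    months = record.age_years * MONTHS_PER_YEAR
    chr1p = record.chr1p
    stage = record.inss_stage

    if stage == "1":
        return LOW if chr1p == "normal" else INDETERMINATE
    if stage == "2":
        if chr1p == "normal":
            return LOW
        if chr1p == "deletion_imbalance":
            return INTERMEDIATE
        return INDETERMINATE
    if stage == "3":
        if chr1p == "deletion_imbalance":
            return INTERMEDIATE
        if months >= STAGE3_AGE_MONTHS:
            # both 1p branches lead to intermediate at >= 24 months
            return INTERMEDIATE
        return LOW if chr1p == "normal" else INDETERMINATE
    if stage == "4":
        return HIGH if months >= STAGE4_AGE_MONTHS else INTERMEDIATE
    if stage == "4s":
        if months >= STAGE4_AGE_MONTHS:
            return INDETERMINATE  # 4s is defined for infants; no rule row
        return LOW if chr1p == "normal" else INDETERMINATE
    raise AssertionError(f"unhandled stage {stage}")


def classify_table(table: pd.DataFrame, assume_chr1p_normal: bool = False) -> pd.Series:
    """Classify every row of a patient table; returns the label series."""
    labels = []
    for _, row in table.iterrows():
        chr1p = row.get("chr1p", "unknown")
        if pd.isna(chr1p) or chr1p == "":
            chr1p = "unknown"
        if assume_chr1p_normal and chr1p == "unknown":
            chr1p = "normal"
        rec = PatientRecord(
            id=str(row["id"]),
            sex=str(row.get("sex", "")),
            age_years=float(row["age_years"]),
            inss_stage=str(row["inss_stage"]),
            mycn=str(row["mycn"]),
            chr1p=chr1p,
        )
        labels.append(classify(rec))
    return pd.Series(labels, index=table.index, name="predicted_label")


def validate_cohort(table: pd.DataFrame, assume_chr1p_normal: bool = True) -> pd.DataFrame:
    """Compare rule-based labels against the labels printed in a cohort table.

    Returns one row per patient with the predicted label, the recorded label
    and a status: ``match``, ``mismatch`` or ``indeterminate``. 1p status is
    assumed normal where a branch requires it and the table does not carry a
    1p column (the default), since cohort tables often omit it.
    """
    if len(table) == 0:
        return pd.DataFrame(columns=["id", "recorded_label", "predicted_label", "status", "reason"])
    predicted = classify_table(table, assume_chr1p_normal=assume_chr1p_normal)
    rows = []
    for (_, row), pred in zip(table.iterrows(), predicted):
        recorded = str(row.get("label", "") or "")
        if pred == INDETERMINATE:
            status, reason = "indeterminate", "rule grid requires unavailable 1p status"
        elif recorded == "":
            status, reason = "indeterminate", "no recorded label"
        elif pred == recorded:
            status, reason = "match", ""
        else:
            status, reason = "mismatch", f"rules give {pred}, table records {recorded}"
        rows.append(
            {
                "id": row["id"],
                "recorded_label": recorded,
                "predicted_label": pred,
                "status": status,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)
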