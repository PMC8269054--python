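"""Bundled worked-example tables.

Two small curated tables accompany the package so that the matcher and the
risk classifier can be exercised on realistic, fully specified inputs
without any imaging data:

* an 18-row peptide-to-protein assignment example — MALDI-MSI m/z values
  from neuroblastoma tumor-cell-rich regions with their discovery and
  tissue-microarray ROC AUCs, matched LC-MS/MS [Mr+H+] masses, MOWSE scores
  and ion-image correlation coefficients, covering 8 proteins;
* a 15-patient neuroblastoma cohort with sex, age, INSS stage, MYCN status
  and the risk classification assigned at diagnosis.
"""

from __future__ import annotations

import pandas as pd

# columns: msi_mz, auc_whole, auc_tma, lcms_mr_h, score, correlation,
#          protein symbol, protein name
_PEPTIDE_MATCH_ROWS = [
    (868.4930, 0.85, 0.73, 868.46, 48.1, 0.38, "COL1A2", "Collagen type I alpha 2 chain"),
    (1562.7700, 0.91, 0.74, 1562.79, 127.0, 0.64, "COL1A2", "Collagen type I alpha 2 chain"),
    (2026.9100, 0.86, 0.73, 2027.02, 65.8, 0.36, "COL1A2", "Collagen type I alpha 2 chain"),
    (1459.8500, 0.72, 0.66, 1459.86, 40.5, 0.38, "COL6A3", "Collagen type VI alpha 3 chain"),
    (2056.9200, 0.88, 0.63, 2057.04, 59.4, 0.32, "COL6A3", "Collagen type VI alpha 3 chain"),
    (766.4820, 0.08, 0.28, 766.46, 21.7, 0.44, "CRMP1", "Collapsin response mediator protein 1"),
    (922.4990, 0.14, 0.34, 922.51, 22.3, 0.40, "CRMP1", "Collapsin response mediator protein 1"),
    (1833.9900, 0.87, 0.67, 1833.91, 65.1, 0.40, "HSPA5", "Heat shock protein family A (Hsp70) member 5"),
    (2042.2200, 0.85, 0.73, 2042.05, 25.6, 0.32, "HSPA5", "Heat shock protein family A (Hsp70) member 5"),
    (1477.8600, 0.90, 0.75, 1477.79, 28.1, 0.41, "HIST1H2BC", "H2B clustered histone 4"),
    (1743.6800, 0.82, 0.58, 1743.82, 96.2, 0.58, "HIST1H2BC", "H2B clustered histone 4"),
    (1775.7900, 0.90, 0.70, 1775.81, 123.0, 0.55, "HIST1H2BC", "H2B clustered histone 4"),
    (1586.7700, 0.90, 0.74, 1586.77, 89.4, 0.47, "KRT9", "Keratin 9"),
    (2705.2800, 0.86, 0.78, 2705.16, 67.9, 0.44, "KRT9", "Keratin 9"),
    (1267.5000, 0.87, 0.74, 1267.65, 63.9, 0.38, "AHNAK", "AHNAK nucleoprotein"),
    (1832.7900, 0.92, 0.70, 1832.88, 44.7, 0.39, "AHNAK", "AHNAK nucleoprotein"),
    (1706.7800, 0.87, 0.74, 1706.78, 31.2, 0.31, "NID2", "Nidogen 2"),
    (2455.3600, 0.79, 0.72, 2455.17, 34.9, 0.33, "NID2", "Nidogen 2"),
]

# columns: id, sex, age_years, inss_stage, mycn, label, recurrence, death
_COHORT_ROWS = [
    ("1", "F", 0.3, "3", "amplified", "high", False, False),
    ("2", "M", 0.6, "2", "amplified", "high", False, False),
    ("3", "M", 1.0, "3", "amplified", "high", False, True),
    ("4", "M", 1.4, "4", "amplified", "high", False, False),
    ("5", "F", 1.2, "4", "amplified", "high", True, True),
    ("6", "M", 2.8, "4", "amplified", "high", True, True),
    ("7", "M", 7.8, "4", "not_amplified", "high", False, False),
    ("8", "F", 8.0, "4", "amplified", "high", False, False),
    ("9", "M", 1.2, "3", "not_amplified", "high", True, False),
    ("10", "F", 2.4, "1", "not_amplified", "low", False, False),
    ("11", "F", 0.8, "4", "not_amplified", "intermediate", False, False),
    ("12", "M", 0.1, "4s", "not_amplified", "low", False, False),
    ("13", "F", 0.1, "3", "mosaic", "low", False, False),
    ("14", "F", 5.9, "3", "not_amplified", "intermediate", False, False),
    ("15", "M", 1.9, "2", "not_amplified", "low", False, False),
]

#: sample ids used for whole-section analyses, by risk group
WHOLE_SECTION_HIGH_RISK_IDS = ("1", "2", "3", "4", "5")
WHOLE_SECTION_OTHER_RISK_IDS = ("10", "11", "12", "13")

#: sample id 9 carries a footnote: classified high after multiple relapses,
#: not by the diagnostic rule grid.
EXCEPTION_IDS = ("9",)


def example_peptide_matches() -> pd.DataFrame:
    """The 18-row peptide assignment example as a DataFrame."""
    return pd.DataFrame(
        _PEPTIDE_MATCH_ROWS,
        columns=[
            "msi_mz",
            "auc_whole",
            "auc_tma",
            "lcms_mr_h",
            "score",
            "correlation",
            "protein",
            "protein_name",
        ],
    )


def example_id_table() -> pd.DataFrame:
    """The assignment example reshaped as an LC-MS/MS identification table.

    Peptide sequences are not part of the example, so each row gets a
    synthetic placeholder sequence; masses, scores and protein symbols are
    the curated values.
    """
    df = example_peptide_matches()
    return pd.DataFrame(
        {
            "peptide": [f"PEP_{p}_{i}" for i, p in enumerate(df["protein"])],
            "mr_h_calc": df["lcms_mr_h"],
            "score": df["score"],
            "protein": df["protein"],
        }
    )


def example_patient_cohort() -> pd.DataFrame:
    """The 15-patient cohort table, in the patient-CSV column layout."""
    df = pd.DataFrame(
        _COHORT_ROWS,
        columns=["id", "sex", "age_years", "inss_stage", "mycn", "label", "recurrence", "death"],
    )
    df["chr1p"] = "unknown"
    return df[["id", "sex", "age_years", "inss_stage", "mycn", "chr1p", "label", "recurrence", "death"]]
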