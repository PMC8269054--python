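"""Assignment of imaging m/z intervals to LC-MS/MS peptide identifications.

An MSI interval is matched to an identified peptide when the absolute
difference between the imaging m/z and the calculated singly protonated
peptide mass [Mr+H+] is below a search mass window (default 0.3 Da, strict)
and the identification carries a MOWSE score above a threshold (default 13).
Per (interval, protein) only the smallest-deviation row is kept, ties broken
by the higher score.

A protein assignment is accepted only when at least two of its peptides are
detected as MSI intervals and their ion images co-vary spatially: each
member peptide is scored by its maximum pairwise Pearson correlation with
the other member intervals, and members below the correlation threshold
(default 0.30) are dropped before the multiplicity rule is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import ROIAnnotation
    from .preprocess import PeakMatrix

DEFAULT_MASS_WINDOW = 0.3
DEFAULT_SCORE_MIN = 13.0
DEFAULT_CORR_MIN = 0.30
DEFAULT_MIN_PEPTIDES = 2


@dataclass
class PeptideMatch:
    msi_mz: float
    lcms_mr_h: float
    deviation: float
    mowse_score: float
    peptide: str
    protein: str
    correlation_coefficient: float = float("nan")

    def __post_init__(self) -> None:
        if self.deviation < 0:
            raise ValueError("deviation must be non-negative")


@dataclass
class ProteinAssignment:
    protein: str
    members: list[PeptideMatch] = field(default_factory=list)
    accepted: bool = False

    @property
    def msi_mzs(self) -> list[float]:
        return [m.msi_mz for m in self.members]


def match_masses(
    intervals: Sequence[float],
    id_table: pd.DataFrame,
    mass_window: float = DEFAULT_MASS_WINDOW,
    score_min: float = DEFAULT_SCORE_MIN,
) -> list[PeptideMatch]:
    """Match MSI interval centers against an identification table.

    ``intervals`` is a sequence of m/z centers in Da. Returns one match per
    (interval, protein) pair within the window; intervals without any match
    are simply absent from the output.
    """
    if mass_window <= 0:
        raise ValueError("mass_window must be positive")
    if len(id_table) == 0:
        return []
    masses = id_table["mr_h_calc"].to_numpy(dtype=float)
    scores = id_table["score"].to_numpy(dtype=float)
    matches: list[PeptideMatch] = []
    for center in intervals:
        dev = np.abs(center - masses)
        ok = (dev < mass_window) & (scores > score_min)
        if not ok.any():
            continue
        sub = id_table.loc[ok].copy()
        sub["deviation"] = dev[ok]
        # per protein: smallest deviation, ties broken by highest score
        sub = sub.sort_values(["deviation", "score"], ascending=[True, False])
        best = sub.groupby("protein", sort=False).head(1)
        for _, row in best.iterrows():
            matches.append(
                PeptideMatch(
                    msi_mz=float(center),
                    lcms_mr_h=float(row["mr_h_calc"]),
                    deviation=float(row["deviation"]),
                    mowse_score=float(row["score"]),
                    peptide=str(row["peptide"]),
                    protein=str(row["protein"]),
                )
            )
    return matches


def spatial_correlation(
    pm: "PeakMatrix",
    interval_a: int,
    interval_b: int,
    roi: "ROIAnnotation | str | None" = None,
) -> float:
    """Pearson correlation of two intervals' ion images over ROI pixels.

    Pixels are pooled across samples. Zero variance in either interval makes
    the coefficient undefined; it is reported as 0 with a warning.
    """
    mask = pm.roi_mask(roi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 ROI pixels for a correlation")
    a = pm.matrix[mask, interval_a]
    b = pm.matrix[mask, interval_b]
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn(
            f"zero variance in interval pair ({interval_a}, {interval_b}); "
            "correlation undefined, reported as 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _member_correlations_from_matrix(
    members: list[PeptideMatch],
    pm: "PeakMatrix",
    roi: "ROIAnnotation | str | None",
) -> list[float]:
    idx = [pm.interval_index(m.msi_mz) for m in members]
    out = []
    for i, ii in enumerate(idx):
        rs = [
            spatial_correlation(pm, ii, jj, roi)
            for j, jj in enumerate(idx)
            if j != i and jj != ii
        ]
        out.append(max(rs) if rs else float("nan"))
    return out


def assign_proteins(
    matches: Iterable[PeptideMatch],
    pm: "PeakMatrix | None" = None,
    roi: "ROIAnnotation | str | None" = None,
    correlations: Mapping[float, float] | None = None,
    corr_min: float = DEFAULT_CORR_MIN,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
) -> list[ProteinAssignment]:
    """Group peptide matches by protein and apply the acceptance rules.

    Member correlation coefficients are either computed from a peak matrix
    (``pm``/``roi``, max pairwise ion-image correlation among the protein's
    member intervals) or supplied precomputed as a mapping
    ``msi_mz -> coefficient``. A protein is accepted when at least
    ``min_peptides`` members with coefficient >= ``corr_min`` remain.
    """
    if pm is None and correlations is None:
        raise ValueError("need either a peak matrix or precomputed correlations")
    by_protein: dict[str, list[PeptideMatch]] = {}
    for m in matches:
        by_protein.setdefault(m.protein, []).append(m)
    assignments = []
    for protein in sorted(by_protein):
        members = by_protein[protein]
        if correlations is not None:
            coeffs = [float(correlations.get(m.msi_mz, float("nan"))) for m in members]
        elif len(members) >= 2:
            coeffs = _member_correlations_from_matrix(members, pm, roi)
        else:
            coeffs = [float("nan")]
        for m, c in zip(members, coeffs):
            m.correlation_coefficient = c
        surviving = [m for m in members if m.correlation_coefficient >= corr_min]
        assignments.append(
            ProteinAssignment(
                protein=protein,
                members=surviving if len(surviving) >= min_peptides else members,
                accepted=len(surviving) >= min_peptides,
            )
        )
    return assignments


REPORT_COLUMNS = [
    "msi_mz",
    "auc_whole",
    "auc_tma",
    "p_value",
    "lcms_mr_h",
    "score",
    "deviation",
    "correlation_coefficient",
    "protein",
    "protein_name",
]


def report_table(
    assignments: Iterable[ProteinAssignment],
    candidates: pd.DataFrame | None = None,
    protein_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Flatten accepted assignments into the standard report layout.

    One row per member m/z value with deviations and AUCs rounded to two
    decimals; per-candidate AUC/p columns are joined from ``candidates``
    (indexed or keyed by interval m/z) when provided.
    """
    cand = None
    if candidates is not None and len(candidates):
        cand = candidates.set_index("mz") if "mz" in candidates.columns else candidates
    rows = []
    for a in assignments:
        if not a.accepted:
            continue
        for m in a.members:
            auc_w = auc_t = p = float("nan")
            if cand is not None and m.msi_mz in cand.index:
                crow = cand.loc[m.msi_mz]
                auc_w = float(crow.get("auc", float("nan")))
                auc_t = float(crow.get("auc_tma", float("nan")))
                p = float(crow.get("p_value", float("nan")))
            rows.append(
                {
                    "msi_mz": m.msi_mz,
                    "auc_whole": round(auc_w, 2) if np.isfinite(auc_w) else auc_w,
                    "auc_tma": round(auc_t, 2) if np.isfinite(auc_t) else auc_t,
                    "p_value": p,
                    "lcms_mr_h": m.lcms_mr_h,
                    "score": m.mowse_score,
                    "deviation": round(m.deviation, 2),
                    "correlation_coefficient": round(m.correlation_coefficient, 2),
                    "protein": m.protein,
                    "protein_name": (protein_names or {}).get(m.protein, ""),
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
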