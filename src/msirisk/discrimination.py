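"""Supervised per-peak screening between risk groups and PCA of candidates.

Each aligned m/z interval is scored by the area under the ROC curve for
separating high-risk (HR, positive class) from non-high-risk (nHR) pixel
intensities; AUC is computed as the Mann-Whitney U statistic normalized by
the number of pixel pairs, ties counted 0.5, so AUC > 0.5 means higher
intensity in HR. Intervals passing an AUC pre-filter are tested with the
two-sided Wilcoxon rank-sum test (exact null distribution for small
tie-free samples, otherwise normal approximation with tie correction —
the same policy as R's wilcox.test). Candidates additionally require an ion-image correlation ratio
when one is supplied. The statistical unit is the pixel, not the patient;
group balance is restored by subsampling an equal number of spectra per
group before scoring. No multiple-testing correction is applied: the screen
uses a fixed p < 0.001 cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import PeakMatrix

DEFAULT_AUC_LO = 0.3
DEFAULT_AUC_HI = 0.7
DEFAULT_PCA_AUC_LO = 0.2
DEFAULT_PCA_AUC_HI = 0.8
DEFAULT_P_MAX = 0.001
DEFAULT_CORR_MIN = 0.30
DEFAULT_COMPONENTS = 5


@dataclass
class CandidatePeak:
    mz: float
    auc: float
    p_value: float
    correlation_ratio: float = float("nan")
    passes_screen: bool = False
    passes_pca_screen: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.auc <= 1):
            raise ValueError("auc must lie in [0, 1]")
        if np.isfinite(self.p_value) and not (0 <= self.p_value <= 1):
            raise ValueError("p_value must lie in [0, 1]")


def balanced_subsample(
    pm: PeakMatrix,
    n_per_group: int,
    seed: int = 0,
    groups: tuple[str, str] = ("HR", "nHR"),
    replace: bool = False,
) -> PeakMatrix:
    """Random equal-size subsample of spectra (rows) per group."""
    rng = np.random.default_rng(seed)
    keep = []
    for g in groups:
        idx = np.nonzero((pm.pixel_table["group"] == g).to_numpy())[0]
        if len(idx) == 0:
            raise ValueError(f"group {g!r} has no pixels")
        if n_per_group > len(idx) and not replace:
            raise ValueError(
                f"group {g!r} has {len(idx)} pixels < n_per_group={n_per_group}; "
                "enable replace to sample with replacement"
            )
        keep.append(rng.choice(idx, size=n_per_group, replace=replace))
    rows = np.concatenate(keep)  # duplicates preserved when sampling with replacement
    return PeakMatrix(
        pm.intervals.copy(),
        pm.matrix[rows],
        pm.pixel_table.iloc[rows].reset_index(drop=True),
    )


def roc_auc(values_pos: np.ndarray, values_neg: np.ndarray) -> float:
    """AUC = U / (n_pos * n_neg), ties counted half; positive class first."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _rank_sum_p(pos: np.ndarray, neg: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Small tie-free samples (both groups <= 50) use the exact null
    distribution of the rank-sum statistic; otherwise the normal
    approximation with tie correction. All-equal inputs give p = 1.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if np.all(pos == pos[0]) and np.all(neg == pos[0]):
        return 1.0
    no_ties = len(np.unique(np.concatenate([pos, neg]))) == len(pos) + len(neg)
    method = "exact" if (no_ties and len(pos) <= 50 and len(neg) <= 50) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    return float(res.pvalue)


def roc_screen(
    pm: PeakMatrix,
    auc_lo: float = DEFAULT_AUC_LO,
    auc_hi: float = DEFAULT_AUC_HI,
    groups: tuple[str, str] = ("HR", "nHR"),
) -> pd.DataFrame:
    """Per-interval AUC plus Wilcoxon p for intervals passing the AUC filter.

    Intervals with auc_lo <= AUC <= auc_hi are not tested (p = NaN).
    """
    gcol = pm.pixel_table["group"].to_numpy()
    pos_mask, neg_mask = gcol == groups[0], gcol == groups[1]
    if not pos_mask.any() or not neg_mask.any():
        raise ValueError("both groups must be present in the peak matrix")
    rows = []
    for k in range(pm.n_intervals):
        pos, neg = pm.matrix[pos_mask, k], pm.matrix[neg_mask, k]
        auc = roc_auc(pos, neg)
        p = _rank_sum_p(pos, neg) if (auc > auc_hi or auc < auc_lo) else float("nan")
        rows.append({"mz": pm.centers[k], "auc": auc, "p_value": p})
    return pd.DataFrame(rows)


def wilcoxon_screen(
    pm: PeakMatrix,
    auc_lo: float = DEFAULT_AUC_LO,
    auc_hi: float = DEFAULT_AUC_HI,
    groups: tuple[str, str] = ("HR", "nHR"),
) -> np.ndarray:
    """Per-interval p-values (NaN where the AUC pre-filter fails)."""
    return roc_screen(pm, auc_lo=auc_lo, auc_hi=auc_hi, groups=groups)["p_value"].to_numpy()


def screen_candidates(
    pm: PeakMatrix,
    auc_lo: float = DEFAULT_AUC_LO,
    auc_hi: float = DEFAULT_AUC_HI,
    p_max: float = DEFAULT_P_MAX,
    corr_min: float = DEFAULT_CORR_MIN,
    correlations: dict[float, float] | None = None,
    groups: tuple[str, str] = ("HR", "nHR"),
) -> list[CandidatePeak]:
    """Flag candidate marker intervals.

    A candidate passes the screen when its AUC falls outside
    [auc_lo, auc_hi], its rank-sum p is below ``p_max`` and — when
    ion-image correlation ratios are supplied — its ratio is at least
    ``corr_min``. The stricter PCA screen uses AUC > 0.8 or < 0.2.
    Sorted by |AUC - 0.5| descending.
    """
    if not (0 <= auc_lo < auc_hi <= 1) or not (0 < p_max <= 1):
        raise ValueError("invalid screening thresholds")
    table = roc_screen(pm, auc_lo=auc_lo, auc_hi=auc_hi, groups=groups)
    out = []
    for _, row in table.iterrows():
        corr = float("nan") if correlations is None else float(correlations.get(row["mz"], float("nan")))
        sig = np.isfinite(row["p_value"]) and row["p_value"] < p_max
        corr_ok = True if correlations is None else corr >= corr_min
        out.append(
            CandidatePeak(
                mz=float(row["mz"]),
                auc=float(row["auc"]),
                p_value=float(row["p_value"]),
                correlation_ratio=corr,
                passes_screen=bool(sig and corr_ok),
                passes_pca_screen=bool(
                    sig and (row["auc"] > DEFAULT_PCA_AUC_HI or row["auc"] < DEFAULT_PCA_AUC_LO)
                ),
            )
        )
    out.sort(key=lambda c: abs(c.auc - 0.5), reverse=True)
    return out


def candidates_frame(candidates: list[CandidatePeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mz": c.mz,
                "auc": c.auc,
                "p_value": c.p_value,
                "correlation_ratio": c.correlation_ratio,
                "passes_screen": c.passes_screen,
                "passes_pca_screen": c.passes_pca_screen,
            }
            for c in candidates
        ]
    )


@dataclass
class PCAResult:
    """Loadings, per-pixel scores and explained-variance fractions."""

    loadings: np.ndarray  # (n_kept_intervals, n_components)
    scores: np.ndarray  # (n_pixels, n_components)
    explained_variance_ratio: np.ndarray
    kept_centers: np.ndarray
    pixel_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def pca_candidates(
    pm: PeakMatrix,
    n_components: int = DEFAULT_COMPONENTS,
    scaling: str = "level",
) -> PCAResult:
    """PCA of the candidate peak matrix after level scaling.

    Level scaling divides each interval's mean-centered intensities by the
    interval mean, (x - mean) / mean, emphasizing relative changes;
    zero-mean intervals are dropped with a warning. Components come from the
    eigendecomposition of the scaled data's covariance; loadings carry a
    deterministic sign convention (largest-magnitude element positive).
    """
    if pm.n_intervals < 2 or pm.n_pixels < 2:
        raise ValueError("need at least 2 intervals and 2 pixels for PCA")
    X = pm.matrix
    if scaling == "level":
        means = X.mean(axis=0)
        keep = means > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-mean intervals before level scaling",
                stacklevel=2,
            )
        X = (X[:, keep] - means[keep]) / means[keep]
        centers = pm.centers[keep]
    elif scaling == "none":
        X = X - X.mean(axis=0)
        centers = pm.centers
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    if X.shape[1] < n_components:
        warnings.warn(
            f"only {X.shape[1]} intervals; truncating to {X.shape[1]} components",
            stacklevel=2,
        )
        n_components = X.shape[1]
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False)
    eigval, eigvec = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    loadings = eigvec[:, :n_components]
    # sign convention: largest |loading| positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Xc @ loadings
    total = eigval.sum()
    evr = eigval[:n_components] / total if total > 0 else np.zeros(n_components)
    return PCAResult(loadings, scores, evr, centers, pm.pixel_table.copy())


def pc_score_image(pcares: PCAResult, component: int, sample: str) -> np.ndarray:
    """2-D map of one principal-component score; missing pixels NaN."""
    if not 0 <= component < pcares.scores.shape[1]:
        raise IndexError(f"component {component} out of range")
    sub = pcares.pixel_table["sample"] == sample
    if not sub.any():
        raise KeyError(f"sample {sample!r} not in PCA result")
    xs = pcares.pixel_table.loc[sub, "x"].to_numpy()
    ys = pcares.pixel_table.loc[sub, "y"].to_numpy()
    img = np.full((ys.max() + 1, xs.max() + 1), np.nan)
    img[ys, xs] = pcares.scores[sub.to_numpy(), component]
    return img
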