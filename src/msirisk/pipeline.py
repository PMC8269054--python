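"""End-to-end orchestration of the discovery pipeline.

A single config (YAML or :class:`PipelineConfig`) drives the stage
sequence: preprocess -> segment (whole sections, then tumor-rich regions
only) -> ROC/Wilcoxon screen -> PCA -> peptide/protein matching -> report,
plus patient risk classification. One master seed deterministically derives
the per-stage seeds, so a rerun with the same config reproduces every
deterministic output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discrimination, io_formats, preprocess, protein_match, risk_rules, segmentation

log = logging.getLogger("msirisk")


@dataclass
class PipelineConfig:
    imzml_paths: list[str] = field(default_factory=list)
    roi_paths: list[str] = field(default_factory=list)
    id_table_path: str | None = None
    patients_path: str | None = None
    output_dir: str = "msirisk_run"

    interval_width: float = preprocess.DEFAULT_INTERVAL_WIDTH
    snr_threshold: float = preprocess.DEFAULT_SNR
    smooth_sigma: float = preprocess.DEFAULT_SMOOTH_SIGMA
    n_clusters_whole: int = 2
    n_clusters_tumor: int = 3
    distance: str = "correlation"
    n_restarts: int = segmentation.DEFAULT_RESTARTS
    n_per_group: int = 35000
    sample_with_replacement: bool = True
    auc_lo: float = discrimination.DEFAULT_AUC_LO
    auc_hi: float = discrimination.DEFAULT_AUC_HI
    p_max: float = discrimination.DEFAULT_P_MAX
    corr_min: float = discrimination.DEFAULT_CORR_MIN
    n_components: int = discrimination.DEFAULT_COMPONENTS
    mass_window: float = protein_match.DEFAULT_MASS_WINDOW
    score_min: float = protein_match.DEFAULT_SCORE_MIN
    min_peptides: int = protein_match.DEFAULT_MIN_PEPTIDES
    tumor_roi_label: str = "tumor_rich"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        tag = zlib.crc32(stage.encode()) % (2**31)
        return int(np.random.SeedSequence([self.seed, tag]).generate_state(1)[0] % (2**31))


def _load_inputs(config: PipelineConfig):
    if not config.imzml_paths:
        raise ValueError("config lists no imzML inputs")
    datasets, rois = [], []
    for i, p in enumerate(config.imzml_paths):
        d = io_formats.read_imzml(p)
        if config.roi_paths:
            ann = io_formats.read_roi(config.roi_paths[i], d)
            d.group = ann.group
            rois.append(ann)
        datasets.append(d)
    return datasets, (rois or None)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory with every artifact."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    config.to_yaml(out / "config.yaml")
    counts: dict[str, int] = {}
    try:
        datasets, rois = _stage("load", _load_inputs, config)
        counts["input_pixels"] = sum(d.n_pixels for d in datasets)

        normalized = _stage("tic_normalize", lambda: [preprocess.tic_normalize(d) for d in datasets])
        centers = _stage(
            "find_peaks",
            lambda: preprocess.find_peaks(
                normalized, snr_threshold=config.snr_threshold, smooth_sigma=config.smooth_sigma
            ),
        )
        intervals = _stage("align_peaks", lambda: preprocess.align_peaks(centers, config.interval_width))
        counts["aligned_intervals"] = len(intervals)
        pm_whole = _stage("peak_matrix_whole", lambda: preprocess.build_peak_matrix(normalized, intervals, rois))
        pm_whole.to_csv(out / "peak_matrix_whole.csv")
        tumor_mask = pm_whole.roi_mask(config.tumor_roi_label) if rois else np.ones(pm_whole.n_pixels, bool)
        pm_tumor = pm_whole.subset(tumor_mask) if tumor_mask.any() else pm_whole
        counts["tumor_pixels"] = int(tumor_mask.sum())

        seg_whole = _stage(
            "segment_whole",
            lambda: segmentation.bisecting_kmeans(
                pm_whole,
                config.n_clusters_whole,
                distance=config.distance,
                seed=config.stage_seed("segment_whole"),
                n_restarts=config.n_restarts,
            ),
        )
        seg_tumor = _stage(
            "segment_tumor",
            lambda: segmentation.bisecting_kmeans(
                pm_tumor,
                min(config.n_clusters_tumor, pm_tumor.n_pixels),
                distance=config.distance,
                seed=config.stage_seed("segment_tumor"),
                n_restarts=config.n_restarts,
            ),
        )
        for name, seg in (("whole", seg_whole), ("tumor", seg_tumor)):
            df = seg.pixel_table.copy()
            df["cluster"] = seg.labels
            df.to_csv(out / f"segmentation_{name}.csv", index=False)

        pm_roc = _stage(
            "balanced_subsample",
            lambda: discrimination.balanced_subsample(
                pm_tumor,
                min(config.n_per_group, pm_tumor.n_pixels),
                seed=config.stage_seed("roc"),
                replace=config.sample_with_replacement,
            ),
        )
        candidates = _stage(
            "screen",
            lambda: discrimination.screen_candidates(
                pm_roc, auc_lo=config.auc_lo, auc_hi=config.auc_hi, p_max=config.p_max
            ),
        )
        cand_df = discrimination.candidates_frame(candidates)
        cand_df.to_csv(out / "candidates.csv", index=False)
        counts["candidates"] = int(cand_df["passes_screen"].sum())

        pca_mzs = [c.mz for c in candidates if c.passes_pca_screen]
        if len(pca_mzs) >= 2:
            keep = np.isin(pm_tumor.centers, pca_mzs)
            pca_pm = preprocess.PeakMatrix(pm_tumor.intervals[keep], pm_tumor.matrix[:, keep], pm_tumor.pixel_table)
            pca = _stage("pca", lambda: discrimination.pca_candidates(pca_pm, n_components=config.n_components))
            pd.DataFrame(
                {"component": np.arange(len(pca.explained_variance_ratio)) + 1,
                 "explained_variance_ratio": pca.explained_variance_ratio}
            ).to_csv(out / "pca_variance.csv", index=False)
        else:
            log.info("pca: fewer than 2 intervals pass the PCA screen; skipped")

        if config.id_table_path:
            id_table = _stage("read_id_table", lambda: io_formats.read_id_table(config.id_table_path))
            screened = [c.mz for c in candidates if c.passes_screen] or list(pm_tumor.centers)
            matches = _stage(
                "match_masses",
                lambda: protein_match.match_masses(
                    screened, id_table, mass_window=config.mass_window, score_min=config.score_min
                ),
            )
            assignments = _stage(
                "assign_proteins",
                lambda: protein_match.assign_proteins(
                    matches,
                    pm=pm_tumor,
                    roi=config.tumor_roi_label if rois else None,
                    corr_min=config.corr_min,
                    min_peptides=config.min_peptides,
                ),
            )
            report = protein_match.report_table(assignments, cand_df.rename(columns={"mz": "mz"}))
            report.to_csv(out / "protein_report.csv", index=False)
            counts["accepted_proteins"] = sum(a.accepted for a in assignments)

        if config.patients_path:
            patients = _stage("read_patients", lambda: io_formats.read_patient_table(config.patients_path))
            report = risk_rules.validate_cohort(patients)
            report.to_csv(out / "risk_report.csv", index=False)
            counts["patients"] = len(patients)

        (out / "counts.json").write_text(json.dumps(counts, indent=2))
    finally:
        log.removeHandler(fh)
        fh.close()
    return out


def _stage(name: str, fn, *args):
    log.info("stage %s: start", name)
    try:
        result = fn(*args) if args else fn()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log.info("stage %s: done", name)
    return result


def run_tma_validation(
    candidates: pd.DataFrame,
    core_pm: "preprocess.PeakMatrix",
    n_per_group: int = 2500,
    seed: int = 0,
    p_max: float = discrimination.DEFAULT_P_MAX,
    replace: bool = True,
) -> pd.DataFrame:
    """Re-score discovery candidates on tissue-microarray core data.

    For each candidate m/z present in the core peak matrix, the ROC AUC and
    Wilcoxon p are recomputed on a balanced subsample of core spectra and
    merged into the candidate table as ``auc_tma`` / ``p_tma`` columns.
    """
    if len(candidates) == 0:
        raise ValueError("no candidates to validate")
    pm = discrimination.balanced_subsample(core_pm, min(n_per_group, core_pm.n_pixels), seed=seed, replace=replace)
    gcol = pm.pixel_table["group"].to_numpy()
    pos, neg = gcol == "HR", gcol == "nHR"
    out = candidates.copy()
    aucs, ps = [], []
    for mz in out["mz"]:
        try:
            k = pm.interval_index(float(mz))
        except KeyError:
            aucs.append(np.nan)
            ps.append(np.nan)
            continue
        a = discrimination.roc_auc(pm.matrix[pos, k], pm.matrix[neg, k])
        aucs.append(a)
        ps.append(discrimination._rank_sum_p(pm.matrix[pos, k], pm.matrix[neg, k]))
    out["auc_tma"] = aucs
    out["p_tma"] = ps
    out["validated"] = (pd.Series(ps) < p_max).to_numpy() & (
        (pd.Series(aucs) - 0.5) * (out["auc"] - 0.5) > 0
    ).to_numpy()
    return out
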