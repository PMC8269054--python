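"""Synthetic MALDI-MSI data with known ground truth.

The generator emulates a two-group tumor imaging study: each synthetic
sample is a rectangular pixel grid split into a contiguous tumor-cell-rich
region and surrounding stroma (smoothed-random-field blobs, so regions are
contiguous like real tissue). A planted subset of peaks differs in mean
intensity between the high-risk (HR) and non-high-risk (nHR) group inside
the tumor-rich region by a configurable fold change; HR tumors additionally
carry several latent spatial subclones with distinct peak signatures, while
nHR tumors are internally homogeneous. Proteins are represented by >= 2
peptide peaks sharing one spatial intensity template, so their noiseless
ion images are perfectly correlated. Technical variation enters as a
per-pixel multiplicative TIC factor plus additive truncated-Gaussian noise
(floored at zero) — exactly the nuisances TIC normalization and rank-based
screening are meant to absorb.

Spectra are emitted directly as centroided peak lists; the downstream
pipeline operates on aligned intervals, so profile-mode peak shapes are not
simulated. Within each sample's tumor-rich region the protein templates are
rescaled to mean 1, which keeps the planted group fold change exact (in
the noiseless limit) also for template-modulated peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import MSIDataset, ROIAnnotation
from . import risk_rules

TUMOR_LABEL = "tumor_rich"
STROMA_LABEL = "stroma"


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a small two-group imaging study: 4 samples per risk
    group on 28x28 grids, peaks in the tryptic range 800-3200 Da, a 2-fold
    planted effect, three latent subclones in HR tumors versus one in nHR,
    and mild technical variation.
    """

    grid_width: int = 28
    grid_height: int = 28
    n_samples_per_group: int = 4
    mz_range: tuple[float, float] = (800.0, 3200.0)
    n_background_peaks: int = 40
    n_discriminative_peaks: int = 10
    n_proteins: int = 3
    peptides_per_protein: int = 2
    effect_size: float = 2.0
    subclone_count_hr: int = 3
    noise_sd: float = 5.0
    tic_variation: tuple[float, float] | None = (0.6, 1.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range lower bound must be below upper bound")
        for name in (
            "grid_width",
            "grid_height",
            "n_samples_per_group",
            "n_background_peaks",
            "n_discriminative_peaks",
            "n_proteins",
            "peptides_per_protein",
            "subclone_count_hr",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.peptides_per_protein < 2:
            raise ValueError("each protein needs at least 2 peptide peaks")
        if self.n_proteins * self.peptides_per_protein > self.n_discriminative_peaks:
            raise ValueError("protein peptides must fit inside the discriminative peaks")
        if self.n_discriminative_peaks > self.n_background_peaks + self.n_discriminative_peaks:
            raise ValueError("n_discriminative_peaks exceeds total peaks")
        if self.tic_variation is not None:
            lo, hi = self.tic_variation
            if not (0 < lo <= hi):
                raise ValueError("tic_variation must be a positive (low, high) range")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    discriminative_mz: list[tuple[float, str]]  # (m/z, "up"|"down" in HR)
    protein_peptides: dict[str, list[tuple[float, int]]]  # protein -> [(m/z, template id)]
    pixel_labels: dict[str, pd.DataFrame]  # sample -> x, y, compartment, subclone
    background_mz: list[float] = field(default_factory=list)
    subclone_marker_mz: list[float] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)  # sample -> HR|nHR

    def __post_init__(self) -> None:
        for protein, peps in self.protein_peptides.items():
            if len(peps) < 2:
                raise ValueError(f"protein {protein} has fewer than 2 peptide peaks")

    def all_mz(self) -> np.ndarray:
        return np.sort(
            np.array([m for m, _ in self.discriminative_mz] + list(self.background_mz))
        )

    def roi_for(self, sample_id: str) -> ROIAnnotation:
        """Tumor-rich/stroma mask of one sample as a ROI annotation."""
        df = self.pixel_labels[sample_id].copy()
        df = df.rename(columns={"compartment": "roi_label"})
        df["group"] = self.groups[sample_id]
        return ROIAnnotation(df[["x", "y", "roi_label", "group"]], sample_id=sample_id)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    return (f - f.min()) / max(f.max() - f.min(), 1e-12)


def _tumor_mask(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Contiguous-ish tumor blob covering roughly 55% of the grid."""
    f = _smooth_field(rng, shape, sigma=min(shape) / 5)
    mask = f >= np.quantile(f, 0.45)
    if mask.all() or not mask.any():  # degenerate fields on tiny grids
        mask = np.zeros(shape, dtype=bool)
        mask[: shape[0] // 2] = True
    return mask


def _subclone_partition(
    rng: np.random.Generator, mask: np.ndarray, k: int
) -> np.ndarray:
    """Partition tumor pixels into k spatially smooth, non-empty subclones."""
    ids = np.full(mask.shape, -1, dtype=int)
    if k == 1:
        ids[mask] = 0
        return ids
    f = _smooth_field(rng, mask.shape, sigma=min(mask.shape) / 6)
    vals = f[mask]
    qs = np.quantile(vals, np.linspace(0, 1, k + 1))
    sub = np.searchsorted(qs[1:-1], vals, side="right")
    ids[mask] = sub
    return ids


def generate_msi_dataset(config: SynthConfig) -> tuple[list[MSIDataset], GroundTruth]:
    """Generate one synthetic MSI dataset per sample plus the ground truth.

    Deterministic under ``config.seed``; two runs with the same config give
    byte-identical spectra.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.grid_height, config.grid_width
    n_total = config.n_background_peaks + config.n_discriminative_peaks

    # peak masses: sample separated slots, jitter slightly
    lo, hi = config.mz_range
    margin = min(5.0, (hi - lo) * 0.02)
    slots = np.linspace(lo + margin, hi - margin, 3 * n_total)
    masses = np.sort(rng.choice(slots, size=n_total, replace=False))
    gap = (slots[1] - slots[0]) if len(slots) > 1 else 1.0
    masses = masses + rng.uniform(-0.1 * gap, 0.1 * gap, size=n_total)
    masses = np.sort(masses)

    order = rng.permutation(n_total)
    disc_idx = np.sort(order[: config.n_discriminative_peaks])
    back_idx = np.sort(order[config.n_discriminative_peaks :])

    directions = rng.choice(["up", "down"], size=len(disc_idx))
    direction_of_peak = dict(zip(disc_idx, directions))
    base = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=n_total)
    stroma_factor = rng.uniform(0.2, 0.8, size=n_total)

    # proteins take the first peptides_per_protein * n_proteins discriminative peaks
    protein_peptides: dict[str, list[tuple[float, int]]] = {}
    protein_of_peak = {}
    pick = rng.permutation(len(disc_idx))
    cursor = 0
    for p in range(config.n_proteins):
        name = f"SYN{p + 1:02d}"
        members = []
        # peptides of one protein share its abundance direction and stroma
        # attenuation, keeping their whole-image ion images exactly proportional
        first_peak = disc_idx[pick[cursor]]
        protein_dir = direction_of_peak[first_peak]
        protein_stroma = stroma_factor[first_peak]
        for _ in range(config.peptides_per_protein):
            peak = disc_idx[pick[cursor]]
            cursor += 1
            members.append((float(masses[peak]), p))
            protein_of_peak[peak] = p
            direction_of_peak[peak] = protein_dir
            stroma_factor[peak] = protein_stroma
        protein_peptides[name] = members
    directions = np.array([direction_of_peak[i] for i in disc_idx])

    # one spatial template per protein, shared by every sample
    templates = np.stack(
        [0.25 + 0.75 * _smooth_field(rng, (h, w), sigma=min(h, w) / 6) for _ in range(config.n_proteins)]
    )

    # subclone signatures: multiplicative factors on background marker peaks,
    # shared across HR samples so subclones are consistent study-wide
    n_markers = max(4, len(back_idx) // 3)
    marker_idx = np.sort(rng.choice(back_idx, size=min(n_markers, len(back_idx)), replace=False))
    subclone_factors = rng.lognormal(mean=0.0, sigma=0.5, size=(config.subclone_count_hr, len(marker_idx)))

    ys, xs = np.mgrid[0:h, 0:w]
    pixels = np.column_stack([xs.ravel(), ys.ravel()])

    datasets: list[MSIDataset] = []
    pixel_labels: dict[str, pd.DataFrame] = {}
    groups: dict[str, str] = {}
    for group, n_sub in (("HR", config.subclone_count_hr), ("nHR", 1)):
        for s in range(config.n_samples_per_group):
            sample_id = f"{group}{s + 1:02d}"
            mask = _tumor_mask(rng, (h, w))
            sub_ids = _subclone_partition(rng, mask, n_sub)

            inten = np.tile(base, (h * w, 1))  # pixels x peaks
            flat_mask = mask.ravel()
            flat_sub = sub_ids.ravel()

            # compartment contrast
            inten[~flat_mask] *= stroma_factor[None, :]

            # protein templates, normalized to mean 1 inside the tumor region
            for peak, p in protein_of_peak.items():
                t = templates[p].ravel().copy()
                t /= t[flat_mask].mean()
                inten[:, peak] *= t

            # planted group effect inside the tumor-rich region
            if group == "HR":
                for j, peak in enumerate(disc_idx):
                    f = config.effect_size if directions[j] == "up" else 1.0 / config.effect_size
                    inten[flat_mask, peak] *= f
                for c in range(n_sub):
                    sel = flat_mask & (flat_sub == c)
                    if sel.any():
                        inten[np.ix_(sel, marker_idx)] *= subclone_factors[c][None, :]

            if config.tic_variation is not None:
                tic = rng.uniform(*config.tic_variation, size=h * w)
                inten *= tic[:, None]
            if config.noise_sd > 0:
                inten = inten + rng.normal(0.0, config.noise_sd, size=inten.shape)
            inten = np.clip(inten, 0.0, None)

            datasets.append(
                MSIDataset(
                    pixels.copy(),
                    [masses.copy() for _ in range(h * w)],
                    [row.astype(np.float32) for row in inten],
                    sample_id=sample_id,
                    group=group,
                )
            )
            pixel_labels[sample_id] = pd.DataFrame(
                {
                    "x": pixels[:, 0],
                    "y": pixels[:, 1],
                    "compartment": np.where(flat_mask, TUMOR_LABEL, STROMA_LABEL),
                    "subclone": np.where(flat_mask, flat_sub, -1),
                }
            )
            groups[sample_id] = group

    truth = GroundTruth(
        discriminative_mz=[(float(masses[i]), str(d)) for i, d in zip(disc_idx, directions)],
        protein_peptides=protein_peptides,
        pixel_labels=pixel_labels,
        background_mz=[float(masses[i]) for i in back_idx],
        subclone_marker_mz=[float(masses[i]) for i in marker_idx],
        groups=groups,
    )
    return datasets, truth


def generate_id_table(
    truth: GroundTruth,
    decoy_count: int = 0,
    score_range: tuple[float, float] = (20.0, 120.0),
    seed: int = 0,
    mass_jitter: float = 0.03,
    decoy_score_range: tuple[float, float] = (0.0, 13.0),
    mz_range: tuple[float, float] = (800.0, 3200.0),
) -> pd.DataFrame:
    """LC-MS/MS identification table for the planted proteins plus decoys.

    One row per true peptide (mass jittered by up to ``mass_jitter`` Da,
    MOWSE score drawn from ``score_range``) plus ``decoy_count`` rows with
    random masses and synthetic decoy proteins. Decoy scores default to the
    range (0, 13], below the downstream MOWSE acceptance threshold.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for protein, peptides in truth.protein_peptides.items():
        for i, (mz, _tid) in enumerate(peptides):
            rows.append(
                {
                    "peptide": f"PEP_{protein}_{i}",
                    "mr_h_calc": mz + rng.uniform(-mass_jitter, mass_jitter),
                    "score": rng.uniform(*score_range),
                    "protein": protein,
                }
            )
    for d in range(decoy_count):
        rows.append(
            {
                "peptide": f"DECOY_PEP_{d}",
                "mr_h_calc": rng.uniform(*mz_range),
                "score": rng.uniform(*decoy_score_range),
                "protein": f"DECOY{d // 2 + 1:03d}",
            }
        )
    return pd.DataFrame(rows, columns=["peptide", "mr_h_calc", "score", "protein"])


def generate_patient_table(n: int, seed: int = 0) -> pd.DataFrame:
    """Random patient attribute table labeled by the risk rule grid.

    Ages are in years; stages and molecular markers are drawn with
    frequencies resembling a diagnostic neuroblastoma cohort. The label
    column is filled by :func:`msirisk.risk_rules.classify`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "id": [str(i + 1) for i in range(n)],
            "sex": rng.choice(["F", "M"], size=n),
            "age_years": np.round(np.clip(rng.lognormal(np.log(1.5), 0.9, size=n), 0.05, 15.0), 1),
            "inss_stage": rng.choice(["1", "2", "3", "4", "4s"], size=n, p=[0.2, 0.15, 0.25, 0.3, 0.1]),
            "mycn": rng.choice(["amplified", "not_amplified", "mosaic"], size=n, p=[0.25, 0.7, 0.05]),
            "chr1p": rng.choice(["normal", "deletion_imbalance"], size=n, p=[0.75, 0.25]),
        }
    )
    df["label"] = risk_rules.classify_table(df)
    return df
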