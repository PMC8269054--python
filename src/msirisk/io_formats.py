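"""Readers and writers for the formats the pipeline touches.

Imaging data travels as imzML 1.1 (an XML index plus a binary ``.ibd``
companion, continuous or processed mode). Everything else is plain CSV:
region-of-interest masks, LC-MS/MS identification tables in the shape of a
Mascot export, and patient attribute tables.

Internal conventions: pixel coordinates are 0-based integers on a unit grid
(imzML's 1-based indices are shifted on read and restored on write); m/z is
stored as float64, intensities as float32.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_LABELS = ("HR", "nHR", "unknown")

ID_TABLE_COLUMNS = ["peptide", "mr_h_calc", "score", "protein"]
ROI_COLUMNS = ["x", "y", "roi_label", "group"]
PATIENT_COLUMNS = ["id", "sex", "age_years", "inss_stage", "mycn", "chr1p", "label"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class MSIDataset:
    """One imaging run: a pixel grid with one mass spectrum per pixel.

    Parameters
    ----------
    pixels : (n, 2) int array of 0-based (x, y) coordinates, unique per pixel.
    mzs, intensities : per-pixel arrays; m/z strictly increasing, intensity >= 0.
    sample_id : identifier of the tissue section / core.
    group : risk group attribute, one of ``HR``, ``nHR`` or ``unknown``.
    """

    pixels: np.ndarray
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    sample_id: str = "sample"
    group: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise FormatError("pixels must be an (n, 2) coordinate array")
        if len(self.pixels) == 0:
            raise FormatError("dataset has no pixels")
        if len(self.mzs) != len(self.pixels) or len(self.intensities) != len(self.pixels):
            raise FormatError("pixels, mzs and intensities must have equal length")
        if self.group not in GROUP_LABELS:
            raise FormatError(f"group must be one of {GROUP_LABELS}, got {self.group!r}")
        seen = set(map(tuple, self.pixels))
        if len(seen) != len(self.pixels):
            raise FormatError("pixel coordinates are not unique")
        for i, (mz, inten) in enumerate(zip(self.mzs, self.intensities)):
            mz = np.asarray(mz, dtype=np.float64)
            inten = np.asarray(inten, dtype=np.float32)
            if len(mz) != len(inten):
                raise FormatError(f"pixel {i}: mz and intensity lengths differ")
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise FormatError(f"pixel {i}: m/z values not strictly increasing")
            if np.any(inten < 0):
                raise FormatError(f"pixel {i}: negative intensity")
            self.mzs[i] = mz
            self.intensities[i] = inten

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(height, width) of the bounding grid."""
        return int(self.pixels[:, 1].max()) + 1, int(self.pixels[:, 0].max()) + 1

    def tic(self) -> np.ndarray:
        """Total ion count per pixel."""
        return np.array([float(np.sum(i)) for i in self.intensities])


@dataclass
class ROIAnnotation:
    """Per-pixel region labels for one dataset plus its group attribute."""

    table: pd.DataFrame  # columns x, y, roi_label, group
    sample_id: str = "sample"

    def pixels_in(self, roi_label: str) -> np.ndarray:
        sub = self.table[self.table["roi_label"] == roi_label]
        return sub[["x", "y"]].to_numpy(dtype=np.int64)

    @property
    def group(self) -> str:
        groups = self.table["group"].unique()
        return str(groups[0]) if len(groups) == 1 else "unknown"

    def coverage(self, dataset: MSIDataset) -> float:
        annotated = set(map(tuple, self.table[["x", "y"]].to_numpy()))
        return len(annotated) / dataset.n_pixels


def read_imzml(path: str | Path) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Continuous and processed binary modes are auto-detected by the parser.
    Coordinates are shifted from imzML's 1-based convention to 0-based.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FormatError(f"missing binary companion file {ibd}")
    parser = ImzMLParser(str(path))
    pixels, mzs, intens = [], [], []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=np.float64)
        if len(mz) > 1 and not np.all(np.diff(mz) > 0):
            raise FormatError(f"pixel {i}: m/z axis not strictly increasing")
        pixels.append((int(x) - 1, int(y) - 1))
        mzs.append(mz)
        intens.append(np.asarray(inten, dtype=np.float32))
    if not pixels:
        raise FormatError("imzML file contains no spectra")
    return MSIDataset(np.array(pixels), mzs, intens, sample_id=path.stem)


def write_imzml(dataset: MSIDataset, path: str | Path, mode: str = "processed") -> Path:
    """Write a dataset as an imzML/ibd pair readable by :func:`read_imzml`."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    with ImzMLWriter(str(path), mode=mode) as writer:
        for (x, y), mz, inten in zip(dataset.pixels, dataset.mzs, dataset.intensities):
            writer.addSpectrum(mz, np.asarray(inten, dtype=np.float64), (int(x) + 1, int(y) + 1, 1))
    return path


def read_roi(path: str | Path, dataset: MSIDataset) -> ROIAnnotation:
    """Read a ROI mask CSV (columns x, y, roi_label, group) for ``dataset``.

    Every annotated pixel must exist in the dataset; duplicates and unknown
    columns are rejected.
    """
    df = pd.read_csv(path)
    extra = set(df.columns) - set(ROI_COLUMNS)
    missing = set(ROI_COLUMNS) - set(df.columns)
    if extra or missing:
        raise FormatError(
            f"ROI CSV columns must be exactly {ROI_COLUMNS}; "
            f"unexpected={sorted(extra)} missing={sorted(missing)}"
        )
    df = df.astype({"x": np.int64, "y": np.int64})
    dup = df.duplicated(subset=["x", "y"])
    if dup.any():
        rows = df.loc[dup, ["x", "y"]].to_numpy().tolist()
        raise FormatError(f"duplicate annotated pixels: {rows[:10]}")
    known = set(map(tuple, dataset.pixels))
    bad = [t for t in map(tuple, df[["x", "y"]].to_numpy()) if t not in known]
    if bad:
        raise FormatError(f"annotated pixels absent from dataset: {bad[:10]}")
    bad_groups = set(df["group"].unique()) - set(GROUP_LABELS)
    if bad_groups:
        raise FormatError(f"unknown group labels {sorted(bad_groups)}; expected {GROUP_LABELS}")
    return ROIAnnotation(df.reset_index(drop=True), sample_id=dataset.sample_id)


def write_roi(annotation: ROIAnnotation, path: str | Path) -> Path:
    annotation.table[ROI_COLUMNS].to_csv(path, index=False)
    return Path(path)


def read_id_table(path: str | Path) -> pd.DataFrame:
    """Read an LC-MS/MS identification CSV (Mascot-export shape).

    Columns: peptide sequence, calculated [Mr+H+] mass in Da, MOWSE score,
    protein symbol. Trailing-dot scores such as ``127.`` parse as floats.
    Rows with a non-numeric mass are rejected with their row number.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"identification table {path} is empty", stacklevel=2)
        return pd.DataFrame(columns=ID_TABLE_COLUMNS)
    missing = set(ID_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"identification CSV missing columns {sorted(missing)}")
    if len(df) == 0:
        warnings.warn(f"identification table {path} has no rows", stacklevel=2)
        return pd.DataFrame(columns=ID_TABLE_COLUMNS)
    for col in ("mr_h_calc", "score"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(f"non-numeric {col} in rows {list(bad[:10])}")
        df[col] = parsed
    if (df["mr_h_calc"] <= 0).any():
        raise FormatError("mr_h_calc must be positive")
    if df["peptide"].isna().any() or (df["peptide"].str.len() == 0).any():
        raise FormatError("empty peptide sequence")
    return df[ID_TABLE_COLUMNS].reset_index(drop=True)


def write_id_table(table: pd.DataFrame, path: str | Path) -> Path:
    table[ID_TABLE_COLUMNS].to_csv(path, index=False)
    return Path(path)


def read_patient_table(path: str | Path) -> pd.DataFrame:
    """Read a patient attribute CSV; ``chr1p`` and ``label`` are optional."""
    df = pd.read_csv(path, dtype={"id": str, "inss_stage": str})
    required = {"id", "sex", "age_years", "inss_stage", "mycn"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"patient CSV missing columns {sorted(missing)}")
    if "chr1p" not in df.columns:
        df["chr1p"] = "unknown"
    if "label" not in df.columns:
        df["label"] = ""
    df["age_years"] = pd.to_numeric(df["age_years"])
    if (df["age_years"] < 0).any():
        raise FormatError("negative patient age")
    return df[PATIENT_COLUMNS].reset_index(drop=True)


def write_patient_table(table: pd.DataFrame, path: str | Path) -> Path:
    cols = [c for c in PATIENT_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)
    return Path(path)
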