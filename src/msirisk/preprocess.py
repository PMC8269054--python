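"""Spectral preprocessing: TIC normalization, peak finding and alignment.

The pipeline's feature unit is the aligned m/z interval: peaks detected on
the dataset-wide mean spectrum are binned into fixed-width, non-overlapping
half-open windows (default width 0.3 Da), and each pixel contributes the
MAXIMUM intensity it shows inside a window ("maximal interval processing").

Noise reduction is applied only while finding peaks (Gaussian smoothing of
the mean spectrum, sigma in Da); pixel intensities are never smoothed, so
quantitation is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .io_formats import MSIDataset, ROIAnnotation

DEFAULT_INTERVAL_WIDTH = 0.3
DEFAULT_SNR = 3.0
DEFAULT_SMOOTH_SIGMA = 0.05
_GRID_STEP = 0.01  # Da; fine grid for the mean spectrum


@dataclass
class PeakMatrix:
    """Pixels x aligned-interval intensity matrix with pixel annotations.

    ``intervals`` is a (k, 2) array of (center, half_width) in Da, centers
    strictly increasing and windows non-overlapping. ``pixel_table`` carries
    one row per matrix row with columns x, y, sample, roi, group.
    """

    intervals: np.ndarray
    matrix: np.ndarray
    pixel_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.intervals = np.atleast_2d(np.asarray(self.intervals, dtype=float))
        self.matrix = np.asarray(self.matrix, dtype=float)
        centers, hw = self.intervals[:, 0], self.intervals[:, 1]
        if len(centers) > 1:
            if not np.all(np.diff(centers) > 0):
                raise ValueError("interval centers must be strictly increasing")
            if np.any(centers[:-1] + hw[:-1] > centers[1:] - hw[1:]):
                raise ValueError("intervals overlap")
        if np.any(self.matrix < 0):
            raise ValueError("peak matrix must be non-negative")
        if self.matrix.shape != (len(self.pixel_table), len(centers)):
            raise ValueError("matrix shape does not match pixel table / intervals")

    @property
    def centers(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.matrix.shape[1]

    def interval_index(self, mz: float) -> int:
        """Index of the interval whose window contains ``mz``."""
        lo = self.intervals[:, 0] - self.intervals[:, 1]
        hi = self.intervals[:, 0] + self.intervals[:, 1]
        hits = np.nonzero((mz >= lo) & (mz < hi))[0]
        if len(hits) == 0:
            raise KeyError(f"no interval contains m/z {mz}")
        return int(hits[0])

    def roi_mask(self, roi: "ROIAnnotation | str | None" = None) -> np.ndarray:
        """Boolean row mask for a ROI (by label or annotation object)."""
        if roi is None:
            return np.ones(self.n_pixels, dtype=bool)
        if isinstance(roi, str):
            return (self.pixel_table["roi"] == roi).to_numpy()
        keys = set(map(tuple, roi.table[["x", "y"]].to_numpy()))
        in_roi = [
            (row.sample == roi.sample_id) and ((row.x, row.y) in keys)
            for row in self.pixel_table.itertuples()
        ]
        return np.asarray(in_roi, dtype=bool)

    def subset(self, mask: np.ndarray) -> "PeakMatrix":
        return PeakMatrix(
            self.intervals.copy(),
            self.matrix[mask],
            self.pixel_table.loc[mask].reset_index(drop=True),
        )

    def to_csv(self, path) -> None:
        df = self.pixel_table.copy()
        for c, v in zip(self.centers, self.matrix.T):
            df[f"{c:.4f}"] = v
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PeakMatrix":
        df = pd.read_csv(path)
        meta_cols = [c for c in ("x", "y", "sample", "roi", "group") if c in df.columns]
        value_cols = [c for c in df.columns if c not in meta_cols]
        centers = np.array([float(c) for c in value_cols])
        hw = np.full_like(centers, DEFAULT_INTERVAL_WIDTH / 2)
        if len(centers) > 1:
            hw = np.minimum(hw, np.min(np.diff(centers)) / 2)
        intervals = np.column_stack([centers, hw])
        return cls(intervals, df[value_cols].to_numpy(float), df[meta_cols])


def tic_normalize(dataset: MSIDataset) -> MSIDataset:
    """Scale each pixel so its total ion count equals the dataset-mean TIC.

    Zero-TIC pixels are left at zero and flagged in
    ``metadata['zero_tic_pixels']``.
    """
    tics = dataset.tic()
    if np.all(tics == 0):
        raise ValueError("all pixels have zero total ion count")
    target = float(np.mean(tics))
    zero = np.nonzero(tics == 0)[0]
    if len(zero):
        warnings.warn(f"{len(zero)} zero-TIC pixels left unscaled", stacklevel=2)
    scaled = [
        inten * np.float32(target / t) if t > 0 else inten
        for inten, t in zip(dataset.intensities, tics)
    ]
    meta = dict(dataset.metadata)
    meta["zero_tic_pixels"] = zero.tolist()
    meta["tic_target"] = target
    return MSIDataset(
        dataset.pixels.copy(),
        [m.copy() for m in dataset.mzs],
        scaled,
        sample_id=dataset.sample_id,
        group=dataset.group,
        metadata=meta,
    )


def mean_spectrum(
    datasets: MSIDataset | list[MSIDataset], grid_step: float = _GRID_STEP
) -> tuple[np.ndarray, np.ndarray]:
    """Dataset-wide mean spectrum on a fine regular m/z grid.

    Centroided peaks are accumulated into the nearest grid point and the sum
    is divided by the total pixel count across all datasets.
    """
    if isinstance(datasets, MSIDataset):
        datasets = [datasets]
    lo = min(float(d.mzs[i].min()) for d in datasets for i in range(d.n_pixels) if len(d.mzs[i]))
    hi = max(float(d.mzs[i].max()) for d in datasets for i in range(d.n_pixels) if len(d.mzs[i]))
    # pad past the outermost peaks so edge peaks are detectable local maxima
    pad = max(1.0, 100 * grid_step)
    grid = np.arange(lo - pad, hi + pad + grid_step, grid_step)
    acc = np.zeros(len(grid))
    n_pixels = 0
    for d in datasets:
        n_pixels += d.n_pixels
        for mz, inten in zip(d.mzs, d.intensities):
            if len(mz) == 0:
                continue
            idx = np.clip(np.round((mz - grid[0]) / grid_step).astype(int), 0, len(grid) - 1)
            np.add.at(acc, idx, inten.astype(float))
    return grid, acc / max(n_pixels, 1)


def find_peaks(
    datasets: MSIDataset | list[MSIDataset],
    snr_threshold: float = DEFAULT_SNR,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    grid_step: float = _GRID_STEP,
) -> np.ndarray:
    """Detect peak centers on the (optionally smoothed) mean spectrum.

    A grid point is a peak when it is a local maximum exceeding
    ``snr_threshold`` times the noise level, estimated as the scaled median
    absolute deviation of the mean spectrum's detrended residual (residual
    against a 1-Da median filter). Returns sorted m/z centers.
    """
    if not np.isfinite(snr_threshold) and snr_threshold > 0:
        return np.array([])
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    grid, spec = mean_spectrum(datasets, grid_step=grid_step)
    if smooth_sigma and smooth_sigma > 0:
        spec = ndimage.gaussian_filter1d(spec, sigma=smooth_sigma / grid_step)
    win = max(3, int(round(1.0 / grid_step)) | 1)
    trend = ndimage.median_filter(spec, size=win, mode="nearest")
    resid = spec - trend
    mad = np.median(np.abs(resid - np.median(resid)))
    noise = max(1.4826 * float(mad), 1e-9 * max(float(spec.max()), 1.0))
    idx, _ = signal.find_peaks(spec, height=snr_threshold * noise)
    return grid[idx]


def align_peaks(
    centers: np.ndarray,
    interval_width: float = DEFAULT_INTERVAL_WIDTH,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Bin sorted peak centers into non-overlapping fixed-width intervals.

    Centers closer than ``interval_width`` are merged into one interval at
    their intensity-weighted mean; merging is repeated until all adjacent
    interval centers are at least one width apart. Returns a (k, 2) array of
    (center, half_width).
    """
    if interval_width <= 0:
        raise ValueError("interval_width must be positive")
    centers = np.asarray(centers, dtype=float)
    if len(centers) == 0:
        return np.empty((0, 2))
    if np.any(np.diff(centers) < 0):
        raise ValueError("centers must be sorted ascending")
    weights = np.ones_like(centers) if weights is None else np.asarray(weights, dtype=float)
    clusters = [[i] for i in range(len(centers))]

    def cluster_center(idx: list[int]) -> float:
        w = weights[idx]
        if w.sum() <= 0:
            return float(np.mean(centers[idx]))
        return float(np.average(centers[idx], weights=w))

    merged = True
    while merged:
        merged = False
        out: list[list[int]] = []
        for cl in clusters:
            if out and cluster_center(cl) - cluster_center(out[-1]) < interval_width:
                out[-1] = out[-1] + cl
                merged = True
            else:
                out.append(cl)
        clusters = out
    result = np.array([[cluster_center(cl), interval_width / 2] for cl in clusters])
    return result


def build_peak_matrix(
    datasets: MSIDataset | list[MSIDataset],
    intervals: np.ndarray,
    rois: "ROIAnnotation | list[ROIAnnotation] | None" = None,
) -> PeakMatrix:
    """Per-pixel interval maxima over one or more (normalized) datasets.

    Each interval is the half-open window [center - hw, center + hw); the
    value is the maximum pixel intensity inside the window, 0 when the pixel
    has no signal there. When ROI annotations are given, rows are restricted
    to annotated pixels and carry the ROI label and group attribute.
    """
    if isinstance(datasets, MSIDataset):
        datasets = [datasets]
    if isinstance(rois, ROIAnnotation):
        rois = [rois]
    if rois is not None and len(rois) != len(datasets):
        raise ValueError("need one ROI annotation per dataset")
    intervals = np.atleast_2d(np.asarray(intervals, dtype=float))
    lo = intervals[:, 0] - intervals[:, 1]
    hi = intervals[:, 0] + intervals[:, 1]
    if len(lo) > 1 and np.any(hi[:-1] > lo[1:]):
        raise ValueError("intervals overlap")

    rows, meta = [], []
    for si, d in enumerate(datasets):
        roi_lut = None
        group_lut = {}
        if rois is not None:
            ann = rois[si].table
            roi_lut = {(r.x, r.y): r.roi_label for r in ann.itertuples()}
            group_lut = {(r.x, r.y): r.group for r in ann.itertuples()}
        for (x, y), mz, inten in zip(d.pixels, d.mzs, d.intensities):
            key = (int(x), int(y))
            if roi_lut is not None and key not in roi_lut:
                continue
            i0 = np.searchsorted(mz, lo, side="left")
            i1 = np.searchsorted(mz, hi, side="left")
            vals = np.zeros(len(lo))
            for k in range(len(lo)):
                if i1[k] > i0[k]:
                    vals[k] = float(inten[i0[k]:i1[k]].max())
            rows.append(vals)
            meta.append(
                {
                    "x": int(x),
                    "y": int(y),
                    "sample": d.sample_id,
                    "roi": roi_lut[key] if roi_lut is not None else "",
                    "group": group_lut.get(key, d.group),
                }
            )
    if not rows:
        raise ValueError("no pixels selected for the peak matrix")
    return PeakMatrix(intervals, np.array(rows), pd.DataFrame(meta))


def ion_image(pm: PeakMatrix, interval_index: int, sample: str) -> np.ndarray:
    """2-D intensity map of one interval for one sample; missing pixels NaN."""
    if not 0 <= interval_index < pm.n_intervals:
        raise IndexError(f"interval index {interval_index} out of range")
    sub = pm.pixel_table["sample"] == sample
    if not sub.any():
        raise KeyError(f"sample {sample!r} not in peak matrix")
    xs = pm.pixel_table.loc[sub, "x"].to_numpy()
    ys = pm.pixel_table.loc[sub, "y"].to_numpy()
    img = np.full((ys.max() + 1, xs.max() + 1), np.nan)
    img[ys, xs] = pm.matrix[sub.to_numpy(), interval_index]
    return img
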