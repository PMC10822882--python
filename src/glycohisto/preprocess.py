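"""Spectrum preprocessing: TIC normalization, peak picking, feature matrix.

The preprocessing contract follows the common MSI convention: each pixel
spectrum is scaled to a common total ion current (TIC), peaks are picked
once on the dataset *mean* spectrum so all pixels share one feature axis,
and per-pixel features are the integrals of the normalized spectrum over
each peak window.  Low-TIC pixels (matrix, glass, tissue folds) can be
pre-flagged as non-cellular so they are excluded from embedding and ROI
statistics while keeping their place in the image grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .io import MSIDataset

__all__ = [
    "PeakPanel",
    "FeatureMatrix",
    "tic_normalize",
    "bin_to_common_axis",
    "mean_spectrum",
    "pick_peaks",
    "build_feature_matrix",
    "flag_noncellular",
]


@dataclass
class PeakPanel:
    """The picked-peak feature axis: centers, integration windows, ids."""

    ids: list
    center_mz: np.ndarray
    window_low: np.ndarray
    window_high: np.ndarray
    snr_threshold: float = 3.0
    min_rel_intensity: float = 0.001

    def __post_init__(self):
        self.center_mz = np.asarray(self.center_mz, dtype=np.float64)
        self.window_low = np.asarray(self.window_low, dtype=np.float64)
        self.window_high = np.asarray(self.window_high, dtype=np.float64)
        order = np.argsort(self.center_mz)
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("peaks must be sorted by center_mz")
        if np.any(self.window_low > self.center_mz) or np.any(self.window_high < self.center_mz):
            raise ValueError("window must contain its center")
        if len(self.center_mz) > 1 and np.any(
            self.window_high[:-1] > self.window_low[1:] + 1e-12
        ):
            raise ValueError("peak windows overlap")

    def __len__(self):
        return len(self.center_mz)

    def to_csv(self, path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {
                "id": self.ids,
                "center_mz": self.center_mz,
                "window_low": self.window_low,
                "window_high": self.window_high,
            }
        ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "PeakPanel":
        t = pd.read_csv(path)
        return cls(
            ids=[str(i) for i in t["id"]],
            center_mz=t["center_mz"].to_numpy(),
            window_low=t["window_low"].to_numpy(),
            window_high=t["window_high"].to_numpy(),
        )


@dataclass
class FeatureMatrix:
    """Pixels x picked-peak intensities, with per-pixel TIC and cellular flag."""

    coords: np.ndarray
    feature_ids: list
    values: np.ndarray
    tic: np.ndarray
    cellular_mask: np.ndarray
    grid_shape: tuple
    normalization_target: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.tic = np.asarray(self.tic, dtype=np.float64)
        self.cellular_mask = np.asarray(self.cellular_mask, dtype=bool)
        if not (len(self.coords) == len(self.values) == len(self.tic) == len(self.cellular_mask)):
            raise ValueError("inconsistent pixel counts across fields")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def pixel_index_grid(self) -> np.ndarray:
        """(n_rows, n_cols) array mapping grid position -> pixel row, -1 if absent."""
        n_cols, n_rows = self.grid_shape
        idx = np.full((n_rows, n_cols), -1, dtype=np.int64)
        idx[self.coords[:, 1], self.coords[:, 0]] = np.arange(self.n_pixels)
        return idx

    def to_csv(self, path) -> Path:
        path = Path(path)
        meta = pd.DataFrame(
            {
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "tic": self.tic,
                "cellular": self.cellular_mask.astype(int),
            }
        )
        feats = pd.DataFrame(self.values, columns=self.feature_ids)
        pd.concat([meta, feats], axis=1).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path, grid_shape=None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = ["x", "y", "tic", "cellular"]
        fids = [c for c in df.columns if c not in meta]
        coords = df[["x", "y"]].to_numpy()
        if grid_shape is None:
            grid_shape = (int(coords[:, 0].max()) + 1, int(coords[:, 1].max()) + 1)
        return cls(
            coords=coords,
            feature_ids=fids,
            values=df[fids].to_numpy(),
            tic=df["tic"].to_numpy(),
            cellular_mask=df["cellular"].to_numpy().astype(bool),
            grid_shape=grid_shape,
        )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def tic_normalize(ds: MSIDataset, target: float = 1.0):
    """Scale each pixel spectrum so its intensity sum equals ``target``.

    Pixels whose total ion current is zero are left at zero.  Returns the
    normalized dataset and the per-pixel pre-normalization TIC array (the
    TIC is needed later for non-cellular flagging).
    """
    if target <= 0:
        raise ValueError("normalization target must be positive")
    out = ds.copy()
    if ds.is_continuous:
        tic = out.intensities.sum(axis=1)
        scale = np.where(tic > 0, target / np.where(tic > 0, tic, 1.0), 0.0)
        out.intensities = out.intensities * scale[:, None]
    else:
        tic = np.zeros(ds.n_pixels)
        for i, (mz, inten) in enumerate(out.spectra):
            s = float(np.asarray(inten, dtype=np.float64).sum())
            tic[i] = s
            if s > 0:
                out.spectra[i] = (mz, np.asarray(inten, dtype=np.float64) * (target / s))
    return out, tic


# ---------------------------------------------------------------------------
# common axis / mean spectrum
# ---------------------------------------------------------------------------

def bin_to_common_axis(ds: MSIDataset, bin_width: float = 0.1) -> MSIDataset:
    """Rebin processed-mode spectra onto one uniform axis.

    Intensities falling into the same bin are summed; the bin center is
    the reported m/z.  Continuous-mode datasets are returned unchanged.
    """
    if ds.is_continuous:
        return ds
    lo = min(float(m[0]) for m, _ in ds.spectra if len(m))
    hi = max(float(m[-1]) for m, _ in ds.spectra if len(m))
    n_bins = int(np.floor((hi - lo) / bin_width)) + 1
    axis = lo + (np.arange(n_bins) + 0.5) * bin_width
    mat = np.zeros((ds.n_pixels, n_bins), dtype=np.float64)
    for i, (mz, inten) in enumerate(ds.spectra):
        idx = np.clip(((np.asarray(mz) - lo) / bin_width).astype(int), 0, n_bins - 1)
        np.add.at(mat[i], idx, np.asarray(inten, dtype=np.float64))
    return MSIDataset(
        coords=ds.coords.copy(),
        mz_axis=axis,
        intensities=mat,
        mz_range=(min(ds.mz_range[0], axis[0]), max(ds.mz_range[1], axis[-1])),
        pixel_size_um=ds.pixel_size_um,
        grid_shape=ds.grid_shape,
    )


def mean_spectrum(ds: MSIDataset, mask=None, bin_width: float = 0.1):
    """Pointwise mean spectrum over selected pixels.

    ``mask`` is a boolean array over pixels (None = all).  Processed-mode
    data are first binned to a uniform axis at ``bin_width``.
    """
    if not ds.is_continuous:
        ds = bin_to_common_axis(ds, bin_width=bin_width)
    if mask is None:
        mask = np.ones(ds.n_pixels, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty pixel mask")
    return ds.mz_axis.copy(), ds.intensities[mask].astype(np.float64).mean(axis=0)


# ---------------------------------------------------------------------------
# peak picking
# ---------------------------------------------------------------------------

def _noise_mad(intensity: np.ndarray, detrend_window: int = 15) -> float:
    """Robust noise level: 1.4826 x MAD of the median-filter-detrended signal."""
    detrended = intensity - median_filter(intensity, size=detrend_window, mode="nearest")
    return 1.4826 * float(np.median(np.abs(detrended - np.median(detrended))))


def pick_peaks(
    mean_spec,
    snr_threshold: float = 3.0,
    min_rel_intensity: float = 0.001,
    window_halfwidth_da: float = 0.4,
) -> PeakPanel:
    """Pick peaks from a mean spectrum as local maxima above noise.

    A sample is a peak apex if it is a local maximum of the mean spectrum,
    exceeds ``snr_threshold`` times the robust noise estimate and exceeds
    ``min_rel_intensity`` times the base peak.  Each peak gets the window
    ``[apex - hw, apex + hw]``; overlapping windows are truncated at the
    midpoint between adjacent apexes.
    """
    mz, intensity = mean_spec
    mz = np.asarray(mz, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    if len(mz) > 1 and not np.all(np.diff(mz) > 0):
        raise ValueError("m/z axis not strictly increasing")
    if len(mz) < 3:
        return PeakPanel(ids=[], center_mz=[], window_low=[], window_high=[],
                         snr_threshold=snr_threshold, min_rel_intensity=min_rel_intensity)

    noise = _noise_mad(intensity)
    base = float(intensity.max())
    threshold = max(noise * snr_threshold, base * min_rel_intensity)
    apexes, _ = find_peaks(intensity, height=threshold if threshold > 0 else None)
    # constant (flat) spectra have no strict local maxima -> zero peaks
    centers = mz[apexes]
    lo = centers - window_halfwidth_da
    hi = centers + window_halfwidth_da
    for k in range(len(centers) - 1):
        mid = 0.5 * (centers[k] + centers[k + 1])
        if hi[k] > mid:
            hi[k] = mid
        if lo[k + 1] < mid:
            lo[k + 1] = mid
    ids = [f"mz_{c:.4f}" for c in centers]
    return PeakPanel(
        ids=ids,
        center_mz=centers,
        window_low=lo,
        window_high=hi,
        snr_threshold=snr_threshold,
        min_rel_intensity=min_rel_intensity,
    )


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def build_feature_matrix(
    ds_norm: MSIDataset,
    panel: PeakPanel,
    tic=None,
    normalization_target: float = 1.0,
    bin_width: float = 0.1,
) -> FeatureMatrix:
    """Integrate each pixel's normalized spectrum over the panel windows.

    ``tic`` is the per-pixel pre-normalization total ion current returned
    by :func:`tic_normalize`; if omitted, the current spectrum sums are
    used (correct only for unnormalized data).
    """
    if not ds_norm.is_continuous:
        ds_norm = bin_to_common_axis(ds_norm, bin_width=bin_width)
    lo, hi = ds_norm.mz_range
    if len(panel) and (panel.window_low[0] < lo - 1e-9 or panel.window_high[-1] > hi + 1e-9):
        raise ValueError("panel window outside dataset mz_range")
    if tic is None:
        tic = ds_norm.intensities.astype(np.float64).sum(axis=1)
    tic = np.asarray(tic, dtype=np.float64)

    axis = ds_norm.mz_axis
    values = np.zeros((ds_norm.n_pixels, len(panel)), dtype=np.float64)
    inten = ds_norm.intensities.astype(np.float64)
    for j in range(len(panel)):
        a = np.searchsorted(axis, panel.window_low[j] - 1e-12, side="left")
        b = np.searchsorted(axis, panel.window_high[j] + 1e-12, side="right")
        if b > a:
            values[:, j] = inten[:, a:b].sum(axis=1)
    return FeatureMatrix(
        coords=ds_norm.coords,
        feature_ids=list(panel.ids),
        values=values,
        tic=tic,
        cellular_mask=tic > 0,
        grid_shape=ds_norm.grid_shape,
        normalization_target=normalization_target,
    )


def flag_noncellular(
    fm: FeatureMatrix, tic_quantile: float = 0.05, min_abs_tic: float = 0.0
) -> FeatureMatrix:
    """Flag low-TIC pixels as non-cellular.

    The cutoff is ``max(quantile(tic, tic_quantile), min_abs_tic)``;
    pixels strictly below it are flagged (ties are kept cellular).  This
    is a coarse pre-flag; cluster-level white-out in the segmentation
    stage is the definitive background removal.
    """
    if not 0.0 <= tic_quantile <= 1.0:
        raise ValueError("tic_quantile must be in [0, 1]")
    cutoff = max(float(np.quantile(fm.tic, tic_quantile)), float(min_abs_tic))
    cellular = fm.tic >= cutoff
    cellular &= fm.tic > 0  # zero-TIC pixels are never cellular
    return replace(fm, cellular_mask=cellular)
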