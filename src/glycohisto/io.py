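"""Reading and writing MALDI-MSI datasets (imzML) and ROI annotation masks.

The in-memory data model is deliberately simple: an :class:`MSIDataset`
holds the pixel grid and one mass spectrum per pixel, either on a shared
m/z axis (imzML *continuous* mode, stored as a dense pixel x m/z matrix)
or as per-pixel (m/z, intensity) arrays (*processed* mode).  Regions of
interest are boolean pixel masks with a morphology label and a role
(reference morphology vs. query region), mirroring how a pathologist
annotates a section.

Coordinates are 0-based, x increasing rightward and y downward (raster
convention); imzML's 1-based coordinates are converted on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "MSIDataset",
    "ROI",
    "ROISet",
    "MORPHOLOGIES",
    "ROLES",
    "read_imzml",
    "write_imzml",
    "read_roi_masks",
    "write_roi_masks",
]

#: Controlled vocabulary for ROI morphology labels.
MORPHOLOGIES = frozenset(
    {
        "normal",
        "low_grade",
        "high_grade",
        "invasive",
        "suspected_pi",
        "suspected_invasion",
        "other",
    }
)

#: ROI roles: reference morphologies vs. query regions to be annotated.
ROLES = frozenset({"reference", "query"})

DEFAULT_MZ_RANGE = (900.0, 3300.0)
DEFAULT_PIXEL_SIZE_UM = (50.0, 50.0)


@dataclass
class MSIDataset:
    """A mass spectrometry imaging dataset: pixel grid + per-pixel spectra.

    Parameters
    ----------
    coords
        ``(n_pixels, 2)`` integer array of 0-based ``(x, y)`` grid positions.
    mz_axis
        Shared, strictly increasing m/z axis (continuous mode) or ``None``.
    intensities
        ``(n_pixels, n_mz)`` intensity matrix (continuous mode) or ``None``.
    spectra
        Per-pixel ``(mz, intensity)`` array pairs (processed mode) or ``None``.
    mz_range
        ``(mz_min, mz_max)`` acquisition window in Da.
    pixel_size_um
        Pixel footprint ``(width, height)`` in micrometres.
    grid_shape
        ``(n_cols, n_rows)``; inferred from max coordinates when omitted.
    """

    coords: np.ndarray
    mz_axis: Optional[np.ndarray] = None
    intensities: Optional[np.ndarray] = None
    spectra: Optional[list] = None
    mz_range: tuple = DEFAULT_MZ_RANGE
    pixel_size_um: tuple = DEFAULT_PIXEL_SIZE_UM
    grid_shape: Optional[tuple] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n_pixels, 2) array of (x, y)")
        if self.grid_shape is None:
            if len(self.coords) == 0:
                raise ValueError("cannot infer grid_shape from an empty dataset")
            self.grid_shape = (
                int(self.coords[:, 0].max()) + 1,
                int(self.coords[:, 1].max()) + 1,
            )
        if self.mz_axis is not None:
            # in-memory intensities stay float64; float32 applies to .ibd storage
            self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
            self.intensities = np.asarray(self.intensities, dtype=np.float64)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def is_continuous(self) -> bool:
        return self.mz_axis is not None

    def spectrum(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (mz, intensity) arrays for pixel ``i``."""
        if self.is_continuous:
            return self.mz_axis, self.intensities[i]
        return self.spectra[i]

    def iter_spectra(self):
        for i in range(self.n_pixels):
            yield self.spectrum(i)

    # -- validation --------------------------------------------------------
    def validate(self) -> "MSIDataset":
        """Check all structural invariants; raise ``ValueError`` on violation."""
        n_cols, n_rows = self.grid_shape
        if len(self.coords) == 0:
            raise ValueError("dataset has no pixels")
        if (
            self.coords[:, 0].min() < 0
            or self.coords[:, 1].min() < 0
            or self.coords[:, 0].max() >= n_cols
            or self.coords[:, 1].max() >= n_rows
        ):
            raise ValueError("pixel coordinates outside grid_shape")
        uniq = {tuple(c) for c in self.coords.tolist()}
        if len(uniq) != len(self.coords):
            raise ValueError("duplicate pixel coordinates")
        lo, hi = self.mz_range
        for mz, inten in self.iter_spectra():
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError("m/z axis not strictly increasing")
            if len(mz) and (mz[0] < lo - 1e-9 or mz[-1] > hi + 1e-9):
                raise ValueError("m/z values outside mz_range")
            if not np.all(np.isfinite(inten)):
                raise ValueError("non-finite intensity")
            if np.any(np.asarray(inten) < 0):
                raise ValueError("negative intensity")
            if self.is_continuous:
                break  # shared axis: one pass suffices for mz checks
        if self.is_continuous and not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity")
        if self.is_continuous and np.any(self.intensities < 0):
            raise ValueError("negative intensity")
        return self

    def copy(self) -> "MSIDataset":
        return replace(
            self,
            coords=self.coords.copy(),
            mz_axis=None if self.mz_axis is None else self.mz_axis.copy(),
            intensities=None if self.intensities is None else self.intensities.copy(),
            spectra=None
            if self.spectra is None
            else [(m.copy(), v.copy()) for m, v in self.spectra],
        )


@dataclass
class ROI:
    """One annotated region: name, morphology label, role and pixel mask.

    ``mask`` is a boolean ``(n_rows, n_cols)`` array indexed ``[y, x]``.
    """

    name: str
    morphology: str
    role: str
    mask: np.ndarray

    def __post_init__(self):
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(
                f"unknown morphology {self.morphology!r}; expected one of {sorted(MORPHOLOGIES)}"
            )
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def pixel_coords(self) -> np.ndarray:
        ys, xs = np.nonzero(self.mask)
        return np.column_stack([xs, ys])


@dataclass
class ROISet:
    """A named collection of ROIs tied to one dataset grid."""

    rois: list
    grid_shape: tuple

    def __post_init__(self):
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)

    def __getitem__(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def references(self) -> list:
        return [r for r in self.rois if r.role == "reference"]

    @property
    def queries(self) -> list:
        return [r for r in self.rois if r.role == "query"]

    def validate(self, ds: MSIDataset, allow_overlap: bool = False) -> "ROISet":
        n_cols, n_rows = ds.grid_shape
        occupied = np.zeros((n_rows, n_cols), dtype=bool)
        occupied[ds.coords[:, 1], ds.coords[:, 0]] = True
        total = np.zeros((n_rows, n_cols), dtype=np.int32)
        for r in self.rois:
            if r.mask.shape != (n_rows, n_cols):
                raise ValueError(f"ROI {r.name!r} mask shape does not match grid")
            if np.any(r.mask & ~occupied):
                raise ValueError(f"ROI {r.name!r} references pixels outside the dataset")
            total += r.mask
        if not allow_overlap and np.any(total > 1):
            raise ValueError("ROI masks overlap (pass allow_overlap=True to permit)")
        return self


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def write_imzml(ds: MSIDataset, path) -> Path:
    """Write a dataset to an imzML/.ibd file pair.

    Continuous mode is used when the dataset carries a shared m/z axis,
    processed mode otherwise.  Intensities are stored as 32-bit floats
    and m/z as 64-bit floats.
    """
    import hashlib
    import uuid as _uuid
    from unittest import mock

    from pyimzml.ImzMLWriter import ImzMLWriter

    if ds.n_pixels == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    mode = "continuous" if ds.is_continuous else "processed"
    if not ds.is_continuous:
        # processed mode tolerates per-pixel axes; continuous requires one axis
        lengths = {len(m) for m, _ in ds.spectra}
        if len(lengths) == 0:
            raise ValueError("no spectra to write")

    # content-derived UUID: identical datasets yield byte-identical files
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(ds.coords).tobytes())
    for mz, inten in ds.iter_spectra():
        h.update(np.asarray(mz, dtype=np.float64).tobytes())
        h.update(np.asarray(inten, dtype=np.float32).tobytes())
    det_uuid = _uuid.UUID(bytes=h.digest()[:16])

    with mock.patch("pyimzml.ImzMLWriter.uuid.uuid4", return_value=det_uuid), ImzMLWriter(
        str(path), mode=mode, mz_dtype=np.float64, intensity_dtype=np.float32
    ) as w:
        for i, (x, y) in enumerate(ds.coords):
            mz, inten = ds.spectrum(i)
            # imzML coordinates are 1-based
            w.addSpectrum(mz, inten, (int(x) + 1, int(y) + 1, 1))
    return path


def read_imzml(path) -> MSIDataset:
    """Read an imzML/.ibd pair into an :class:`MSIDataset`.

    A shared m/z axis is detected by comparing per-pixel axes; if all
    pixels share one axis the dataset is returned in continuous form.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FileNotFoundError(f"missing binary data file: {ibd}")
    parser = ImzMLParser(str(path))
    coords = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=np.int64)
    spectra = []
    for i in range(len(parser.coordinates)):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        if len(mz) > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError(f"pixel {i}: m/z axis not strictly increasing")
        if np.any(inten < 0):
            raise ValueError(f"pixel {i}: negative intensity")
        spectra.append((mz, inten))

    shared = len(spectra) > 0 and all(
        len(m) == len(spectra[0][0]) and np.array_equal(m, spectra[0][0])
        for m, _ in spectra[1:]
    )
    mz_lo = min(float(m[0]) for m, _ in spectra if len(m))
    mz_hi = max(float(m[-1]) for m, _ in spectra if len(m))
    mz_range = (min(DEFAULT_MZ_RANGE[0], mz_lo), max(DEFAULT_MZ_RANGE[1], mz_hi))
    if shared:
        ds = MSIDataset(
            coords=coords,
            mz_axis=spectra[0][0],
            intensities=np.vstack([v for _, v in spectra]),
            mz_range=mz_range,
        )
    else:
        ds = MSIDataset(coords=coords, spectra=spectra, mz_range=mz_range)
    return ds.validate()


# ---------------------------------------------------------------------------
# ROI masks: indexed label image + CSV sidecar
# ---------------------------------------------------------------------------

def write_roi_masks(roiset: ROISet, image_path, sidecar_path=None) -> tuple[Path, Path]:
    """Write an ROISet as an indexed label image (PNG) + CSV sidecar.

    Label 0 marks unannotated pixels; ROI i gets label i+1.  The sidecar
    has the header ``label,name,morphology,role``.
    """
    image_path = Path(image_path)
    if sidecar_path is None:
        sidecar_path = image_path.with_suffix(".csv")
    sidecar_path = Path(sidecar_path)
    n_cols, n_rows = roiset.grid_shape
    if len(roiset) > 255:
        raise ValueError("more than 255 ROIs cannot be stored in an 8-bit label image")
    labels = np.zeros((n_rows, n_cols), dtype=np.uint8)
    rows = []
    for i, roi in enumerate(roiset, start=1):
        if np.any(labels[roi.mask] != 0):
            raise ValueError("overlapping ROI masks cannot be stored as a label image")
        labels[roi.mask] = i
        rows.append({"label": i, "name": roi.name, "morphology": roi.morphology, "role": roi.role})
    Image.fromarray(labels, mode="L").save(image_path)
    pd.DataFrame(rows, columns=["label", "name", "morphology", "role"]).to_csv(
        sidecar_path, index=False
    )
    return image_path, sidecar_path


def read_roi_masks(path, ds: MSIDataset, sidecar_path=None) -> ROISet:
    """Read ROI masks from an indexed label image + CSV sidecar.

    ``path`` is the label image (PNG or single-channel TIFF); the sidecar
    defaults to the same path with a ``.csv`` suffix.
    """
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(".csv")
    labels = np.asarray(Image.open(path))
    if labels.ndim != 2:
        raise ValueError("label image must be single-channel (one integer label per pixel)")
    n_cols, n_rows = ds.grid_shape
    if labels.shape != (n_rows, n_cols):
        raise ValueError(
            f"label image shape {labels.shape} does not match grid (rows, cols)=({n_rows}, {n_cols})"
        )
    table = pd.read_csv(sidecar_path)
    required = {"label", "name", "morphology", "role"}
    if not required.issubset(table.columns):
        raise ValueError(f"sidecar must have columns {sorted(required)}")
    by_label = {int(r.label): r for r in table.itertuples()}
    rois = []
    for lab in sorted(int(v) for v in np.unique(labels) if v != 0):
        if lab not in by_label:
            raise ValueError(f"label {lab} present in image but missing from sidecar")
        row = by_label[lab]
        rois.append(
            ROI(
                name=str(row.name),
                morphology=str(row.morphology),
                role=str(row.role),
                mask=labels == lab,
            )
        )
    rs = ROISet(rois=rois, grid_shape=ds.grid_shape)
    return rs.validate(ds)
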