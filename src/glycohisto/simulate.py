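"""Synthetic MALDI-MSI tissue sections with known glycan phenotypes.

The simulator is the test bed for the pseudoinvasion-vs-true-invasion
decision logic.  A 2-D section is partitioned into morphology regions —
a surface epithelium band (normal / low-grade / high-grade dysplasia),
submucosal stroma, and a deep submucosal lesion — each carrying a
region-specific relative-abundance profile over a panel of glycan-like
peak masses.  Three scenario kinds encode the biology under test:

* ``pseudoinvasion``: the deep lesion's profile is an exact copy of one
  surface profile (misplaced epithelium keeps its phenotype);
* ``true_invasion``: the deep lesion carries a novel profile at Pearson
  distance >= a stated separation from every surface profile;
* ``malignant_polyp``: the full stratified layout with an invasive deep
  lesion, for segmentation benchmarking.

Pixel spectra are sums of Gaussian peaks with multiplicative log-normal
per-peak noise and per-pixel overall intensity jitter (so TIC
normalization is consequential), plus a small additive baseline; pixels
outside the tissue get a low-signal non-cellular background.  Everything
is fully determined by the scenario seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import MSIDataset, ROI, ROISet, write_imzml, write_roi_masks
from .phenotype import pearson_distance

__all__ = [
    "SyntheticScenario",
    "SCENARIO_KINDS",
    "glycan_panel_centers",
    "default_scenario",
    "simulate_dataset",
    "scenario_to_files",
]

SCENARIO_KINDS = ("pseudoinvasion", "true_invasion", "malignant_polyp")

#: m/z offsets (Da) sampled around every panel center: 17 samples at 0.1 Da.
AXIS_OFFSETS = np.round(np.arange(-8, 9) * 0.1, 10)

#: monoisotopic-ish building-block masses for plausible N-glycan spacings
_HEX = 162.0528
_HEXNAC = 203.0794
_NEUAC_DERIV = 273.0845


def glycan_panel_centers(
    n_peaks: int = 40,
    mz_min: float = 900.0,
    mz_max: float = 3300.0,
    min_spacing: float = 3.0,
) -> np.ndarray:
    """Deterministic panel of glycan-like peak masses.

    Candidate masses are combinations of hexose / HexNAc / derivatized
    sialic-acid increments on a chitobiose-like core, restricted to the
    acquisition window, thinned to a minimum spacing and subsampled
    evenly to ``n_peaks``.
    """
    core = 893.3278  # Hex3HexNAc2-like anchor
    cands = set()
    for a in range(0, 13):
        for b in range(0, 9):
            for c in range(0, 5):
                m = core + a * _HEX + b * _HEXNAC + c * _NEUAC_DERIV
                if mz_min + 10 <= m <= mz_max - 10:
                    cands.add(round(m, 4))
    cands = sorted(cands)
    spaced = []
    for m in cands:
        if not spaced or m - spaced[-1] >= min_spacing:
            spaced.append(m)
    if len(spaced) < n_peaks:
        raise ValueError("cannot build the requested panel within the m/z window")
    idx = np.linspace(0, len(spaced) - 1, n_peaks).round().astype(int)
    return np.array([spaced[i] for i in idx], dtype=np.float64)


@dataclass
class Region:
    name: str
    morphology: str
    role: str
    profile_id: str
    mask: np.ndarray  # (n_rows, n_cols) boolean


@dataclass
class SyntheticScenario:
    """Full generative description of one synthetic tissue section."""

    kind: str
    grid_shape: tuple
    pixel_size_um: tuple
    panel_centers: np.ndarray
    sigma_mz: float
    regions: list
    profiles: dict  # profile_id -> (n_peaks,) relative abundances
    pi_source: Optional[str]
    noise_sigma: float
    scale_jitter_sigma: float
    baseline_fraction: float
    background_tic_fraction: float
    min_invasive_separation: float
    seed: int

    def __post_init__(self):
        self.panel_centers = np.asarray(self.panel_centers, dtype=np.float64)
        for pid, prof in self.profiles.items():
            prof = np.asarray(prof, dtype=np.float64)
            if np.any(prof < 0):
                raise ValueError(f"profile {pid!r} has negative abundances")
            self.profiles[pid] = prof
        n_cols, n_rows = self.grid_shape
        for r in self.regions:
            if r.mask.shape != (n_rows, n_cols):
                raise ValueError(f"region {r.name!r} geometry outside grid")
        if self.pi_source is not None:
            lesion = self._deep_lesion()
            if not np.array_equal(
                self.profiles[lesion.profile_id], self.profiles[self.pi_source]
            ):
                raise AssertionError("pseudoinvasion profile must copy its source profile")
        if self.kind in ("true_invasion", "malignant_polyp"):
            lesion = self._deep_lesion()
            sep = min(
                pearson_distance(self.profiles[lesion.profile_id], self.profiles[p])
                for p in self.surface_profile_ids()
            )
            if sep < self.min_invasive_separation - 1e-12:
                raise AssertionError(
                    f"invasive profile separation {sep:.3f} below required "
                    f"{self.min_invasive_separation}"
                )

    def _deep_lesion(self) -> Region:
        for r in self.regions:
            if r.role == "query":
                return r
        raise ValueError("scenario has no query (deep lesion) region")

    def surface_profile_ids(self) -> list:
        return [
            r.profile_id
            for r in self.regions
            if r.role == "reference" and r.morphology in ("normal", "low_grade", "high_grade")
        ]

    def mz_axis(self) -> np.ndarray:
        return np.sort((self.panel_centers[:, None] + AXIS_OFFSETS[None, :]).ravel())

    def truth_labels(self) -> np.ndarray:
        """(n_rows, n_cols) integer labels: 0 = background, i+1 = regions[i]."""
        n_cols, n_rows = self.grid_shape
        lab = np.zeros((n_rows, n_cols), dtype=np.int64)
        for i, r in enumerate(self.regions, start=1):
            lab[r.mask] = i
        return lab

    def analytic_distances(self) -> pd.DataFrame:
        """Noise-free Pearson distances between the region profiles."""
        names = [r.name for r in self.regions]
        D = np.zeros((len(names), len(names)))
        for i, a in enumerate(self.regions):
            for j, b in enumerate(self.regions):
                if i < j:
                    D[i, j] = D[j, i] = pearson_distance(
                        self.profiles[a.profile_id], self.profiles[b.profile_id]
                    )
        return pd.DataFrame(D, index=names, columns=names)

    def to_json(self, path=None) -> str:
        payload = {
            "kind": self.kind,
            "grid_shape": list(self.grid_shape),
            "pixel_size_um": list(self.pixel_size_um),
            "panel_centers": [float(v) for v in self.panel_centers],
            "sigma_mz": self.sigma_mz,
            "regions": [
                {"name": r.name, "morphology": r.morphology, "role": r.role,
                 "profile_id": r.profile_id, "n_pixels": int(r.mask.sum())}
                for r in self.regions
            ],
            "profiles": {k: [float(v) for v in p] for k, p in self.profiles.items()},
            "pi_source": self.pi_source,
            "noise_sigma": self.noise_sigma,
            "scale_jitter_sigma": self.scale_jitter_sigma,
            "baseline_fraction": self.baseline_fraction,
            "background_tic_fraction": self.background_tic_fraction,
            "min_invasive_separation": self.min_invasive_separation,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# scenario construction
# ---------------------------------------------------------------------------

def _sample_profiles(seed: int, n_peaks: int, min_invasive_separation: float) -> dict:
    """Region abundance profiles: correlated log-normal vectors with a floor.

    Surface profiles share part of their log-abundance structure (epithelial
    lineages are related), the stromal profile is drawn the same way, and
    the invasive profile is drawn independently and re-drawn until it sits
    at least ``min_invasive_separation`` from every surface profile.
    """
    rng = np.random.default_rng([1, seed])
    z_shared = rng.normal(0.0, 1.0, n_peaks)
    floor = 0.05  # keeps every panel peak detectable in the mean spectrum
    profiles = {}
    for pid in ("normal", "low_grade", "high_grade", "stroma"):
        for _ in range(200):
            cand = floor + np.exp(0.7 * z_shared + 0.7 * rng.normal(0.0, 1.0, n_peaks))
            ok = all(
                pearson_distance(cand, profiles[q]) >= 0.2 for q in profiles
            )
            if ok:
                profiles[pid] = cand
                break
        else:
            raise RuntimeError("could not draw sufficiently distinct region profiles")
    for _ in range(200):
        cand = floor + np.exp(rng.normal(0.0, 1.2, n_peaks))
        sep = min(
            pearson_distance(cand, profiles[p])
            for p in ("normal", "low_grade", "high_grade")
        )
        if sep >= min_invasive_separation:
            profiles["invasive"] = cand
            break
    else:
        raise RuntimeError("could not draw a sufficiently novel invasive profile")
    return profiles


def _geometry(grid_shape=(60, 60), margin: int = 4):
    """Region masks: surface bands on top, stroma below, deep lesion disc."""
    n_cols, n_rows = grid_shape
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    tissue = (
        (xx >= margin) & (xx < n_cols - margin) & (yy >= margin) & (yy < n_rows - margin)
    )
    surf_lo, surf_hi = margin, margin + 8
    thirds = np.linspace(margin, n_cols - margin, 4).round().astype(int)
    surface = tissue & (yy < surf_hi)
    normal = surface & (xx < thirds[1])
    low_grade = surface & (xx >= thirds[1]) & (xx < thirds[2])
    high_grade = surface & (xx >= thirds[2])
    cx, cy, rad = n_cols // 2, int(n_rows * 0.63), 8
    lesion = tissue & ((xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2) & (yy >= surf_hi)
    stroma = tissue & (yy >= surf_hi) & ~lesion
    return {
        "normal": normal,
        "low_grade": low_grade,
        "high_grade": high_grade,
        "stroma": stroma,
        "lesion": lesion,
        "tissue": tissue,
    }


def default_scenario(
    kind: str,
    seed: int = 1,
    noise_sigma: float = 0.1,
    scale_jitter_sigma: float = 0.2,
    pi_source: str = "low_grade",
    min_invasive_separation: float = 0.5,
    grid_shape: tuple = (60, 60),
    n_peaks: int = 40,
) -> SyntheticScenario:
    """Build the standard scenario for one of the three study layouts."""
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}")
    profiles = _sample_profiles(seed, n_peaks, min_invasive_separation)
    geo = _geometry(grid_shape=grid_shape)

    if kind == "pseudoinvasion":
        lesion_morph, lesion_profile = "suspected_pi", pi_source
        profiles = dict(profiles)
        pi = pi_source
    elif kind == "true_invasion":
        lesion_morph, lesion_profile, pi = "suspected_invasion", "invasive", None
    else:  # malignant_polyp
        lesion_morph, lesion_profile, pi = "invasive", "invasive", None

    regions = [
        Region("surface_normal", "normal", "reference", "normal", geo["normal"]),
        Region("surface_lg", "low_grade", "reference", "low_grade", geo["low_grade"]),
        Region("surface_hg", "high_grade", "reference", "high_grade", geo["high_grade"]),
        Region("submucosa", "other", "reference", "stroma", geo["stroma"]),
        Region("deep_lesion", lesion_morph, "query", lesion_profile, geo["lesion"]),
    ]
    return SyntheticScenario(
        kind=kind,
        grid_shape=grid_shape,
        pixel_size_um=(50.0, 50.0),
        panel_centers=glycan_panel_centers(n_peaks=n_peaks),
        sigma_mz=0.15,
        regions=regions,
        profiles=profiles,
        pi_source=pi,
        noise_sigma=noise_sigma,
        scale_jitter_sigma=scale_jitter_sigma,
        baseline_fraction=0.01,
        background_tic_fraction=0.05,
        min_invasive_separation=min_invasive_separation,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# dataset synthesis
# ---------------------------------------------------------------------------

def simulate_dataset(sc: SyntheticScenario):
    """Render a scenario into (MSIDataset, ROISet, truth label matrix).

    Every grid position gets a spectrum.  Tissue pixel p in region g:
    ``scale_p * sum_k a_gk * exp(eps_pk) * Gaussian(c_k, sigma_mz) + baseline``
    with ``eps ~ N(0, noise_sigma^2)`` per pixel and peak and log-normal
    ``scale_p``.  Background pixels carry only a noisy baseline whose TIC
    is ``background_tic_fraction`` of the median tissue TIC.
    """
    rng = np.random.default_rng([2, sc.seed])
    n_cols, n_rows = sc.grid_shape
    axis = sc.mz_axis()
    n_mz = len(axis)
    n_peaks = len(sc.panel_centers)

    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    n_px = len(coords)
    truth = sc.truth_labels()
    labels_flat = truth.ravel()

    # per-peak Gaussian templates over the (non-uniform) axis
    B = np.exp(-((axis[None, :] - sc.panel_centers[:, None]) ** 2) / (2 * sc.sigma_mz**2))

    A = np.zeros((n_px, n_peaks))
    for i, r in enumerate(sc.regions, start=1):
        sel = labels_flat == i
        prof = sc.profiles[r.profile_id]
        eps = (
            rng.normal(0.0, sc.noise_sigma, size=(int(sel.sum()), n_peaks))
            if sc.noise_sigma > 0
            else np.zeros((int(sel.sum()), n_peaks))
        )
        A[sel] = prof[None, :] * np.exp(eps)

    signal = A @ B
    tissue = labels_flat > 0
    tissue_tic = np.median(signal[tissue].sum(axis=1)) if tissue.any() else 1.0
    baseline = sc.baseline_fraction * tissue_tic / n_mz
    signal[tissue] += baseline

    if sc.scale_jitter_sigma > 0:
        scale = np.exp(rng.normal(0.0, sc.scale_jitter_sigma, size=n_px))
        signal[tissue] *= scale[tissue, None]

    bg = ~tissue
    if bg.any():
        bg_level = sc.background_tic_fraction * tissue_tic / n_mz
        bg_noise = (
            np.exp(rng.normal(0.0, sc.noise_sigma, size=(int(bg.sum()), n_mz)))
            if sc.noise_sigma > 0
            else np.ones((int(bg.sum()), n_mz))
        )
        signal[bg] = bg_level * bg_noise

    ds = MSIDataset(
        coords=coords,
        mz_axis=axis,
        intensities=signal,
        mz_range=(900.0, 3300.0),
        pixel_size_um=sc.pixel_size_um,
        grid_shape=sc.grid_shape,
    ).validate()

    rois = ROISet(
        rois=[ROI(r.name, r.morphology, r.role, r.mask.copy()) for r in sc.regions],
        grid_shape=sc.grid_shape,
    ).validate(ds)
    return ds, rois, truth


def scenario_to_files(sc: SyntheticScenario, outdir, force: bool = False) -> dict:
    """Write a scenario's dataset, ROI masks, truth table and metadata.

    Produces ``data.imzML``/``data.ibd``, ``rois.png`` + ``rois.csv``,
    ``truth.csv`` (x, y, region label and name) and ``scenario.json``.
    Refuses to overwrite existing files unless ``force`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "imzml": outdir / "data.imzML",
        "ibd": outdir / "data.ibd",
        "roi_image": outdir / "rois.png",
        "roi_sidecar": outdir / "rois.csv",
        "truth": outdir / "truth.csv",
        "scenario": outdir / "scenario.json",
    }
    clashes = [p for p in paths.values() if p.exists()]
    if clashes and not force:
        raise FileExistsError(
            f"output files already exist (pass force=True to overwrite): {clashes[0]}"
        )
    ds, rois, truth = simulate_dataset(sc)
    write_imzml(ds, paths["imzml"])
    write_roi_masks(rois, paths["roi_image"], paths["roi_sidecar"])
    names = {0: "background", **{i: r.name for i, r in enumerate(sc.regions, start=1)}}
    ys, xs = np.mgrid[0 : truth.shape[0], 0 : truth.shape[1]]
    pd.DataFrame(
        {
            "x": xs.ravel(),
            "y": ys.ravel(),
            "region_label": truth.ravel(),
            "region_name": [names[int(v)] for v in truth.ravel()],
        }
    ).to_csv(paths["truth"], index=False)
    sc.to_json(paths["scenario"])
    return {k: str(v) for k, v in paths.items()}
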