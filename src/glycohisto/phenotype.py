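"""ROI phenotype matching by Pearson correlation distance.

Each annotated region's glycan phenotype is summarised as the mean of its
cellular pixels' normalized feature vectors.  Pairs of regions are
compared with the Pearson correlation distance d = 1 - r (0 for identical
profiles, up to 2 for perfect anticorrelation; not a metric — the
triangle inequality can fail).  A query region (e.g. a deep submucosal
lesion) is annotated with the morphology of the closest reference
region; if even the best reference is farther than a novelty threshold,
the query is called a *novel* phenotype — the in-silico analogue of the
diagnostic argument that a novel molecular phenotype deep in the
submucosa favors true invasion over pseudoinvasion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import ROI, ROISet
from .preprocess import FeatureMatrix

__all__ = [
    "PhenotypeReport",
    "roi_mean_profile",
    "pearson_distance",
    "distance_matrix",
    "annotate_query",
    "cluster_concordance",
    "phenotype_report",
]


@dataclass
class PhenotypeReport:
    """ROI mean profiles, pairwise distances and query annotations."""

    roi_names: list
    roi_morphologies: dict
    roi_roles: dict
    profiles: dict                 # name -> np.ndarray feature vector
    distances: np.ndarray          # (n_roi, n_roi) Pearson correlation distance
    annotations: dict              # query name -> annotation dict
    params: dict

    def distance(self, a: str, b: str) -> float:
        ia, ib = self.roi_names.index(a), self.roi_names.index(b)
        return float(self.distances[ia, ib])

    def distance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.roi_names, columns=self.roi_names)

    def to_json(self, path=None) -> str:
        payload = {
            "rois": [
                {
                    "name": n,
                    "morphology": self.roi_morphologies[n],
                    "role": self.roi_roles[n],
                    "profile": [float(v) for v in self.profiles[n]],
                }
                for n in self.roi_names
            ],
            "distance_matrix": {
                "names": self.roi_names,
                "values": [[float(v) for v in row] for row in self.distances],
            },
            "annotations": self.annotations,
            "params": self.params,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.distance_frame().to_csv(path)
        return path


def roi_mean_profile(fm: FeatureMatrix, roi: ROI) -> np.ndarray:
    """Mean normalized feature vector over the ROI's cellular pixels."""
    idx = fm.pixel_index_grid()[roi.mask]
    idx = idx[idx >= 0]
    idx = idx[fm.cellular_mask[idx]]
    if len(idx) == 0:
        raise ValueError(f"ROI {roi.name!r} contains no cellular pixels")
    return fm.values[idx].mean(axis=0)


def pearson_distance(p, q) -> float:
    """Pearson correlation distance d = 1 - r between two feature vectors.

    r is computed with the raw-sums form
    ``(n*sum(pq) - sum(p)*sum(q)) / sqrt((n*sum(p^2) - sum(p)^2) * (...))``,
    which makes d(x, x) exactly zero for any input (the numerator and the
    squared denominator coincide bit for bit).  Adequate for normalized
    intensity profiles; not intended for data with a huge mean-to-spread
    ratio.  Undefined (raises) for constant vectors or length < 3.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    n = len(p)
    if n < 3:
        raise ValueError("profiles must have length >= 3")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        raise ValueError("Pearson correlation is undefined for constant profiles")
    sp, sq = p.sum(), q.sum()
    num = n * (p @ q) - sp * sq
    var_p = n * (p @ p) - sp * sp
    var_q = n * (q @ q) - sq * sq
    r = num / np.sqrt(var_p * var_q)
    return float(1.0 - max(-1.0, min(1.0, r)))


def distance_matrix(profiles: dict) -> tuple[list, np.ndarray]:
    """Symmetric Pearson-distance matrix over named ROI profiles."""
    names = list(profiles)
    if len(names) < 2:
        raise ValueError("need at least two ROI profiles")
    n = len(names)
    D = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            d = pearson_distance(profiles[names[i]], profiles[names[j]])
            D[i, j] = D[j, i] = d
    return names, D


def annotate_query(
    profiles: dict,
    reference_morphologies: dict,
    query_name: str,
    threshold: float = 0.25,
    novel_if: str = "ge",
) -> dict:
    """Annotate one query ROI against the reference ROIs.

    The query is labeled with the morphology of the reference minimising
    the Pearson distance (ties broken by reference name); it is called
    *novel* when the best distance reaches the threshold (``novel_if``:
    "ge" counts an exact tie with the threshold as novel, "gt" does not).
    """
    if novel_if not in {"ge", "gt"}:
        raise ValueError("novel_if must be 'ge' or 'gt'")
    refs = sorted(reference_morphologies)
    if not refs:
        raise ValueError("at least one reference ROI is required")
    dists = {r: pearson_distance(profiles[query_name], profiles[r]) for r in refs}
    best = min(refs, key=lambda r: (dists[r], r))
    best_d = dists[best]
    novel = best_d >= threshold if novel_if == "ge" else best_d > threshold
    return {
        "query": query_name,
        "best_reference": best,
        "molecular_annotation": reference_morphologies[best],
        "best_distance": float(best_d),
        "reference_distances": {r: float(dists[r]) for r in refs},
        "novel": bool(novel),
        "threshold": float(threshold),
        "novel_if": novel_if,
    }


def cluster_concordance(
    fm: FeatureMatrix,
    cluster_id: np.ndarray,
    query_roi: ROI,
    reference_roi: ROI,
) -> float:
    """Fraction of query cellular pixels whose cluster also occurs in the reference.

    A qualitative second line of evidence alongside the profile distance:
    a pseudoinvasion focus shares the cluster(s) of its source surface
    epithelium, a true invasion forms its own cluster.
    """
    grid = fm.pixel_index_grid()
    # cluster label per pixel row (only cellular rows have one)
    labels_full = np.full(fm.n_pixels, -1, dtype=np.int64)
    labels_full[np.nonzero(fm.cellular_mask)[0]] = np.asarray(cluster_id)

    def roi_labels(roi):
        idx = grid[roi.mask]
        idx = idx[idx >= 0]
        lab = labels_full[idx]
        return lab[lab >= 0]

    q = roi_labels(query_roi)
    ref = roi_labels(reference_roi)
    if len(q) == 0 or len(ref) == 0:
        raise ValueError("empty ROI (no cellular pixels) in concordance computation")
    return float(np.isin(q, np.unique(ref)).mean())


def phenotype_report(
    fm: FeatureMatrix,
    roiset: ROISet,
    threshold: float = 0.25,
    novel_if: str = "ge",
    cluster_id: Optional[np.ndarray] = None,
) -> PhenotypeReport:
    """Compute ROI profiles, the full distance matrix and query annotations."""
    if not roiset.references:
        raise ValueError("at least one reference ROI is required for phenotype scoring")
    profiles = {r.name: roi_mean_profile(fm, r) for r in roiset}
    names, D = distance_matrix(profiles)
    ref_morph = {r.name: r.morphology for r in roiset.references}
    annotations = {}
    for q in roiset.queries:
        ann = annotate_query(profiles, ref_morph, q.name, threshold=threshold, novel_if=novel_if)
        if cluster_id is not None:
            ann["cluster_concordance"] = {
                r.name: cluster_concordance(fm, cluster_id, q, r) for r in roiset.references
            }
        annotations[q.name] = ann
    return PhenotypeReport(
        roi_names=names,
        roi_morphologies={r.name: r.morphology for r in roiset},
        roi_roles={r.name: r.role for r in roiset},
        profiles=profiles,
        distances=D,
        annotations=annotations,
        params={"threshold": threshold, "novel_if": novel_if},
    )
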