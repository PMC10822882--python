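"""Spatial segmentation: embedding, graph clustering, molecular histology image.

Cellular pixel feature vectors are embedded in 2-D with UMAP for
visualisation and QC, and partitioned by community detection on a shared
nearest-neighbor (SNN) graph built from the feature matrix — the
architecture popularised by single-cell clustering pipelines (kNN -> SNN
with Jaccard weights -> modularity optimisation at a resolution).  Each
cluster is assigned a distinct RGB color and painted into a raster with
one image pixel per MSI pixel; non-cellular pixels are white, which makes
the result read like a stained section ("molecular histology").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .preprocess import FeatureMatrix

__all__ = [
    "SegmentationResult",
    "DEFAULT_PALETTE",
    "embed",
    "snn_graph",
    "cluster",
    "make_palette",
    "render_molecular_histology",
    "whiteout_noncellular_clusters",
    "segment",
]

WHITE = (255, 255, 255)

# Categorical palette (tab20-derived, white excluded), used in cluster-size order.
DEFAULT_PALETTE = [
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207), (174, 199, 232), (255, 187, 120),
    (152, 223, 138), (255, 152, 150), (197, 176, 213), (196, 156, 148),
    (247, 182, 210), (199, 199, 199), (219, 219, 141), (158, 218, 229),
]


@dataclass
class SegmentationResult:
    """Everything the segmentation stage produces for one tissue."""

    embedding: Optional[np.ndarray]  # (n_cellular, 2) or None if not embedded
    cluster_id: np.ndarray           # (n_cellular,) integer labels 0..k-1
    palette: dict                    # cluster -> (r, g, b)
    image: np.ndarray                # (n_rows, n_cols, 3) uint8
    params: dict
    cellular_mask: np.ndarray        # per-pixel, possibly updated by whiteout
    whited_clusters: set = field(default_factory=set)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max()) + 1 if len(self.cluster_id) else 0

    def cluster_table(self, fm: FeatureMatrix) -> pd.DataFrame:
        coords = fm.coords[fm.cellular_mask]
        return pd.DataFrame(
            {"x": coords[:, 0], "y": coords[:, 1], "cluster_id": self.cluster_id}
        )

    def save_image(self, path, upscale: int = 1) -> Path:
        from PIL import Image

        img = self.image
        if upscale > 1:
            img = np.kron(img, np.ones((upscale, upscale, 1), dtype=np.uint8))
        path = Path(path)
        Image.fromarray(img, mode="RGB").save(path)
        return path


def embed(
    fm: FeatureMatrix,
    n_neighbors: int = 30,
    min_dist: float = 0.3,
    n_components: int = 2,
    seed: int = 42,
) -> np.ndarray:
    """UMAP-embed the cellular pixel feature vectors.

    Deterministic for a fixed seed (single-threaded when seeded).
    """
    import umap

    X = fm.values[fm.cellular_mask]
    if len(X) < n_neighbors + 1:
        raise ValueError(
            f"only {len(X)} cellular pixels but n_neighbors={n_neighbors}; "
            "lower n_neighbors below the number of cellular pixels"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            n_components=n_components,
            random_state=int(seed),
        )
        return np.asarray(reducer.fit_transform(X), dtype=np.float64)


def snn_graph(X: np.ndarray, n_neighbors: int = 20, prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each point is connected to its k nearest neighbors (self included);
    the weight of edge (i, j) is |N(i) ∩ N(j)| / |N(i) ∪ N(j)| and edges
    with weight below ``prune`` are dropped.
    """
    n = len(X)
    k = min(n_neighbors, n)
    nn = NearestNeighbors(n_neighbors=k, algorithm="auto").fit(X)
    idx = nn.kneighbors(return_distance=False)
    # include self in the neighborhood, as kNN-graph clustering conventionally does
    rows = np.repeat(np.arange(n), idx.shape[1] + 1)
    cols = np.concatenate([idx, np.arange(n)[:, None]], axis=1).ravel()
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A.data[:] = 1.0
    shared = (A @ A.T).tocoo()
    ksz = idx.shape[1] + 1
    jacc = shared.data / (2 * ksz - shared.data)
    keep = (jacc >= prune) & (shared.row != shared.col)
    return sp.csr_matrix((jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 by decreasing size (ties: smallest member index)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    first_member = {u: int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-int((labels == u).sum()), first_member[u]))
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=np.int64)


def cluster(
    data,
    n_neighbors: int = 20,
    resolution: float = 0.4,
    seed: int = 42,
    prune: float = 1 / 15,
) -> np.ndarray:
    """Cluster pixels by Leiden community detection on an SNN graph.

    ``data`` is a FeatureMatrix (cellular pixels are used) or a plain
    (n, d) array — the feature matrix by default, or the 2-D embedding if
    the caller prefers clustering in embedding space.  Labels are
    0..k-1, ordered by decreasing cluster size; deterministic given seed.
    """
    import igraph as ig
    import leidenalg

    if isinstance(data, FeatureMatrix):
        X = data.values[data.cellular_mask]
    else:
        X = np.asarray(data, dtype=np.float64)
    n = len(X)
    if n == 0:
        raise ValueError("no cellular pixels to cluster")
    if n == 1:
        warnings.warn("single pixel: trivial one-cluster result")
        return np.zeros(1, dtype=np.int64)

    W = snn_graph(X, n_neighbors=n_neighbors, prune=prune)
    W = sp.triu(W, k=1).tocoo()
    g = ig.Graph(
        n=n, edges=list(zip(W.row.tolist(), W.col.tolist())), edge_attrs={"weight": W.data}
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return _relabel_by_size(np.array(part.membership, dtype=np.int64))


def make_palette(n_clusters: int) -> dict:
    """Distinct categorical palette for ``n_clusters`` clusters; white reserved."""
    palette = {}
    for c in range(n_clusters):
        base = DEFAULT_PALETTE[c % len(DEFAULT_PALETTE)]
        if c >= len(DEFAULT_PALETTE):
            # darken repeated colors to keep them distinguishable
            f = 0.6 ** (c // len(DEFAULT_PALETTE))
            base = tuple(max(0, int(v * f)) for v in base)
        palette[c] = base
    return palette


def render_molecular_histology(
    fm: FeatureMatrix, cluster_id: np.ndarray, palette: Optional[dict] = None
) -> tuple[np.ndarray, dict]:
    """Paint each cellular pixel with its cluster color; everything else white.

    Returns the (n_rows, n_cols, 3) uint8 raster and the palette used.
    """
    cluster_id = np.asarray(cluster_id)
    n_clusters = int(cluster_id.max()) + 1 if len(cluster_id) else 0
    if palette is None:
        palette = make_palette(n_clusters)
    if any(tuple(v) == WHITE for v in palette.values()):
        raise ValueError("palette must not contain white; white marks non-cellular pixels")
    n_cols, n_rows = fm.grid_shape
    img = np.full((n_rows, n_cols, 3), 255, dtype=np.uint8)
    coords = fm.coords[fm.cellular_mask]
    for c in range(n_clusters):
        sel = coords[cluster_id == c]
        img[sel[:, 1], sel[:, 0]] = palette[c]
    return img, palette


def whiteout_noncellular_clusters(
    result: SegmentationResult, fm: FeatureMatrix, median_tic_threshold: float
) -> SegmentationResult:
    """Recolor whole clusters as white when their median pre-normalization TIC
    falls below ``median_tic_threshold``, and mark their pixels non-cellular.

    This is the cluster-level analogue of the pixel TIC flag and the
    mechanism that removes matrix/background areas from the image.
    """
    tic_cellular = fm.tic[fm.cellular_mask]
    cellular = fm.cellular_mask.copy()
    coords = fm.coords[fm.cellular_mask]
    img = result.image.copy()
    whited = set(result.whited_clusters)
    for c in range(result.n_clusters):
        members = result.cluster_id == c
        if not members.any():
            continue
        if float(np.median(tic_cellular[members])) < median_tic_threshold:
            whited.add(c)
            sel = coords[members]
            img[sel[:, 1], sel[:, 0]] = WHITE
            flat = fm.pixel_index_grid()[sel[:, 1], sel[:, 0]]
            cellular[flat] = False
    return replace(result, image=img, cellular_mask=cellular, whited_clusters=whited)


def segment(
    fm: FeatureMatrix,
    n_neighbors_umap: int = 30,
    min_dist: float = 0.3,
    snn_k: int = 20,
    resolution: float = 0.4,
    seed: int = 42,
    cluster_on: str = "features",
    run_umap: bool = True,
    whiteout_median_tic_fraction: Optional[float] = 0.2,
) -> SegmentationResult:
    """Full segmentation stage: embed, cluster, render, white out background.

    ``cluster_on`` selects the clustering substrate ("features", the
    default matching the SNN-graph convention, or "embedding").  When
    ``whiteout_median_tic_fraction`` is set, clusters whose median TIC is
    below that fraction of the median cellular TIC are whited out.
    """
    if cluster_on not in {"features", "embedding"}:
        raise ValueError("cluster_on must be 'features' or 'embedding'")
    embedding = None
    if run_umap or cluster_on == "embedding":
        embedding = embed(fm, n_neighbors=n_neighbors_umap, min_dist=min_dist, seed=seed)
    substrate = embedding if cluster_on == "embedding" else fm
    labels = cluster(substrate, n_neighbors=snn_k, resolution=resolution, seed=seed)
    img, palette = render_molecular_histology(fm, labels)
    result = SegmentationResult(
        embedding=embedding,
        cluster_id=labels,
        palette=palette,
        image=img,
        params={
            "n_neighbors": n_neighbors_umap,
            "min_dist": min_dist,
            "snn_k": snn_k,
            "resolution": resolution,
            "seed": seed,
            "cluster_on": cluster_on,
        },
        cellular_mask=fm.cellular_mask.copy(),
    )
    if whiteout_median_tic_fraction is not None:
        med = float(np.median(fm.tic[fm.cellular_mask]))
        result = whiteout_noncellular_clusters(
            result, fm, median_tic_threshold=whiteout_median_tic_fraction * med
        )
    return result
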