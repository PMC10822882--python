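"""High-level model interface: fit a molecular-histology model to one tissue.

:class:`MolecularHistology` bundles the full analysis of a single MSI
tissue section — TIC normalization, mean-spectrum peak picking, feature
extraction, SNN-graph segmentation and ROI phenotype matching — behind a
model/results pair.  Construct the model from data (an imzML file, an
in-memory dataset, or a synthetic scenario), call :meth:`fit`, and read
estimates off the returned :class:`MolecularHistologyResults`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .io import MSIDataset, ROISet, read_imzml, read_roi_masks
from .preprocess import (
    FeatureMatrix,
    PeakPanel,
    build_feature_matrix,
    flag_noncellular,
    mean_spectrum,
    pick_peaks,
    tic_normalize,
)
from .phenotype import PhenotypeReport, phenotype_report
from .segment import SegmentationResult, segment

__all__ = ["PipelineParams", "MolecularHistology", "MolecularHistologyResults"]


@dataclass
class PipelineParams:
    """Every tunable parameter of the analysis, serialized into the manifest."""

    # preprocessing
    tic_target: float = 1.0
    snr_threshold: float = 3.0
    min_rel_intensity: float = 0.001
    window_halfwidth_da: float = 0.4
    bin_width: float = 0.1
    noncellular_quantile: float = 0.05
    min_abs_tic: float = 0.0
    # segmentation
    n_neighbors: int = 30
    min_dist: float = 0.3
    snn_k: int = 20
    resolution: float = 0.4
    cluster_on: str = "features"
    run_umap: bool = True
    whiteout_median_tic_fraction: float = 0.2
    seed: int = 42
    # phenotype
    threshold: float = 0.25
    novel_if: str = "ge"

    def validate(self) -> "PipelineParams":
        if self.tic_target <= 0:
            raise ValueError("tic_target must be positive")
        if not 0 <= self.noncellular_quantile <= 1:
            raise ValueError("noncellular_quantile must be in [0, 1]")
        if self.cluster_on not in {"features", "embedding"}:
            raise ValueError("cluster_on must be 'features' or 'embedding'")
        if self.novel_if not in {"ge", "gt"}:
            raise ValueError("novel_if must be 'ge' or 'gt'")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        return self


class MolecularHistology:
    """Molecular-histology model of one MSI tissue section.

    Parameters
    ----------
    dataset
        The raw (unnormalized) :class:`MSIDataset`.
    rois
        Optional :class:`ROISet` of reference/query regions; without it,
        only segmentation is fitted (no phenotype report).
    params
        :class:`PipelineParams` or keyword overrides of its fields.
    """

    def __init__(self, dataset: MSIDataset, rois: Optional[ROISet] = None, **params):
        self.dataset = dataset.validate()
        self.rois = rois.validate(dataset) if rois is not None else None
        if len(params) == 1 and isinstance(params.get("params"), PipelineParams):
            self.params = params["params"].validate()
        else:
            self.params = PipelineParams(**params).validate()

    @classmethod
    def from_imzml(cls, path, roi_path=None, roi_sidecar=None, **params) -> "MolecularHistology":
        ds = read_imzml(path)
        rois = read_roi_masks(roi_path, ds, roi_sidecar) if roi_path is not None else None
        return cls(ds, rois, **params)

    @classmethod
    def from_scenario(cls, scenario, **params) -> "MolecularHistology":
        from .simulate import simulate_dataset

        ds, rois, _ = simulate_dataset(scenario)
        return cls(ds, rois, **params)

    def fit(self, segment_tissue: bool = True) -> "MolecularHistologyResults":
        """Run the full analysis and return the results object."""
        p = self.params
        ds_norm, tic = tic_normalize(self.dataset, target=p.tic_target)
        mz, mean_int = mean_spectrum(ds_norm, bin_width=p.bin_width)
        panel = pick_peaks(
            (mz, mean_int),
            snr_threshold=p.snr_threshold,
            min_rel_intensity=p.min_rel_intensity,
            window_halfwidth_da=p.window_halfwidth_da,
        )
        fm = build_feature_matrix(
            ds_norm, panel, tic=tic, normalization_target=p.tic_target, bin_width=p.bin_width
        )
        fm = flag_noncellular(fm, tic_quantile=p.noncellular_quantile, min_abs_tic=p.min_abs_tic)

        segmentation = None
        if segment_tissue:
            segmentation = segment(
                fm,
                n_neighbors_umap=p.n_neighbors,
                min_dist=p.min_dist,
                snn_k=p.snn_k,
                resolution=p.resolution,
                seed=p.seed,
                cluster_on=p.cluster_on,
                run_umap=p.run_umap,
                whiteout_median_tic_fraction=p.whiteout_median_tic_fraction,
            )

        report = None
        if self.rois is not None and self.rois.references:
            # profile statistics use the post-whiteout cellular mask; the
            # cluster vector is filtered to the surviving pixels to match
            fm_scored, labels_scored = fm, None
            if segmentation is not None:
                from dataclasses import replace

                kept = segmentation.cellular_mask[fm.cellular_mask]
                fm_scored = replace(fm, cellular_mask=segmentation.cellular_mask)
                labels_scored = segmentation.cluster_id[kept]
            report = phenotype_report(
                fm_scored,
                self.rois,
                threshold=p.threshold,
                novel_if=p.novel_if,
                cluster_id=labels_scored,
            )
        return MolecularHistologyResults(
            model=self,
            panel=panel,
            feature_matrix=fm,
            segmentation=segmentation,
            report=report,
        )


class MolecularHistologyResults:
    """Fitted molecular histology: feature matrix, segmentation, phenotype calls."""

    def __init__(self, model, panel, feature_matrix, segmentation, report):
        self.model = model
        self.panel: PeakPanel = panel
        self.feature_matrix: FeatureMatrix = feature_matrix
        self.segmentation: Optional[SegmentationResult] = segmentation
        self.report: Optional[PhenotypeReport] = report

    @property
    def params(self) -> PipelineParams:
        return self.model.params

    @property
    def n_clusters(self) -> Optional[int]:
        return None if self.segmentation is None else self.segmentation.n_clusters

    def summary(self) -> str:
        """Plain-text summary table of the fitted tissue."""
        lines = []
        p = self.params
        fm = self.feature_matrix
        lines.append("Molecular histology summary")
        lines.append("=" * 64)
        lines.append(f"pixels: {fm.n_pixels}   picked peaks: {fm.n_features}")
        lines.append(
            f"cellular pixels (pre-flag): {int(fm.cellular_mask.sum())}"
        )
        if self.segmentation is not None:
            s = self.segmentation
            sizes = np.bincount(s.cluster_id, minlength=s.n_clusters)
            lines.append(
                f"clusters: {s.n_clusters} (whited out: {sorted(s.whited_clusters)})"
            )
            lines.append("cluster sizes: " + ", ".join(f"{c}:{n}" for c, n in enumerate(sizes)))
        if self.report is not None:
            lines.append("-" * 64)
            lines.append("ROI Pearson correlation distances (d = 1 - r):")
            lines.append(self.report.distance_frame().round(4).to_string())
            for name, ann in self.report.annotations.items():
                lines.append("-" * 64)
                verdict = "NOVEL phenotype" if ann["novel"] else "matches reference"
                lines.append(
                    f"query {name!r}: best reference = {ann['best_reference']} "
                    f"({ann['molecular_annotation']}), d = {ann['best_distance']:.4f} "
                    f"-> {verdict} (threshold {ann['threshold']}, heuristic)"
                )
        lines.append("=" * 64)
        lines.append(f"params: seed={p.seed}, resolution={p.resolution}, snn_k={p.snn_k}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------
    def manifest(self) -> dict:
        import igraph
        import leidenalg
        import sklearn
        import umap

        return {
            "glycohisto_version": __version__,
            "params": asdict(self.params),
            "n_pixels": int(self.feature_matrix.n_pixels),
            "n_features": int(self.feature_matrix.n_features),
            "n_clusters": self.n_clusters,
            "versions": {
                "numpy": np.__version__,
                "scikit-learn": sklearn.__version__,
                "umap-learn": umap.__version__,
                "igraph": igraph.__version__,
                "leidenalg": leidenalg.version,
            },
        }

    def save(self, outdir, upscale: int = 1) -> dict:
        """Write the full output bundle; returns a name -> path mapping."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["peak_panel"] = str(self.panel.to_csv(outdir / "peak_panel.csv"))
        paths["feature_matrix"] = str(self.feature_matrix.to_csv(outdir / "feature_matrix.csv"))
        if self.segmentation is not None:
            paths["clusters"] = str(outdir / "clusters.csv")
            self.segmentation.cluster_table(self.feature_matrix).to_csv(
                paths["clusters"], index=False
            )
            paths["image"] = str(
                self.segmentation.save_image(outdir / "molecular_histology.png", upscale=upscale)
            )
            if self.segmentation.embedding is not None:
                paths["embedding"] = str(outdir / "embedding.csv")
                coords = self.feature_matrix.coords[self.feature_matrix.cellular_mask]
                pd.DataFrame(
                    {
                        "x": coords[:, 0],
                        "y": coords[:, 1],
                        "umap_1": self.segmentation.embedding[:, 0],
                        "umap_2": self.segmentation.embedding[:, 1],
                    }
                ).to_csv(paths["embedding"], index=False)
        if self.report is not None:
            paths["report"] = str(outdir / "report.json")
            self.report.to_json(paths["report"])
            paths["distances"] = str(self.report.to_csv(outdir / "distances.csv"))
        paths["manifest"] = str(outdir / "manifest.json")
        Path(paths["manifest"]).write_text(json.dumps(self.manifest(), indent=2, sort_keys=True))
        return paths

    # -- plotting -------------------------------------------------------------
    def plot_image(self, ax=None):
        """Show the molecular-histology raster."""
        import matplotlib.pyplot as plt

        if self.segmentation is None:
            raise ValueError("no segmentation fitted")
        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.segmentation.image, interpolation="nearest")
        ax.set_title("molecular histology")
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        return ax

    def plot_embedding(self, ax=None):
        """Scatter the 2-D embedding colored by cluster."""
        import matplotlib.pyplot as plt

        if self.segmentation is None or self.segmentation.embedding is None:
            raise ValueError("no embedding fitted (run_umap=False?)")
        if ax is None:
            _, ax = plt.subplots()
        emb = self.segmentation.embedding
        colors = np.array(
            [self.segmentation.palette[c] for c in self.segmentation.cluster_id]
        ) / 255.0
        ax.scatter(emb[:, 0], emb[:, 1], c=colors, s=4, linewidths=0)
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        return ax
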