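# Methods

This note documents the models, parameter choices and limitations of
`glycohisto` at the level a maintainer or reviewer needs; the README covers
usage.

## Problem setting

A MALDI-MSI run over a tissue section yields one mass spectrum per pixel
(default data model: 50 × 50 μm² pixels, m/z 900–3,300 — typical for
N-glycan imaging on a TOF instrument). A pathologist supplies regions of
interest (ROIs) in pixel coordinates: *reference* ROIs for the surface
morphologies (normal epithelium, low-/high-grade dysplasia, stroma) and a
*query* ROI for a deep submucosal lesion whose nature is in question. The
package answers two questions: (i) what does the section look like when
pixels are colored by spectral cluster ("molecular histology"), and (ii) is
the query's glycan phenotype a copy of some surface phenotype or a novel
one?

## Preprocessing

1. **TIC normalization.** Each pixel spectrum is scaled so its intensity sum
   equals `tic_target` (default 1.0). Pearson correlation is location- and
   scale-invariant, so the target is cosmetic; unit sum aids interpretation.
   Zero-TIC pixels are kept in the grid (image geometry) but excluded from
   all statistics. Normalization happens before peak integration; the
   operation order is a package convention, since "peak picked, TIC
   normalized" workflows in vendor software do not fix it.
2. **Common axis.** Processed-mode (per-pixel axis) data are binned to a
   uniform axis at `bin_width` = 0.1 Da before anything else; continuous
   data are used as stored.
3. **Peak picking** runs once on the dataset **mean** spectrum, not per
   pixel — the common MSI convention, which stabilizes the feature axis
   across pixels. Apexes are local maxima above
   `max(snr_threshold × noise, min_rel_intensity × base peak)` with
   `snr_threshold` = 3 and `min_rel_intensity` = 0.1%. The noise level is
   1.4826 × MAD of the median-filter-detrended mean spectrum (robust,
   standard). Each peak gets a ± `window_halfwidth_da` = 0.4 Da window;
   overlapping windows are truncated at the midpoint between apexes. These
   defaults are typical for TOF glycomics in this mass range and are all
   configurable.
4. **Features** are window integrals of the normalized spectrum, so a panel
   tiling the axis conserves the normalization target exactly (tested to
   1e-6).
5. **Non-cellular pre-flag.** Pixels whose pre-normalization TIC falls below
   the `noncellular_quantile` (default 0.05) cutoff are flagged non-cellular
   and excluded from embedding and ROI statistics. This is deliberately a
   *coarse* pre-flag: with a default 5% quantile it can flag at most ~5% of
   pixels, which is far less than the off-tissue area of a typical slide.
   The authoritative background removal is cluster-level (below), which is
   also how non-cellular area is identified in practice — a whole cluster of
   matrix/glass pixels, not individual outliers.

## Segmentation

Cellular pixel feature vectors are clustered by Leiden modularity
optimisation (RBConfiguration objective) on a shared-nearest-neighbor graph:
k = `snn_k` = 20 nearest neighbours (self included), Jaccard edge weights,
edges pruned below 1/15. This mirrors the default single-cell pipeline
architecture (kNN → SNN → community detection on the graph, not on the 2-D
embedding); a `cluster_on="embedding"` switch exists because "UMAP cluster"
is ambiguous in common usage, but the feature-graph route is the default.
UMAP (n_neighbors 30, min_dist 0.3) provides the 2-D embedding for QC and
plotting and is reproducible under `seed` (default 42, recorded in the run
manifest together with every other parameter and library versions).

**Resolution.** The default modularity resolution is **0.4**, not the 0.8
familiar from single-cell work. A tissue section has a handful of
morphological compartments, one of which (stroma/submucosa) can easily be
more than half of all pixels; at resolution 0.8 the optimiser reliably
splits that large homogeneous compartment into 2–3 clusters, which is noise
from the point of view of molecular histology. At 0.4 the synthetic
stratified section is recovered exactly (ARI 1.0 at the reference seed).
This is a scale choice, not a tuning constant: occasional splits of a very
large homogeneous compartment can still occur at particular noise
realisations at *any* resolution — a known scale sensitivity of modularity
clustering, and the main known limitation of the segmentation stage. Splits
never merged distinct compartments in our checks, so phenotype matching and
the invasive-cluster purity property are unaffected.

Clusters are relabeled by decreasing size (deterministic, tie-free), colored
from a categorical palette with white reserved, and painted one raster pixel
per MSI pixel. **Cluster white-out:** any cluster whose median
pre-normalization TIC is below `whiteout_median_tic_fraction` = 0.2 of the
median cellular TIC is recolored white and marked non-cellular.

## Phenotype matching

ROI profiles are arithmetic means (not medians — "average intensity of the
ROI" is the convention) of the normalized feature vectors over the ROI's
cellular pixels. Distances are Pearson correlation distances `d = 1 − r` on
the full picked-peak vector; no feature selection is applied. `d` is not a
metric (no triangle inequality) and none is assumed. The implementation
uses the raw-sums form of `r`, which makes `d(x, x)` exactly 0 for every
input; it is appropriate for normalized intensity profiles, not for data
with an enormous mean-to-spread ratio.

A query is annotated with the morphology of the reference minimising `d`
(ties broken by name) and called **novel** when the best distance reaches
`threshold` = 0.25. The threshold is a heuristic chosen to separate reported
pseudoinvasion-type distances (~0.0–0.23) from reported invasion-vs-dysplasia
distances (~0.26); it is flagged as heuristic in the report output,
configurable, and the tie rule (`novel_if`: "ge"/"gt") is explicit.
`cluster_concordance` adds a second, qualitative line of evidence: the
fraction of query pixels whose cluster also occurs in a reference ROI
(≈1 for misplaced epithelium, ≈0 for a lesion forming its own cluster).

## Synthetic tissue generator

The simulator emulates the study design, not the instrument physics. A
60 × 60 grid holds a surface epithelium band split into normal / low-grade /
high-grade thirds, submucosal stroma, a deep lesion disc (~200 px) and a
4-pixel background margin. A 40-peak panel spans 900–3,300 Da at
glycan-like spacings (hexose/HexNAc/derivatized-sialic-acid increments on a
core mass); the m/z axis samples ±0.8 Da around each center at 0.1 Da, which
keeps a full section under 20 MB of imzML and makes window integrals exactly
proportional to abundances.

Region profiles are correlated log-normal abundance vectors (surface
lineages share half of their log-variance; a 0.05 abundance floor keeps
every peak detectable in the mean spectrum). The three scenario kinds encode
the hypotheses:

- `pseudoinvasion` — the lesion profile is a **bitwise copy** of one surface
  profile (default source: low-grade dysplasia);
- `true_invasion` — the lesion profile is drawn independently and redrawn
  until its Pearson distance to every surface profile is ≥ 0.5;
- `malignant_polyp` — the full stratified layout with an invasive lesion,
  used for segmentation benchmarking.

Pixel spectra are sums of σ = 0.15 Da Gaussians with per-pixel, per-peak
multiplicative log-normal noise (σ = 0.1 by default), per-pixel log-normal
overall intensity jitter (σ = 0.2, so TIC normalization is consequential —
additive Gaussian noise would not exercise it), a small additive baseline
(1% of tissue TIC) and a background whose TIC is 5% of the median tissue
TIC. The noise defaults are engineering choices: per-pixel glycan intensity
distributions for real sections are not published. Everything is a
deterministic function of the scenario seed, down to byte-identical imzML
output (the file UUID is derived from the content hash).

**What passing tests show — and don't.** The generator produces compact,
well-separated phenotype blobs with unambiguous polygonal geometry. Success
on it demonstrates that the pipeline's logic is correct and numerically
stable, not that the method resolves real histology: real sections have
gradual transitions, mixed pixels at boundaries, mass-calibration drift,
isotope envelopes and detector effects that are all out of scope here.

## Numerical guarantees (all tested)

- Normalization conservation: nonzero pixels sum to the target within 1e-9;
  a tiling panel conserves it within 1e-6.
- Pearson distance agrees with a from-definition oracle to 1e-12;
  `d(x, x) = 0` exactly; positive-affine maps give 0 exactly whenever the
  float arithmetic is exact (integer-valued data) and to ~1e-13 otherwise.
- Noise-free limit: with noise and jitter off, pipeline ROI distances equal
  the scenario's analytic profile distances to 1e-9 (the non-uniform axis
  with identical per-peak sampling makes this exact up to rounding).
- Determinism: the full `run` bundle (report JSON, PNG, manifest) is
  bitwise reproducible for a fixed config and seed; timestamps appear only
  in the log.

Test and validation problem sizes (60 × 60 sections, 20 replicates for the
recovery rates) were chosen so the full suite runs comfortably on a single
CPU while keeping every replicate a complete end-to-end pipeline run.

## Known limitations

- Modularity clustering can split very large homogeneous compartments at
  particular noise realisations (see Segmentation); the molecular annotation
  is unaffected because it uses profile distances, not cluster identity.
- The novelty threshold is heuristic and dataset-scale dependent.
- One tissue per run; cohort-level orchestration is out of scope.
- Processed-mode support goes through fixed-width binning; no recalibration
  or peak alignment across pixels is attempted.
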