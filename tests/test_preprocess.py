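import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycohisto import (
    MSIDataset,
    PeakPanel,
    build_feature_matrix,
    flag_noncellular,
    mean_spectrum,
    pearson_distance,
    pick_peaks,
    tic_normalize,
)
from glycohisto.preprocess import bin_to_common_axis
from glycohisto.phenotype import roi_mean_profile


def _one_pixel(intensities, mz=None):
    intensities = np.asarray(intensities, dtype=float)
    if mz is None:
        mz = 1000.0 + 10.0 * np.arange(len(intensities))
    return MSIDataset(coords=np.array([[0, 0]]), mz_axis=np.asarray(mz, dtype=float),
                      intensities=intensities[None, :])


# ---------------------------------------------------------------------------
# TIC normalization
# ---------------------------------------------------------------------------

def test_tic_normalize_scales_to_target():
    ds = _one_pixel([2.0, 3.0, 5.0])
    out, tic = tic_normalize(ds, target=1.0)
    np.testing.assert_allclose(out.intensities[0], [0.2, 0.3, 0.5])
    assert tic[0] == 10.0


def test_tic_normalize_zero_pixel_left_and_flagged():
    ds = _one_pixel([0.0, 0.0, 0.0])
    out, tic = tic_normalize(ds)
    np.testing.assert_array_equal(out.intensities[0], 0.0)
    assert tic[0] == 0.0  # the zero TIC is the flag carried downstream


def test_tic_normalize_rejects_nonpositive_target(tiny_dataset):
    with pytest.raises(ValueError):
        tic_normalize(tiny_dataset, target=-1.0)


def test_tic_normalize_every_nonzero_pixel_sums_to_target(pi_bundle):
    _, ds, _, _ = pi_bundle
    out, tic = tic_normalize(ds, target=1.0)
    sums = out.intensities.sum(axis=1)
    nz = tic > 0
    np.testing.assert_allclose(sums[nz], 1.0, atol=1e-9)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3),
       seed=st.integers(min_value=0, max_value=10_000))
def test_scale_equivariance_of_normalization_and_distances(scale, seed):
    """Multiplying a pixel's raw intensities by c > 0 changes nothing downstream."""
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.1, 5.0, size=8)
    a, _ = tic_normalize(_one_pixel(raw))
    b, _ = tic_normalize(_one_pixel(raw * scale))
    np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-9)
    other = rng.uniform(0.1, 5.0, size=8)
    assert pearson_distance(raw, other) == pytest.approx(
        pearson_distance(raw * scale, other), abs=1e-12
    )


# ---------------------------------------------------------------------------
# mean spectrum
# ---------------------------------------------------------------------------

def test_mean_spectrum_single_pixel_is_identity():
    ds = _one_pixel([1.0, 4.0, 2.0])
    mz, inten = mean_spectrum(ds)
    np.testing.assert_allclose(inten, [1.0, 4.0, 2.0])


def test_mean_spectrum_pointwise_average():
    ds = MSIDataset(
        coords=np.array([[0, 0], [1, 0]]),
        mz_axis=np.array([1000.0, 1010.0]),
        intensities=np.array([[0.0, 2.0], [2.0, 0.0]]),
    )
    _, inten = mean_spectrum(ds)
    np.testing.assert_allclose(inten, [1.0, 1.0])


def test_mean_spectrum_empty_mask_rejected(tiny_dataset):
    with pytest.raises(ValueError):
        mean_spectrum(tiny_dataset, mask=np.zeros(4, dtype=bool))


def test_mean_spectrum_apexes_match_simulator_panel(pi_bundle, pi_fm):
    sc, _, _, _ = pi_bundle
    ds_norm, _, _, _ = pi_fm
    mz, inten = mean_spectrum(ds_norm)
    for center in sc.panel_centers:
        block = np.abs(mz - center) <= 1.2
        apex = mz[block][np.argmax(inten[block])]
        assert abs(apex - center) <= 0.1 + 1e-9  # within one axis sample


def test_processed_mode_binning_gives_common_axis():
    spectra = [
        (np.array([1000.02, 1000.31]), np.array([1.0, 2.0])),
        (np.array([1000.07, 1000.33, 1000.38]), np.array([3.0, 1.0, 1.0])),
    ]
    ds = MSIDataset(coords=np.array([[0, 0], [1, 0]]), spectra=spectra)
    binned = bin_to_common_axis(ds, bin_width=0.1)
    assert binned.is_continuous
    # intensities falling in one bin are summed
    assert binned.intensities.sum() == pytest.approx(8.0)
    mz, inten = mean_spectrum(ds, bin_width=0.1)
    assert len(mz) == len(inten)


# ---------------------------------------------------------------------------
# peak picking
# ---------------------------------------------------------------------------

def test_flat_spectrum_has_no_peaks():
    mz = np.linspace(1000, 1010, 101)
    panel = pick_peaks((mz, np.full(101, 3.0)))
    assert len(panel) == 0


def test_three_gaussians_recovered_exactly():
    """Apexes of isolated Gaussians must equal the brute-force argmax per region."""
    mz = np.arange(1000.0, 1030.0, 0.05)
    centers, amps = [1005.0, 1015.0, 1025.0], [100.0, 50.0, 10.0]
    inten = np.zeros_like(mz)
    for c, a in zip(centers, amps):
        inten += a * np.exp(-((mz - c) ** 2) / (2 * 0.1**2))
    panel = pick_peaks((mz, inten))
    assert len(panel) == 3
    for c, picked in zip(centers, panel.center_mz):
        region = np.abs(mz - c) < 2.0
        brute_apex = mz[region][np.argmax(inten[region])]
        assert picked == brute_apex


def test_simulated_panel_recovery(pi_bundle, pi_fm):
    sc, _, _, _ = pi_bundle
    _, _, panel, _ = pi_fm
    matched = sum(
        np.min(np.abs(panel.center_mz - c)) <= 0.2 for c in sc.panel_centers
    )
    assert matched >= 38


def test_pick_peaks_rejects_nonmonotone_axis():
    with pytest.raises(ValueError):
        pick_peaks((np.array([3.0, 2.0, 1.0]), np.array([1.0, 2.0, 1.0])))


def test_overlapping_windows_truncated_at_midpoint():
    mz = np.arange(1000.0, 1002.0, 0.05)
    inten = np.exp(-((mz - 1000.5) ** 2) / (2 * 0.05**2)) + np.exp(
        -((mz - 1001.0) ** 2) / (2 * 0.05**2)
    )
    panel = pick_peaks((mz, inten), window_halfwidth_da=0.4)
    assert len(panel) == 2
    assert panel.window_high[0] <= panel.window_low[1] + 1e-12
    assert panel.window_high[0] == pytest.approx(0.5 * (panel.center_mz[0] + panel.center_mz[1]))


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def test_whole_axis_window_conserves_target():
    ds = _one_pixel([2.0, 3.0, 5.0])
    out, tic = tic_normalize(ds)
    panel = PeakPanel(ids=["all"], center_mz=[1010.0], window_low=[995.0],
                      window_high=[1025.0])
    fm = build_feature_matrix(out, panel, tic=tic)
    assert fm.values[0, 0] == pytest.approx(1.0)


def test_empty_window_gives_zero():
    ds = _one_pixel([1.0, 0.0, 1.0])
    out, tic = tic_normalize(ds)
    panel = PeakPanel(ids=["gap"], center_mz=[1010.0], window_low=[1006.0],
                      window_high=[1014.0])
    fm = build_feature_matrix(out, panel, tic=tic)
    assert fm.values[0, 0] == 0.0


def test_tiling_panel_conserves_target(pi_bundle):
    """A panel whose windows tile the axis must conserve the TIC target per pixel."""
    _, ds, _, _ = pi_bundle
    out, tic = tic_normalize(ds)
    axis = out.mz_axis
    edges = np.concatenate([[axis[0] - 1.0], 0.5 * (axis[1:] + axis[:-1]), [axis[-1] + 1.0]])
    n = 20
    cut = np.linspace(0, len(edges) - 1, n + 1).astype(int)
    panel = PeakPanel(
        ids=[f"w{i}" for i in range(n)],
        center_mz=[0.5 * (edges[cut[i]] + edges[cut[i + 1]]) for i in range(n)],
        window_low=edges[cut[:-1]],
        window_high=edges[cut[1:]],
    )
    fm = build_feature_matrix(out, panel, tic=tic)
    sums = fm.values.sum(axis=1)
    np.testing.assert_allclose(sums[tic > 0], 1.0, atol=1e-6)


def test_window_outside_range_rejected(tiny_dataset):
    out, tic = tic_normalize(tiny_dataset)
    panel = PeakPanel(ids=["bad"], center_mz=[500.0], window_low=[499.0], window_high=[501.0])
    with pytest.raises(ValueError):
        build_feature_matrix(out, panel, tic=tic)


def test_region_profiles_recovered(pi_bundle, pi_fm):
    sc, _, rois, _ = pi_bundle
    _, _, _, fm = pi_fm
    # match picked features back to simulator panel peaks
    prof = roi_mean_profile(fm, rois["surface_lg"])
    picked_centers = np.array([float(f.split("_")[1]) for f in fm.feature_ids])
    keep = [np.argmin(np.abs(picked_centers - c)) for c in sc.panel_centers]
    recovered = prof[keep]
    truth = sc.profiles["low_grade"]
    r = 1 - pearson_distance(recovered, truth)
    assert r >= 0.99


# ---------------------------------------------------------------------------
# non-cellular flagging
# ---------------------------------------------------------------------------

def _fm_with_tic(tic):
    tic = np.asarray(tic, dtype=float)
    n = len(tic)
    from glycohisto import FeatureMatrix

    return FeatureMatrix(
        coords=np.column_stack([np.arange(n), np.zeros(n, dtype=int)]),
        feature_ids=["f"],
        values=np.ones((n, 1)),
        tic=tic,
        cellular_mask=tic > 0,
        grid_shape=(n, 1),
    )


def test_flag_ties_kept_cellular():
    fm = flag_noncellular(_fm_with_tic(np.full(10, 2.0)))
    assert fm.cellular_mask.all()


def test_flag_single_zero_pixel():
    fm = flag_noncellular(_fm_with_tic([0.0] + [1.0] * 99))
    assert fm.cellular_mask.sum() == 99
    assert not fm.cellular_mask[0]


def test_flag_quantile_out_of_range():
    with pytest.raises(ValueError):
        flag_noncellular(_fm_with_tic([1.0, 2.0, 3.0]), tic_quantile=1.5)


def test_flag_background_at_quantile_matching_geometry(polyp_bundle, polyp_fm):
    """With the cutoff quantile set to the known background fraction, nearly
    all true background pixels (TIC ~5% of tissue) fall below it."""
    _, _, _, truth = polyp_bundle
    _, _, _, fm = polyp_fm
    bg_fraction = float((truth == 0).mean())
    flagged = flag_noncellular(fm, tic_quantile=bg_fraction)
    truth_pp = truth[fm.coords[:, 1], fm.coords[:, 0]]
    bg = truth_pp == 0
    assert (~flagged.cellular_mask[bg]).mean() >= 0.95
    # and almost no tissue pixels are lost
    assert flagged.cellular_mask[~bg].mean() >= 0.95
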