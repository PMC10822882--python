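import numpy as np
import pytest

from glycohisto import (
    MSIDataset,
    build_feature_matrix,
    default_scenario,
    flag_noncellular,
    mean_spectrum,
    pick_peaks,
    simulate_dataset,
    tic_normalize,
)


@pytest.fixture(scope="session")
def pi_bundle():
    """Pseudoinvasion scenario, seed 1: (scenario, dataset, rois, truth)."""
    sc = default_scenario("pseudoinvasion", seed=1)
    ds, rois, truth = simulate_dataset(sc)
    return sc, ds, rois, truth


@pytest.fixture(scope="session")
def polyp_bundle():
    """Malignant-polyp scenario, seed 1 (all strata + invasive lesion)."""
    sc = default_scenario("malignant_polyp", seed=1)
    ds, rois, truth = simulate_dataset(sc)
    return sc, ds, rois, truth


def preprocess_bundle(ds):
    """Standard preprocessing chain used across tests."""
    ds_norm, tic = tic_normalize(ds)
    panel = pick_peaks(mean_spectrum(ds_norm))
    fm = flag_noncellular(build_feature_matrix(ds_norm, panel, tic=tic))
    return ds_norm, tic, panel, fm


@pytest.fixture(scope="session")
def pi_fm(pi_bundle):
    _, ds, _, _ = pi_bundle
    return preprocess_bundle(ds)


@pytest.fixture(scope="session")
def polyp_fm(polyp_bundle):
    _, ds, _, _ = polyp_bundle
    return preprocess_bundle(ds)


@pytest.fixture()
def tiny_dataset():
    """2x2 continuous-mode dataset with a shared 5-point axis."""
    mz = np.array([1000.0, 1100.0, 1200.0, 1300.0, 1400.0])
    intensities = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
            [0.0, 1.0, 0.0, 1.0, 0.0],
            [2.0, 2.0, 2.0, 2.0, 2.0],
        ]
    )
    coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
    return MSIDataset(coords=coords, mz_axis=mz, intensities=intensities)
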