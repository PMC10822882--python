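import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycohisto import (
    FeatureMatrix,
    ROI,
    annotate_query,
    cluster_concordance,
    distance_matrix,
    pearson_distance,
    phenotype_report,
    roi_mean_profile,
)


def pearson_distance_oracle(p, q):
    """From-definition Pearson distance: explicit covariance / sigma formula."""
    p, q = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    dp, dq = p - p.mean(), q - q.mean()
    cov = float(np.sum(dp * dq)) / len(p)
    sig_p = np.sqrt(float(np.sum(dp * dp)) / len(p))
    sig_q = np.sqrt(float(np.sum(dq * dq)) / len(q))
    return 1.0 - cov / (sig_p * sig_q)


def _fm(values, tic=None, cellular=None, width=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    width = width or n
    coords = np.column_stack([np.arange(n) % width, np.arange(n) // width])
    return FeatureMatrix(
        coords=coords,
        feature_ids=[f"f{i}" for i in range(values.shape[1])],
        values=values,
        tic=np.ones(n) if tic is None else np.asarray(tic, float),
        cellular_mask=np.ones(n, dtype=bool) if cellular is None else np.asarray(cellular),
        grid_shape=(width, (n - 1) // width + 1),
    )


def _roi(name, mask_positions, shape, morphology="low_grade", role="reference"):
    mask = np.zeros(shape, dtype=bool)
    for (x, y) in mask_positions:
        mask[y, x] = True
    return ROI(name, morphology, role, mask)


# ---------------------------------------------------------------------------
# roi_mean_profile
# ---------------------------------------------------------------------------

def test_single_pixel_roi_profile_is_that_pixel():
    fm = _fm([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    roi = _roi("a", [(0, 0)], (1, 2))
    np.testing.assert_array_equal(roi_mean_profile(fm, roi), [1.0, 2.0, 3.0])


def test_roi_profile_is_arithmetic_mean():
    fm = _fm([[0.0, 2.0], [2.0, 0.0]])
    roi = _roi("a", [(0, 0), (1, 0)], (1, 2))
    np.testing.assert_array_equal(roi_mean_profile(fm, roi), [1.0, 1.0])


def test_empty_roi_error_names_the_roi():
    fm = _fm([[1.0, 2.0]], cellular=[False])
    roi = _roi("deep_lesion", [(0, 0)], (1, 1))
    with pytest.raises(ValueError, match="deep_lesion"):
        roi_mean_profile(fm, roi)


def test_simulated_roi_profile_matches_truth(pi_bundle, pi_fm):
    sc, _, rois, _ = pi_bundle
    _, _, _, fm = pi_fm
    prof = roi_mean_profile(fm, rois["surface_lg"])
    centers = np.array([float(f.split("_")[1]) for f in fm.feature_ids])
    keep = [int(np.argmin(np.abs(centers - c))) for c in sc.panel_centers]
    r = 1 - pearson_distance(prof[keep], sc.profiles["low_grade"])
    assert r >= 0.99


# ---------------------------------------------------------------------------
# pearson_distance
# ---------------------------------------------------------------------------

def test_identical_vectors_distance_zero_exactly():
    assert pearson_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


def test_anticorrelated_vectors_distance_two():
    assert pearson_distance([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(2.0)


def test_frozen_from_definition_example():
    # oracle value computed from the covariance/sigma definition: d = 1 - 4/5
    assert pearson_distance([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(0.2, abs=1e-12)


def test_agrees_with_from_definition_oracle():
    rng = np.random.default_rng(12345)
    for _ in range(300):
        n = int(rng.integers(3, 200))
        p, q = rng.normal(size=n), rng.normal(size=n)
        assert pearson_distance(p, q) == pytest.approx(
            pearson_distance_oracle(p, q), abs=1e-12
        )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    a=st.floats(min_value=0.01, max_value=100.0),
    b=st.floats(min_value=-50.0, max_value=50.0),
)
def test_affine_invariance(seed, a, b):
    rng = np.random.default_rng(seed)
    p = rng.normal(size=20)
    q = rng.normal(size=20)
    assert pearson_distance(a * p + b, q) == pytest.approx(pearson_distance(p, q), abs=1e-9)


def test_constant_or_short_vectors_rejected():
    with pytest.raises(ValueError, match="constant"):
        pearson_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="length"):
        pearson_distance([1.0, 2.0], [2.0, 1.0])


# ---------------------------------------------------------------------------
# distance matrix
# ---------------------------------------------------------------------------

def test_distance_matrix_symmetric_zero_diagonal():
    profiles = {
        "a": np.array([1.0, 2.0, 3.0, 4.0]),
        "b": np.array([1.0, 2.0, 4.0, 3.0]),
        "c": np.array([4.0, 3.0, 2.0, 1.0]),
    }
    names, D = distance_matrix(profiles)
    assert D.shape == (3, 3)
    np.testing.assert_array_equal(np.diag(D), 0.0)
    np.testing.assert_array_equal(D, D.T)
    for i, a in enumerate(names):
        for j, r in enumerate(names):
            if i != j:
                assert D[i, j] == pytest.approx(pearson_distance(profiles[a], profiles[r]))
    assert np.all(D >= 0) and np.all(D <= 2)


def test_identical_profiles_off_diagonal_zero():
    v = np.array([1.0, 5.0, 2.0])
    _, D = distance_matrix({"a": v, "b": v.copy()})
    assert D[0, 1] == 0.0


# ---------------------------------------------------------------------------
# annotate_query
# ---------------------------------------------------------------------------

def test_query_equal_to_reference_matches_it():
    lg = np.array([1.0, 3.0, 2.0, 5.0])
    profiles = {"lg_ref": lg, "hg_ref": np.array([5.0, 1.0, 3.0, 2.0]), "q": lg.copy()}
    ann = annotate_query(profiles, {"lg_ref": "low_grade", "hg_ref": "high_grade"}, "q")
    assert ann["best_reference"] == "lg_ref"
    assert ann["molecular_annotation"] == "low_grade"
    assert ann["best_distance"] == 0.0
    assert ann["novel"] is False


def test_query_far_from_all_references_is_novel():
    profiles = {
        "r1": np.array([1.0, 2.0, 3.0, 4.0]),
        "r2": np.array([2.0, 4.0, 6.0, 8.0]),
        "q": np.array([4.0, 3.0, 2.0, 1.0]),  # d = 2 to both
    }
    ann = annotate_query(profiles, {"r1": "normal", "r2": "low_grade"}, "q")
    assert ann["novel"] is True
    assert ann["best_distance"] >= 1.0


def test_tie_broken_by_reference_name():
    v = np.array([1.0, 2.0, 3.0])
    profiles = {"b_ref": v.copy(), "a_ref": v.copy(), "q": v.copy()}
    ann = annotate_query(profiles, {"b_ref": "normal", "a_ref": "low_grade"}, "q")
    assert ann["best_reference"] == "a_ref"


def test_threshold_tie_rule_configurable():
    profiles = {"r": np.array([1.0, 2.0, 3.0, 4.0]), "q": np.array([1.0, 2.0, 4.0, 3.0])}
    refs = {"r": "low_grade"}
    d = pearson_distance(profiles["q"], profiles["r"])  # 0.2
    ge = annotate_query(profiles, refs, "q", threshold=d, novel_if="ge")
    gt = annotate_query(profiles, refs, "q", threshold=d, novel_if="gt")
    assert ge["novel"] is True and gt["novel"] is False


def test_no_references_rejected():
    with pytest.raises(ValueError):
        annotate_query({"q": np.array([1.0, 2.0, 3.0])}, {}, "q")


# ---------------------------------------------------------------------------
# cluster concordance
# ---------------------------------------------------------------------------

def test_concordance_shared_and_disjoint_clusters():
    fm = _fm(np.ones((4, 2)), width=2)
    q = _roi("q", [(0, 0), (1, 0)], (2, 2), role="query")
    r = _roi("r", [(0, 1), (1, 1)], (2, 2))
    shared = np.array([0, 0, 0, 0])
    disjoint = np.array([0, 0, 1, 1])
    assert cluster_concordance(fm, shared, q, r) == 1.0
    assert cluster_concordance(fm, disjoint, q, r) == 0.0


def test_pseudoinvasion_concordant_with_source_morphology(pi_bundle, pi_fm):
    _, _, rois, _ = pi_bundle
    _, _, _, fm = pi_fm
    from glycohisto import cluster

    labels = cluster(fm, seed=42)
    conc = cluster_concordance(fm, labels, rois["deep_lesion"], rois["surface_lg"])
    assert conc >= 0.8


def test_phenotype_report_end_to_end(pi_bundle, pi_fm):
    sc, _, rois, _ = pi_bundle
    _, _, _, fm = pi_fm
    rep = phenotype_report(fm, rois)
    assert set(rep.roi_names) == {r.name for r in rois}
    np.testing.assert_array_equal(rep.distances, rep.distances.T)
    ann = rep.annotations["deep_lesion"]
    assert ann["molecular_annotation"] == "low_grade"
    assert ann["best_distance"] < 0.1
    assert ann["novel"] is False
    # d(PI, LG source) below d(PI, any other reference)
    d_src = rep.distance("deep_lesion", "surface_lg")
    for other in ("surface_normal", "surface_hg", "submucosa"):
        assert d_src < rep.distance("deep_lesion", other)
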