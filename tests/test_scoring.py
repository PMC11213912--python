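"""Saliency geometry, score arithmetic, aggregation, and calibration."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from histotils import synthetic as syn
from histotils.scoring import (
    RoiCounts,
    ScoreCalibrator,
    aggregate,
    calibrate,
    calibration_report,
    pool_counts,
    roi_counts,
    saliency,
    score_variants,
    slide_score_table,
)
from histotils.taxonomy import build_default_taxonomy

from conftest import oracle_prediction, toy_roi_params


def brute_force_saliency(region_map, mpp, dist_microns, taxonomy):
    """All-pairs nearest-tumor-distance oracle via a KD-tree."""
    tumor = np.argwhere(np.isin(region_map, taxonomy.region_codes_in_group("epithelium")))
    stroma = np.argwhere(np.isin(region_map, taxonomy.region_codes_in_group("stroma")))
    if len(tumor) == 0 or len(stroma) == 0:
        return 0.0
    d, _ = cKDTree(tumor).query(stroma)
    d = d * mpp
    return float(((d > 0) & (d <= dist_microns)).sum() / region_map.size)


def test_saliency_half_plane_quarter(taxonomy):
    region = np.full((256, 256), taxonomy.region_code("stroma"), dtype=int)
    region[:, :128] = taxonomy.region_code("cancer")
    val = saliency(region, mpp=0.5)
    assert val == pytest.approx(0.25)
    assert val == pytest.approx(
        brute_force_saliency(region, 0.5, 32.0, taxonomy)
    )


def test_saliency_boundary_cases(taxonomy):
    stroma_only = np.full((32, 32), taxonomy.region_code("stroma"), dtype=int)
    assert saliency(stroma_only, 0.5) == 0.0
    tumor_only = np.full((32, 32), taxonomy.region_code("cancer"), dtype=int)
    assert saliency(tumor_only, 0.5) == 0.0


def test_saliency_matches_brute_force_on_random_blobs(taxonomy):
    rng = np.random.default_rng(0)
    region = np.full((64, 64), taxonomy.region_code("stroma"), dtype=int)
    yy, xx = np.mgrid[0:64, 0:64]
    for _ in range(3):
        cy, cx, r = rng.uniform(10, 54, 2).tolist() + [rng.uniform(5, 12)]
        region[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = taxonomy.region_code("cancer")
    for mpp in (0.5, 1.0):
        assert saliency(region, mpp) == pytest.approx(
            brute_force_saliency(region, mpp, 32.0, taxonomy), abs=1e-9
        )


# --- counting ----------------------------------------------------------------

class _FakeInstance:
    def __init__(self, class_code, region_code):
        self.class_code = class_code
        self.region_code = region_code


class _FakePrediction:
    def __init__(self, instances, region_map, mpp=0.5):
        self.instances = instances
        self._region_map = region_map
        self.mpp = mpp

    @property
    def region_map(self):
        return self._region_map


def test_roi_counts_worked_example(taxonomy):
    stroma = taxonomy.region_code("stroma")
    cancer_r = taxonomy.region_code("cancer")
    lymph = taxonomy.nucleus_code("lymphocyte")
    fib = taxonomy.nucleus_code("fibroblast")
    cancer_n = taxonomy.nucleus_code("cancer")
    instances = (
        [_FakeInstance(lymph, stroma)] * 10
        + [_FakeInstance(fib, stroma)] * 10
        + [_FakeInstance(cancer_n, cancer_r)] * 20
    )
    region = np.full((100, 100), stroma, dtype=int)
    region[:50] = cancer_r
    c = roi_counts(_FakePrediction(instances, region), mpp=1.0)
    assert (c.n_til_stroma, c.n_cells_stroma, c.n_cells_total) == (10, 20, 40)
    assert c.stromal_area_mm2 == pytest.approx(5000 * 1e-6)
    scores = score_variants(c)
    assert scores["nTnS"] == pytest.approx(0.5)
    assert scores["nTnA"] == pytest.approx(0.25)
    assert scores["nTSa"] == pytest.approx(10 / 0.005)


def test_roi_counts_excludes_debris(taxonomy):
    stroma = taxonomy.region_code("stroma")
    debris = taxonomy.nucleus_code("debris")
    lymph = taxonomy.nucleus_code("lymphocyte")
    instances = [_FakeInstance(debris, stroma), _FakeInstance(lymph, stroma)]
    region = np.full((10, 10), stroma, dtype=int)
    c = roi_counts(_FakePrediction(instances, region), mpp=0.5)
    assert (c.n_til_stroma, c.n_cells_stroma, c.n_cells_total) == (1, 1, 1)


def test_roi_counts_empty_prediction(taxonomy):
    region = np.full((8, 8), taxonomy.region_code("empty"), dtype=int)
    c = roi_counts(_FakePrediction([], region), mpp=0.5)
    assert (c.n_til_stroma, c.n_cells_stroma, c.n_cells_total) == (0, 0, 0)
    assert c.stromal_area_mm2 == 0.0


def test_roi_counts_match_generator_truth(taxonomy):
    sample = syn.generate_roi(toy_roi_params(12), render_rgb=False)
    pred = oracle_prediction(sample, taxonomy)
    c = roi_counts(pred)
    truth = sample.truth_table()
    live = truth[truth["class"] != taxonomy.nucleus_code("debris")]
    stromal = live[live.region.isin(taxonomy.region_codes_in_group("stroma"))]
    assert c.n_cells_total == len(live)
    assert c.n_cells_stroma == len(stromal)
    assert c.n_til_stroma == stromal["class"].isin(
        taxonomy.nucleus_codes_in_group("TILs")
    ).sum()


def test_score_variants_zero_denominators():
    c = RoiCounts(0, 0, 0, 0.0)
    s = score_variants(c)
    assert all(np.isnan(v) for v in s.values())


def test_counts_invariant_enforced():
    with pytest.raises(ValueError):
        RoiCounts(5, 3, 10, 1.0)


# --- aggregation -------------------------------------------------------------

def _counts(n_til, n_str, n_tot, area, sal):
    return RoiCounts(n_til, n_str, n_tot, area, sal)


def test_aggregate_identical_rois_agree_across_modes():
    c = _counts(5, 10, 20, 0.01, 0.4)
    rois = [c] * 4
    g = aggregate(rois, "global")
    w = aggregate(rois, "saliency_weighted")
    for v in g:
        assert g[v] == pytest.approx(w[v])


def test_aggregate_weighted_example():
    rois = [_counts(2, 10, 10, 0.001, 1.0), _counts(6, 10, 10, 0.001, 3.0)]
    w = aggregate(rois, "saliency_weighted")
    assert w["nTnS"] == pytest.approx((1 * 0.2 + 3 * 0.6) / 4)


def test_aggregate_matches_bruteforce_weighted_mean():
    rng = np.random.default_rng(3)
    rois = [
        _counts(int(t), int(t + s), int(t + s + 5), 0.002 + rng.random() * 0.01,
                float(rng.random()))
        for t, s in rng.integers(1, 30, size=(20, 2))
    ]
    w = aggregate(rois, "saliency_weighted")
    scores = [score_variants(c) for c in rois]
    weights = np.array([c.saliency for c in rois])
    for v in ("nTSa", "nTnS", "nTnA"):
        s = np.array([x[v] for x in scores])
        assert w[v] == pytest.approx((weights * s).sum() / weights.sum(), abs=1e-9)


def test_aggregate_order_invariance():
    rng = np.random.default_rng(4)
    rois = [
        _counts(i, i + 3, i + 8, 0.001 * (i + 1), float(rng.random()))
        for i in range(10)
    ]
    shuffled = [rois[i] for i in rng.permutation(10)]
    for mode in ("global", "saliency_weighted"):
        a, b = aggregate(rois, mode), aggregate(shuffled, mode)
        for v in a:
            assert a[v] == pytest.approx(b[v], abs=1e-12)


def test_monotone_in_til_count():
    base = _counts(5, 20, 40, 0.01, 0.5)
    more = _counts(6, 20, 40, 0.01, 0.5)
    s0, s1 = score_variants(base), score_variants(more)
    for v in s0:
        assert s1[v] > s0[v]


def test_ntna_dominated_by_ntns():
    c = _counts(7, 15, 40, 0.01, 0.2)
    s = score_variants(c)
    assert s["nTnA"] <= s["nTnS"]


def test_aggregate_zero_weights_falls_back(caplog):
    rois = [_counts(1, 5, 10, 0.001, 0.0), _counts(3, 5, 10, 0.001, 0.0)]
    w = aggregate(rois, "saliency_weighted")
    assert w["nTnS"] == pytest.approx((0.2 + 0.6) / 2)


def test_pool_counts_sums():
    pooled = pool_counts([_counts(1, 2, 3, 0.1, 0.5), _counts(4, 5, 6, 0.2, 0.1)])
    assert (pooled.n_til_stroma, pooled.n_cells_stroma, pooled.n_cells_total) == (5, 7, 9)
    assert pooled.stromal_area_mm2 == pytest.approx(0.3)


def test_slide_score_table_layout():
    rois = [_counts(2, 10, 20, 0.005, 0.3)] * 3
    df = slide_score_table(rois, slide_id="s1", calibration_scales={"nTnS": 2.0})
    assert df.loc[0, "slide_id"] == "s1"
    assert df.loc[0, "n_rois"] == 3
    assert df.loc[0, "nTnS_global_calibrated"] == pytest.approx(0.4)


# --- calibration -------------------------------------------------------------

def test_calibrate_exact_scale():
    comp = np.linspace(0.1, 0.6, 12)
    res = calibrate(comp, 2.0 * comp)
    assert res.scale == pytest.approx(2.0)
    assert res.inlier_mask.all()
    np.testing.assert_allclose(res.calibrated, 2.0 * comp)
    assert calibrate(comp, comp).scale == pytest.approx(1.0)


def test_calibrate_validations():
    with pytest.raises(ValueError):
        calibrate([1, 2], [1, 2])
    with pytest.raises(ValueError):
        calibrate([1.0] * 5, [1, 2, 3, 4, 5])


def test_calibrate_recovers_cohort_scale():
    rng = np.random.default_rng(8)
    true = rng.uniform(0.02, 0.6, 50)
    df = syn.generate_cohort(50, true, visual_noise_sd=0.02, scale=1.8,
                             n_outliers=3, seed=8)
    res = calibrate(df.computational_score, df.visual_score)
    assert (~res.inlier_mask).sum() == 3
    np.testing.assert_array_equal(
        np.flatnonzero(~res.inlier_mask),
        np.flatnonzero(df.is_injected_outlier.values),
    )
    assert res.scale == pytest.approx(1.8, abs=0.05)


def test_calibrate_scale_converges_as_noise_vanishes():
    rng = np.random.default_rng(9)
    true = rng.uniform(0.05, 0.5, 30)
    df = syn.generate_cohort(30, true, visual_noise_sd=0.0, scale=1.8,
                             n_outliers=0, seed=9)
    res = calibrate(df.computational_score, df.visual_score)
    assert res.scale == pytest.approx(1.8, abs=1e-12)


def test_outliers_kept_in_calibrated_output():
    rng = np.random.default_rng(10)
    true = rng.uniform(0.02, 0.6, 40)
    df = syn.generate_cohort(40, true, visual_noise_sd=0.01, scale=1.5,
                             n_outliers=2, seed=10)
    report, k = calibration_report(df.computational_score, df.visual_score,
                                   df.slide_id)
    assert len(report) == 40  # outliers calibrated too, just not fit on
    assert report.inlier.sum() == 38
    np.testing.assert_allclose(report.calibrated, k * report.computational)


def test_calibrator_estimator_api():
    comp = np.linspace(0.1, 0.5, 10)
    cal = ScoreCalibrator().fit(comp, 3.0 * comp)
    assert cal.scale_ == pytest.approx(3.0)
    np.testing.assert_allclose(cal.transform([0.2]), [0.6])
    assert cal.get_params() == {"z_threshold": 1.96}
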