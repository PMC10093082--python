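import numpy as np
import pytest

import mitopotential as mp
from mitopotential.segmentation import (LabelMap, SegmentationParams, define_measurement_regions,
                                        match_centroids, measure_object_intensities,
                                        segment_nuclei)


def _spot_image(centers, sigma=4.0, amp=900.0, bg=20.0, shape=(128, 128)):
    from mitopotential.synth import _add_gaussian_spot
    img = np.full(shape, bg, dtype=np.float32)
    for r, c in centers:
        _add_gaussian_spot(img, r, c, sigma, amp)
    return img


def test_constant_image_yields_no_objects():
    assert segment_nuclei(np.zeros((128, 128))).n_objects == 0
    assert segment_nuclei(np.full((64, 64), 42.0)).n_objects == 0


def test_detects_all_nuclei_with_accurate_centroids(monolayer_set):
    pset, gt = monolayer_set
    lm = segment_nuclei(pset.get("B02", 0, "hoechst", 0))
    assert lm.n_objects == 20
    matched, _, _, f1 = match_centroids(lm.centroids(), gt.nuclei_centers, max_dist=2.0)
    assert matched == 20 and f1 == 1.0


def test_touching_nuclei_split_by_watershed():
    img = _spot_image([(60, 54), (60, 66)])  # 12 px apart: one fused blob
    fused = segment_nuclei(img, SegmentationParams(split_touching=False, exclude_border=False))
    split = segment_nuclei(img, SegmentationParams(split_touching=True, exclude_border=False))
    assert fused.n_objects == 1
    assert split.n_objects == 2


def test_min_area_filter_and_border_exclusion():
    img = _spot_image([(5, 64), (64, 64)])
    lm = segment_nuclei(img, SegmentationParams(exclude_border=True))
    assert lm.n_objects == 1  # border-touching nucleus removed
    lm2 = segment_nuclei(img, SegmentationParams(exclude_border=True, min_area_px=10_000))
    assert lm2.n_objects == 0


def test_cell_region_growth_matches_analytic_disc(disc_label):
    lm, _ = disc_label
    regions = define_measurement_regions(lm, r_cell=5, r_gap=2, r_ring=5)
    area = (regions.cell_labels == 1).sum()
    expected = np.pi * 20 ** 2
    assert abs(area - expected) / expected < 0.10


def test_rings_exclude_all_cell_regions(monolayer_set):
    pset, _ = monolayer_set
    lm = segment_nuclei(pset.get("B02", 0, "hoechst", 0))
    regions = define_measurement_regions(lm, 8, 2, 5)
    any_cell = regions.cell_labels > 0
    for ring in regions.ring_masks.values():
        assert not (ring & any_cell).any()


def test_neighbouring_cell_regions_partition_midline():
    img = _spot_image([(64, 54), (64, 66)], sigma=3.0)
    lm = segment_nuclei(img, SegmentationParams(exclude_border=False))
    regions = define_measurement_regions(lm, r_cell=10, r_gap=2, r_ring=4)
    # both objects keep a region and the regions are disjoint by construction
    assert (regions.cell_labels == 1).any() and (regions.cell_labels == 2).any()
    # pixels on the midline belong to their nearest nucleus
    cl = regions.cell_labels
    assert cl.max() == 2 and not ((cl == 1) & (cl == 2)).any()


def test_empty_label_map_gives_empty_regions():
    lm = LabelMap(np.zeros((32, 32), dtype=np.int32), 0)
    regions = define_measurement_regions(lm)
    assert regions.n_objects == 0 and regions.ring_masks == {}


def test_uniform_image_corrected_is_exactly_zero(disc_label):
    lm, _ = disc_label
    regions = define_measurement_regions(lm, 5, 2, 5)
    table = measure_object_intensities(regions, np.full((64, 64), 77.0), 0)
    assert (table["corrected_intensity"] == 0.0).all()


def test_corrected_invariant_to_constant_offset(monolayer_set):
    pset, _ = monolayer_set
    hoechst = pset.get("B02", 0, "hoechst", 0)
    tmrm = pset.get("B02", 0, "tmrm", 0)
    lm = segment_nuclei(hoechst)
    regions = define_measurement_regions(lm)
    t0 = measure_object_intensities(regions, tmrm, 0)
    t1 = measure_object_intensities(regions, tmrm + 1234.5, 0)
    np.testing.assert_allclose(t0["corrected_intensity"], t1["corrected_intensity"], atol=1e-3)


def test_ring_mean_estimates_background(monolayer_set):
    pset, gt = monolayer_set
    lm = segment_nuclei(pset.get("B02", 0, "hoechst", 0))
    regions = define_measurement_regions(lm)
    table = measure_object_intensities(regions, pset.get("B02", 0, "tmrm", 0), 0)
    bg = gt.latents["background_level"]
    np.testing.assert_allclose(table["ring_mean_intensity"], bg, rtol=0.10)


def test_relabeling_permutes_rows_only(disc_label):
    lm, img = disc_label
    regions = define_measurement_regions(lm, 5, 2, 5)
    t1 = measure_object_intensities(regions, img, 0)
    relabeled = LabelMap(np.where(lm.labels == 1, 1, 0).astype(np.int32), 1)
    regions2 = define_measurement_regions(relabeled, 5, 2, 5)
    t2 = measure_object_intensities(regions2, img, 0)
    num_cols = ["roi_mean_intensity", "ring_mean_intensity", "corrected_intensity",
                "object_area_px", "centroid_row", "centroid_col"]
    np.testing.assert_allclose(t1[num_cols].to_numpy(dtype=float),
                               t2[num_cols].to_numpy(dtype=float))


def test_shape_mismatch_rejected(disc_label):
    lm, _ = disc_label
    regions = define_measurement_regions(lm)
    with pytest.raises(ValueError, match="shape"):
        measure_object_intensities(regions, np.zeros((32, 32)), 0)
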