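import numpy as np
import pytest

import mitopotential as mp


# ---------------------------------------------------------------- monolayer

def test_monolayer_blank_when_zero_cells():
    pset, gt = mp.generate_monolayer_timelapse(n_cells=0, noise_cv=0, read_noise_sd=0, seed=1)
    assert len(gt.objects) == 0
    img = pset.get("B02", 0, "hoechst", 0)
    assert np.ptp(img) == 0  # background only


def test_monolayer_latent_kinetics_exact_without_noise():
    """Noise-free TMRM pixels take exactly background or background + basal*factor."""
    pset, gt = mp.generate_monolayer_timelapse(
        n_cells=10, basal_mean=400, background_level=100, f_o=1.3, f_f=0.4,
        noise_cv=0, read_noise_sd=0, seed=7)
    for tp, fac in [(0, 1.0), (1, 1.3), (2, 0.4)]:
        vals = np.unique(pset.get("B02", 0, "tmrm", tp))
        np.testing.assert_allclose(sorted(vals), [100.0, 100.0 + 400 * fac], rtol=1e-6)
    assert (gt.objects["f_o"] == 1.3).all() and (gt.objects["f_f"] == 0.4).all()


def test_monolayer_determinism():
    a, _ = mp.generate_monolayer_timelapse(n_cells=15, seed=42)
    b, _ = mp.generate_monolayer_timelapse(n_cells=15, seed=42)
    for key in a.grid_keys():
        np.testing.assert_array_equal(a.images[key], b.images[key])


def test_monolayer_density_cap():
    with pytest.raises(ValueError, match="density cap"):
        mp.generate_monolayer_timelapse(n_cells=500, shape=(128, 128), seed=0)


def test_invalid_kinetic_factors_rejected():
    with pytest.raises(ValueError):
        mp.generate_monolayer_timelapse(n_cells=1, f_o=0.0, seed=0)


# ---------------------------------------------------------------- aggregation

def test_aggregation_singles_only():
    pset, gt = mp.generate_aggregation_field({"single": 10}, planes=1, seed=2)
    assert len(gt.objects) == 10
    assert (gt.objects["object_class"] == "single").all()


def test_aggregation_class_area_ordering(aggregation_set):
    _, gt = aggregation_set
    assert len(gt.objects) == 11
    order = ["single", "grouped", "aggregate", "spheroid"]
    med = {c: gt.objects.query("object_class == @c")["projected_area_px"].median()
           for c in order}
    areas = [med[c] for c in order]
    assert areas == sorted(areas)
    # realized class ranges are disjoint
    for lo_cls, hi_cls in zip(order[:-1], order[1:]):
        assert (gt.objects.query("object_class == @lo_cls")["projected_area_px"].max()
                < gt.objects.query("object_class == @hi_cls")["projected_area_px"].min())


def test_spheroid_area_matches_analytic_disc():
    pset, gt = mp.generate_aggregation_field(
        {"spheroid": 1}, area_params={"spheroid": {"diameter": (40, 40)}}, planes=1, seed=3)
    area = gt.objects["projected_area_px"].iloc[0]
    assert abs(area - np.pi * 20 ** 2) / (np.pi * 20 ** 2) < 0.10


def test_aggregation_overlapping_ranges_rejected():
    with pytest.raises(ValueError, match="overlap"):
        mp.generate_aggregation_field(
            {"single": 1, "grouped": 1},
            area_params={"single": {"n_nuclei": (1, 2)}, "grouped": {"n_nuclei": (2, 3)}},
            seed=0)


def test_aggregation_zstack_blur_increases_offfocus():
    pset, gt = mp.generate_aggregation_field({"single": 3}, planes=5, seed=4, noise_cv=0)
    fp = int(gt.objects["focus_plane"].iloc[0])
    r, c = gt.objects[["row", "col"]].iloc[0]
    peak_by_plane = [pset.get("B02", 0, "hoechst", 0, z)[int(r) - 2:int(r) + 3,
                                                        int(c) - 2:int(c) + 3].max()
                     for z in range(5)]
    assert np.argmax(peak_by_plane) == fp


# ---------------------------------------------------------------- fibers

def test_fiber_debris_only():
    pset, gt = mp.generate_fiber_stack(n_fibers=0, n_debris=5, seed=1)
    assert (~gt.fibers["is_fiber"]).sum() == 5
    assert gt.fibers["is_fiber"].sum() == 0


def test_fiber_geometry_recorded(fiber_set):
    _, gt = fiber_set
    fibers = gt.fibers[gt.fibers["is_fiber"]]
    assert len(fibers) == 3
    np.testing.assert_allclose(fibers["length_px"] / fibers["width_px"], 300 / 24)


def test_fiber_illumination_dome_amplitude():
    pset, gt = mp.generate_fiber_stack(n_fibers=0, n_debris=0, seed=0, noise_cv=0,
                                       illumination_amplitude=200, background=1000)
    img = pset.get("B02", 0, "brightfield", 0, 0)
    center = img[250:262, 250:262].mean()
    corner = img[:8, :8].mean()
    assert abs((center - corner) - 200) < 12


# ---------------------------------------------------------------- feature tables

def test_feature_table_shift_zero_not_linearly_separable():
    from sklearn.linear_model import LogisticRegression
    table, labels = mp.generate_feature_table(1000, class_shift=0.0, seed=3)
    X = table.drop(columns="object_id").to_numpy()
    y = (labels == "A").astype(int)
    clf = LogisticRegression(max_iter=500).fit(X[:1500], y[:1500])
    acc = clf.score(X[1500:], y[1500:])
    assert 0.40 < acc < 0.60


def test_feature_table_shift_two_linear_baseline():
    """Independent linear oracle: the declared class shift is separable."""
    from sklearn.linear_model import LogisticRegression
    table, labels = mp.generate_feature_table(5000, class_shift=2.0, noise_sd=1.0, seed=1)
    X = table.drop(columns="object_id").to_numpy()
    y = (labels == "A").astype(int)
    clf = LogisticRegression(max_iter=500).fit(X[:8000], y[:8000])
    assert clf.score(X[8000:], y[8000:]) > 0.90


def test_feature_table_determinism_and_contract():
    a, la = mp.generate_feature_table(100, seed=9)
    b, lb = mp.generate_feature_table(100, seed=9)
    assert a.equals(b) and (la == lb).all()
    with pytest.raises(ValueError, match="n_features"):
        mp.generate_feature_table(10, n_features=4)


# ---------------------------------------------------------------- DNA content

def test_dna_content_fraction_recovery_by_labels():
    vals, gt = mp.generate_dna_content(10000, 0.6, 0.1, 0.3, cv=0.05, seed=11)
    emp = gt.objects["phase"].value_counts(normalize=True)
    assert abs(emp["G0/G1"] - 0.6) < 0.02
    assert abs(emp["S"] - 0.1) < 0.02
    assert abs(emp["G2/M"] - 0.3) < 0.02


def test_dna_content_noise_free_support():
    vals, gt = mp.generate_dna_content(2000, 0.5, 0.2, 0.3, cv=0.0, seed=2, g1_mode=100.0)
    ph = gt.objects["phase"].to_numpy()
    assert np.all(vals[ph == "G0/G1"] == 100.0)
    assert np.all(vals[ph == "G2/M"] == 200.0)
    s = vals[ph == "S"]
    assert s.min() >= 100.0 and s.max() <= 200.0


def test_dna_content_validates_fractions():
    with pytest.raises(ValueError):
        mp.generate_dna_content(100, 0.5, 0.2, 0.2)
    with pytest.raises(ValueError):
        mp.generate_dna_content(100, 1.2, -0.2, 0.0)
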