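import numpy as np
import pytest

import mitopotential as mp
from mitopotential.fibers import (FiberDetectParams, FiberFilterParams, basic_flatfield,
                                  detect_fiber_candidates, filter_true_fibers,
                                  measure_fiber_tmrm, sliding_parabola)


def _dome(shape=(256, 256), amp=200.0, bg=1000.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    d2 = (rr - shape[0] / 2) ** 2 + (cc - shape[1] / 2) ** 2
    return bg + amp * (1 - d2 / d2.max())


# ---------------------------------------------------------------- flatfield

def test_flatfield_uniform_unchanged():
    img = np.full((64, 64), 500.0)
    np.testing.assert_allclose(basic_flatfield(img), img, rtol=1e-6)


def test_flatfield_removes_illumination_gradient():
    img = _dome()
    out = basic_flatfield(img)
    residual = out[128, 128] - out[4, 4]
    assert abs(residual) < 20  # 200-unit dome flattened 10x


def test_flatfield_nearly_idempotent():
    img = _dome()
    once = basic_flatfield(img)
    twice = basic_flatfield(once)
    np.testing.assert_allclose(twice, once, rtol=0.01)


def test_flatfield_zero_mean_rejected():
    with pytest.raises(ValueError, match="zero-mean"):
        basic_flatfield(np.zeros((32, 32)))


# ---------------------------------------------------------------- sliding parabola

def test_parabola_constant_image_maps_to_zero():
    out = sliding_parabola(np.full((64, 64), 321.0))
    np.testing.assert_array_equal(out, 0.0)


def test_parabola_output_bounded_by_input():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 100, (96, 96))
    out = sliding_parabola(img)
    assert (out <= img + 1e-9).all() and (out >= 0).all()


def test_parabola_preserves_ridge_removes_dome():
    """Narrow bright ridge survives within 5%; smooth dome suppressed below 5%."""
    dome = _dome(amp=200.0, bg=0.0)
    img = dome.copy()
    img[:, 126:131] += 300.0  # 5 px wide ridge
    out = sliding_parabola(img)
    ridge_height = out[:, 128].mean() - out[:, 100].mean()
    assert abs(ridge_height - 300.0) / 300.0 < 0.05
    off_ridge = out[:, :100]
    assert off_ridge.max() < 0.05 * 200.0


def test_parabola_invariant_to_constant_offset():
    rng = np.random.default_rng(1)
    img = rng.uniform(10, 50, (64, 64))
    np.testing.assert_allclose(sliding_parabola(img + 500.0), sliding_parabola(img), atol=1e-6)


def test_parabola_requires_positive_curvature():
    with pytest.raises(ValueError):
        sliding_parabola(np.zeros((8, 8)), curvature=0.0)


# ---------------------------------------------------------------- detection

def test_blank_stack_gives_no_candidates():
    stack = np.full((2, 128, 128), 1000.0)
    assert detect_fiber_candidates(stack).n_objects == 0


def test_empty_stack_rejected():
    with pytest.raises(ValueError, match="empty"):
        detect_fiber_candidates(np.empty((0, 64, 64)))


def test_each_true_fiber_overlapped_by_one_candidate(fiber_set, fiber_candidates):
    pset, gt = fiber_set
    candidates, _ = fiber_candidates
    assert candidates.n_objects >= 3
    # render each ground-truth fiber mask and check IoU with its best candidate
    H, W = candidates.labels.shape
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    hits = []
    for _, f in gt.fibers[gt.fibers["is_fiber"]].iterrows():
        dr = (f.r1 - f.r0) / f.length_px
        dc = (f.c1 - f.c0) / f.length_px
        u = (rr - f.row) * dr + (cc - f.col) * dc
        v = -(rr - f.row) * dc + (cc - f.col) * dr
        truth = (np.abs(u) <= f.length_px / 2) & (np.abs(v) <= f.width_px / 2)
        best_iou, best_lab = 0.0, 0
        for lab in range(1, candidates.n_objects + 1):
            cand = candidates.labels == lab
            iou = (truth & cand).sum() / (truth | cand).sum()
            if iou > best_iou:
                best_iou, best_lab = iou, lab
        hits.append((best_lab, best_iou))
    assert all(iou >= 0.5 for _, iou in hits)
    assert len({lab for lab, _ in hits}) == 3  # one candidate per fiber


def test_fiber_in_single_plane_still_detected():
    """Union across planes recovers a fiber sharp in only one plane."""
    pset, gt = mp.generate_fiber_stack(n_fibers=1, n_debris=0, planes=4, seed=9)
    stack = pset.stack("B02", 0, "brightfield", 0)
    candidates = detect_fiber_candidates(stack)
    assert candidates.n_objects >= 1
    assert max(np.bincount(candidates.labels.ravel())[1:]) > 3000


# ---------------------------------------------------------------- gates

def test_exact_fiber_count_with_debris(fiber_candidates):
    candidates, flat = fiber_candidates
    records = filter_true_fibers(candidates, flat)
    assert sum(f.is_true_fiber for f in records) == 3
    for f in records:
        if not f.is_true_fiber:
            assert f.aspect_ratio < 5 or f.striation_score < 0.2


def test_round_debris_rejected_by_aspect_gate(fiber_candidates):
    candidates, flat = fiber_candidates
    records = filter_true_fibers(candidates, flat,
                                 FiberFilterParams(gate_area=False, gate_striation=False))
    for f in records:
        assert f.is_true_fiber == (f.aspect_ratio >= 5)


def test_striation_score_separates_striated_from_smooth():
    striated, _ = mp.generate_fiber_stack(n_fibers=1, n_debris=0, seed=4,
                                          striation_period_px=12.0)
    smooth, _ = mp.generate_fiber_stack(n_fibers=1, n_debris=0, seed=4,
                                        striation_period_px=1e9)
    def top_score(pset):
        stack = pset.stack("B02", 0, "brightfield", 0)
        cands = detect_fiber_candidates(stack)
        flat = np.max([sliding_parabola(basic_flatfield(p)) for p in stack], axis=0)
        recs = filter_true_fibers(cands, flat, FiberFilterParams(gate_striation=False))
        return max(f.striation_score for f in recs if f.aspect_ratio >= 5)
    assert top_score(striated) > top_score(smooth) + 0.2


def test_disabling_all_gates_returns_everything(fiber_candidates):
    candidates, flat = fiber_candidates
    records = filter_true_fibers(candidates, flat, FiberFilterParams(
        gate_area=False, gate_aspect=False, gate_striation=False))
    assert all(f.is_true_fiber for f in records)
    assert len(records) == candidates.n_objects


# ---------------------------------------------------------------- photometry

def test_uniform_tmrm_gives_zero_corrected(fiber_candidates):
    candidates, flat = fiber_candidates
    records = filter_true_fibers(candidates, flat)
    table = measure_fiber_tmrm(records, {0: np.full(flat.shape, 99.0)})
    assert (table["corrected_intensity"] == 0).all()


def test_fiber_corrected_matches_latent_signal(fiber_set, fiber_candidates):
    pset, gt = fiber_set
    candidates, flat = fiber_candidates
    records = filter_true_fibers(candidates, flat)
    tmrm = {0: pset.stack("B02", 0, "tmrm", 0).max(axis=0)}
    table = measure_fiber_tmrm(records, tmrm)
    latent = gt.latents["tmrm_signal"]
    np.testing.assert_allclose(table["corrected_intensity"], latent, rtol=0.10)


def test_fiber_kinetic_ratio_recovery(fiber_set):
    from mitopotential.pipeline import workflow_fibers
    pset, gt = fiber_set
    res = workflow_fibers(pset)
    s = res["summaries"][0]
    assert abs(s.oligo_ratio - gt.latents["f_o"]) / gt.latents["f_o"] < 0.10
    assert abs(s.fccp_ratio - gt.latents["f_f"]) / gt.latents["f_f"] < 0.10
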