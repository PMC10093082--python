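"""Per-nucleus Hoechst feature vectors for marker-free population separation.

For every segmented nucleus a fixed, versioned vector of 28 features is
computed on the Hoechst channel: morphology (area, perimeter,
roundness 4πA/P², axial ratio, solidity), intensity statistics on
background-subtracted values (mean, SD, quantiles, integrated), GLCM
texture (contrast, correlation, entropy, homogeneity at pixel offsets
1/2/4 averaged over four directions, on 32-level quantised
object-masked patches), a radial symmetry measure (normalised L1
difference between the patch and its 180° rotation about the
centroid), and threshold compactness (fraction of pixels above
k·median for k = 1.2, 1.5).
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix
from skimage.measure import regionprops

from .segmentation import LabelMap

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
GLCM_OFFSETS = (1, 2, 4)
GLCM_LEVELS = 32
COMPACTNESS_K = (1.2, 1.5)

FEATURE_COLUMNS = [
    "area", "perimeter", "roundness", "axial_ratio", "solidity",
    "intensity_mean", "intensity_sd", "intensity_q05", "intensity_q25",
    "intensity_q50", "intensity_q75", "intensity_q95", "intensity_integrated",
    *[f"glcm_{stat}_o{o}" for o in GLCM_OFFSETS
      for stat in ("contrast", "correlation", "entropy", "homogeneity")],
    "symmetry_asymmetry",
    *[f"compact_k{k}" for k in COMPACTNESS_K],
]


def feature_schema_hash() -> str:
    """Stable hash of the feature schema, stored with trained models."""
    payload = SCHEMA_VERSION + "|" + ",".join(FEATURE_COLUMNS)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _glcm_features(patch: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Masked GLCM statistics on a 32-level quantised patch.

    Pixels outside the object are assigned a reserved level whose
    co-occurrence rows/columns are discarded before normalisation, so
    texture reflects the object only.
    """
    vals = patch[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.floor((patch - lo) / (hi - lo) * (GLCM_LEVELS - 1)).astype(np.uint8) + 1
        q = np.clip(q, 1, GLCM_LEVELS)
    else:
        q = np.ones(patch.shape, dtype=np.uint8)
    q[~mask] = 0
    glcm = graycomatrix(q, distances=list(GLCM_OFFSETS), angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=GLCM_LEVELS + 1, symmetric=True, normed=False)
    out = {}
    i_idx, j_idx = np.mgrid[0:GLCM_LEVELS, 0:GLCM_LEVELS].astype(float)
    for d_i, offset in enumerate(GLCM_OFFSETS):
        stats = {"contrast": [], "correlation": [], "entropy": [], "homogeneity": []}
        for a_i in range(4):
            P = glcm[1:, 1:, d_i, a_i].astype(float)
            tot = P.sum()
            if tot == 0:
                stats["contrast"].append(0.0)
                stats["correlation"].append(1.0)
                stats["entropy"].append(0.0)
                stats["homogeneity"].append(1.0)
                continue
            P = P / tot
            diff2 = (i_idx - j_idx) ** 2
            stats["contrast"].append(float((P * diff2).sum()))
            stats["homogeneity"].append(float((P / (1.0 + diff2)).sum()))
            nz = P[P > 0]
            stats["entropy"].append(float(-(nz * np.log(nz)).sum()))
            mu_i = (P * i_idx).sum()
            mu_j = (P * j_idx).sum()
            var_i = (P * (i_idx - mu_i) ** 2).sum()
            var_j = (P * (j_idx - mu_j) ** 2).sum()
            if var_i <= 0 or var_j <= 0:
                stats["correlation"].append(1.0)
            else:
                cov = (P * (i_idx - mu_i) * (j_idx - mu_j)).sum()
                stats["correlation"].append(float(cov / np.sqrt(var_i * var_j)))
        for stat, vals_ in stats.items():
            out[f"glcm_{stat}_o{offset}"] = float(np.mean(vals_))
    return out


def _symmetry_asymmetry(patch: np.ndarray, mask: np.ndarray, centroid_local) -> float:
    """Normalised L1 difference between the patch and its 180° rotation.

    The patch is re-cropped to a window symmetric about the (rounded)
    centroid so that rotation by 180° maps the window onto itself; the
    comparison runs over pixels where either orientation is inside the
    object.
    """
    cy, cx = int(round(centroid_local[0])), int(round(centroid_local[1]))
    ry = min(cy, patch.shape[0] - 1 - cy)
    rx = min(cx, patch.shape[1] - 1 - cx)
    if ry < 1 or rx < 1:
        return 0.0
    win = patch[cy - ry:cy + ry + 1, cx - rx:cx + rx + 1]
    wmask = mask[cy - ry:cy + ry + 1, cx - rx:cx + rx + 1]
    rot = win[::-1, ::-1]
    rmask = wmask[::-1, ::-1]
    both = wmask | rmask
    if not both.any():
        return 0.0
    num = np.abs(np.where(wmask, win, 0) - np.where(rmask, rot, 0))[both].sum()
    den = (np.where(wmask, win, 0) + np.where(rmask, rot, 0))[both].sum()
    return float(num / den) if den > 0 else 0.0


def compute_nuclear_features(label_map: LabelMap, hoechst_image: np.ndarray,
                             min_area_px: int = 10,
                             background: float | None = None) -> pd.DataFrame:
    """One row of named features per segmented nucleus.

    Intensity features use background-subtracted values; the
    background reference is the field-level 5th percentile (per-ring
    references would be contaminated by neighbouring nuclei inside
    aggregates) unless ``background`` is given.  Objects smaller than
    ``min_area_px`` are dropped with a logged warning.  Column order
    follows ``FEATURE_COLUMNS`` and is versioned via
    ``feature_schema_hash``.
    """
    if hoechst_image.shape != label_map.labels.shape:
        raise ValueError("label map and image shapes differ")
    if background is None:
        background = float(np.percentile(hoechst_image, 5))
    img = hoechst_image.astype(float) - background
    rows = []
    for prop in regionprops(label_map.labels, intensity_image=img):
        if prop.area < min_area_px:
            logger.warning("dropping object %d: area %d px < %d", prop.label, prop.area, min_area_px)
            continue
        mask = prop.image
        patch = prop.image_intensity
        vals = patch[mask]
        # Crofton perimeter: far less rasterisation bias on smooth shapes
        perim = max(prop.perimeter_crofton, 1.0)
        roundness = min(4 * np.pi * prop.area / perim ** 2, 1.0)
        minor = max(prop.axis_minor_length, 1.0)
        med = np.median(vals)
        feats = {
            "object_id": int(prop.label),
            "area": float(prop.area),
            "perimeter": float(perim),
            "roundness": float(roundness),
            "axial_ratio": float(prop.axis_major_length / minor),
            "solidity": float(prop.solidity),
            "intensity_mean": float(vals.mean()),
            "intensity_sd": float(vals.std()),
            "intensity_q05": float(np.percentile(vals, 5)),
            "intensity_q25": float(np.percentile(vals, 25)),
            "intensity_q50": float(np.percentile(vals, 50)),
            "intensity_q75": float(np.percentile(vals, 75)),
            "intensity_q95": float(np.percentile(vals, 95)),
            "intensity_integrated": float(vals.sum()),
        }
        feats.update(_glcm_features(patch, mask))
        feats["symmetry_asymmetry"] = _symmetry_asymmetry(
            np.where(mask, patch, 0.0), mask, prop.centroid_local)
        for k in COMPACTNESS_K:
            feats[f"compact_k{k}"] = float((vals > k * med).mean()) if med > 0 else 0.0
        rows.append(feats)
    table = pd.DataFrame(rows, columns=["object_id", *FEATURE_COLUMNS])
    if len(table) and table[FEATURE_COLUMNS].isna().any().any():
        bad = table[FEATURE_COLUMNS].columns[table[FEATURE_COLUMNS].isna().any()].tolist()
        raise ValueError(f"NaN features produced in columns {bad}")
    return table
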