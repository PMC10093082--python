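"""Z-stack projection and area-based classing of 3D cell structures.

Neural cultures grown in 3D form structures at four scales — single
cells, grouped cells, big aggregates and spheroids.  Structures are
detected as connected components of the merged Hoechst foreground of a
Z-projection (clusters, not watershed-split nuclei) and classed by
projected area expressed in multiples of the median single-nucleus
area.  Default thresholds are 2 / 10 / 60 nucleus-equivalents and are
configuration-exposed, since only the four-class scheme itself is
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segmentation import SegmentationParams, hoechst_foreground, segment_nuclei, LabelMap

CLASS_NAMES = ("single", "grouped", "aggregate", "spheroid")


@dataclass
class AggregationClassScheme:
    """Area thresholds (in nucleus-equivalents) separating the four classes."""

    a1: float = 2.0
    a2: float = 10.0
    a3: float = 60.0
    #: median single-nucleus area in px; set from data or config
    median_nucleus_area_px: float = 100.0

    def __post_init__(self):
        if not (0 < self.a1 < self.a2 < self.a3):
            raise ValueError("thresholds must satisfy 0 < a1 < a2 < a3")

    def classify_area(self, area_px: float) -> str:
        q = area_px / self.median_nucleus_area_px
        if q < self.a1:
            return "single"
        if q < self.a2:
            return "grouped"
        if q < self.a3:
            return "aggregate"
        return "spheroid"


def project_zstack(stack: np.ndarray, method: str = "max") -> np.ndarray:
    """Reduce a (planes, H, W) stack to a 2-D image.

    ``max`` keeps the brightest (usually in-focus) value per pixel,
    ``mean`` averages planes, ``focus_weighted`` weights each plane by
    its local gradient energy (a simple sharpness proxy).
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.shape[0] == 1:
        return stack[0]
    if method == "max":
        return stack.max(axis=0)
    if method == "mean":
        return stack.mean(axis=0)
    if method == "focus_weighted":
        weights = []
        for plane in stack:
            gy, gx = np.gradient(plane.astype(float))
            energy = ndi.uniform_filter(gy * gy + gx * gx, size=15)
            weights.append(energy)
        w = np.stack(weights)
        w = w / np.clip(w.sum(axis=0, keepdims=True), 1e-12, None)
        return (stack * w).sum(axis=0)
    raise ValueError(f"unknown projection method {method!r}")


def detect_clusters(hoechst_projection: np.ndarray,
                    params: SegmentationParams | None = None) -> LabelMap:
    """Connected components of the Hoechst foreground (no nucleus splitting)."""
    params = params or SegmentationParams(split_touching=False, threshold_method="relative")
    mask = hoechst_foreground(hoechst_projection, params)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    return LabelMap(labels=labels.astype(np.int32), n_objects=int(n))


def median_single_nucleus_area(hoechst_projection: np.ndarray,
                               params: SegmentationParams | None = None) -> float:
    """Median area of detected *single* cells — the scheme's area unit.

    Single cells are clusters containing exactly one watershed-split
    nucleus; dense clusters, where the watershed under-splits and
    would inflate the unit, are excluded.  Falls back to the median
    watershed-nucleus area when the field has no single cells.
    """
    params = params or SegmentationParams(split_touching=True, exclude_border=False,
                                          threshold_method="relative")
    lm = segment_nuclei(hoechst_projection, params)
    if lm.n_objects == 0:
        raise ValueError("no nuclei detected; cannot estimate median nucleus area")
    clusters = detect_clusters(hoechst_projection, params)
    single_areas = []
    for obj in range(1, clusters.n_objects + 1):
        mask = clusters.labels == obj
        inner = np.unique(lm.labels[mask])
        if len(inner[inner > 0]) == 1:
            single_areas.append(int(mask.sum()))
    if single_areas:
        return float(np.median(single_areas))
    areas = np.bincount(lm.labels.ravel())[1:]
    return float(np.median(areas[areas > 0]))


def classify_aggregates(cluster_label_map: LabelMap,
                        scheme: AggregationClassScheme) -> pd.DataFrame:
    """Class each cluster by projected area.

    Returns one row per cluster: object_id, area_px, area in
    nucleus-equivalents, and the assigned class.  Empty map → empty
    result.  Classing is monotone in area by construction.
    """
    labels = cluster_label_map.labels
    n = cluster_label_map.n_objects
    if n == 0:
        return pd.DataFrame(columns=["object_id", "area_px", "nucleus_equivalents",
                                     "aggregation_class", "centroid_row", "centroid_col"])
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    cents = ndi.center_of_mass(labels > 0, labels, np.arange(1, n + 1))
    rows = []
    for obj in range(1, n + 1):
        area = float(areas[obj - 1])
        rows.append({
            "object_id": obj, "area_px": area,
            "nucleus_equivalents": area / scheme.median_nucleus_area_px,
            "aggregation_class": scheme.classify_area(area),
            "centroid_row": float(cents[obj - 1][0]), "centroid_col": float(cents[obj - 1][1]),
        })
    return pd.DataFrame(rows)
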