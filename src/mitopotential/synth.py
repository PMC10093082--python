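"""Synthetic plate-image and feature-table generator with recorded ground truth.

Every input the pipeline consumes can be generated here with known
latent values, so each stage is testable against truth rather than by
eye.  Nuclei are isotropic Gaussian spots truncated at 3σ; the
perinuclear TMRM signal is an annulus around each nucleus (a proxy for
the mitochondrial network that puts the ROI/ring photometry geometry
under test); noise is per-pixel multiplicative log-normal (fixed CV)
plus additive Gaussian read noise.  Kinetic responses are encoded as
per-object multiplicative factors: ``f_o`` (oligomycin hyperpolarisation,
signal rise) and ``f_f`` (FCCP depolarisation, signal collapse) applied
to the basal amplitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import PlateImageSet, TimepointInfo

DEFAULT_TIMEPOINTS = [
    TimepointInfo(0, "basal", 0.0),
    TimepointInfo(1, "oligomycin", 300.0),
    TimepointInfo(2, "fccp", 600.0),
]

AGGREGATION_CLASSES = ("single", "grouped", "aggregate", "spheroid")


@dataclass
class GroundTruth:
    """Latent truth recorded at generation time.

    ``objects`` has one row per generated object (nucleus, cluster or
    DNA-content cell) with whatever columns the generator produced
    (centers, class, kinetic factors, population label, DNA content);
    ``fibers`` holds per-fiber/debris geometry; ``latents`` holds
    scalar generator parameters (background level, basal amplitude...).
    """

    objects: pd.DataFrame = field(default_factory=pd.DataFrame)
    fibers: pd.DataFrame = field(default_factory=pd.DataFrame)
    latents: dict = field(default_factory=dict)

    def __post_init__(self):
        if "f_o" in self.objects.columns and len(self.objects):
            if not (self.objects["f_o"] > 0).all():
                raise ValueError("hyperpolarization factor f_o must be > 0")
            if not (self.objects["f_f"] >= 0).all():
                raise ValueError("depolarization factor f_f must be >= 0")

    @property
    def nuclei_centers(self) -> np.ndarray:
        return self.objects[["row", "col"]].to_numpy(dtype=float)

    def to_json(self, path) -> None:
        payload = {
            "objects": self.objects.to_dict(orient="list"),
            "fibers": self.fibers.to_dict(orient="list"),
            "latents": self.latents,
        }
        Path(path).write_text(json.dumps(payload, default=float))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            objects=pd.DataFrame(payload["objects"]),
            fibers=pd.DataFrame(payload["fibers"]),
            latents=payload["latents"],
        )


# ---------------------------------------------------------------------
# low-level rendering helpers


def _mult_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    """Log-normal multiplicative noise field with mean 1 and CV ``cv``."""
    if cv <= 0:
        return np.ones(shape, dtype=np.float32)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape).astype(np.float32)


def _apply_noise(img: np.ndarray, rng: np.random.Generator, cv: float, read_sd: float) -> np.ndarray:
    out = img * _mult_noise(rng, img.shape, cv)
    if read_sd > 0:
        out = out + rng.normal(0.0, read_sd, img.shape).astype(np.float32)
    return np.clip(out, 0, None).astype(np.float32)


def _add_gaussian_spot(img: np.ndarray, r: float, c: float, sigma: float, amp: float,
                       texture: np.ndarray | None = None) -> None:
    """Add an isotropic Gaussian spot truncated at 3σ, in place."""
    rad = int(np.ceil(3 * sigma))
    r0, r1 = max(0, int(r) - rad), min(img.shape[0], int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(img.shape[1], int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - r) ** 2 + (cc - c) ** 2
    spot = amp * np.exp(-d2 / (2 * sigma * sigma))
    spot[d2 > (3 * sigma) ** 2] = 0.0
    if texture is not None:
        spot = spot * texture[: spot.shape[0], : spot.shape[1]]
    img[r0:r1, c0:c1] += spot.astype(np.float32)


def _add_annulus(img: np.ndarray, r: float, c: float, r_in: float, r_out: float, amp: float) -> None:
    """Add a flat annulus of value ``amp`` between radii r_in and r_out, in place."""
    rad = int(np.ceil(r_out))
    r0, r1 = max(0, int(r) - rad), min(img.shape[0], int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(img.shape[1], int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - r) ** 2 + (cc - c) ** 2
    mask = (d2 >= r_in * r_in) & (d2 <= r_out * r_out)
    img[r0:r1, c0:c1][mask] += amp


def _place_points(rng: np.random.Generator, n: int, shape, min_sep: float, margin: float,
                  max_tries_per_point: int = 300) -> np.ndarray:
    """Dart-throwing placement with a minimum pairwise separation.

    Raises when the requested density exceeds packing capacity.
    """
    pts: list[tuple[float, float]] = []
    tries = 0
    budget = max_tries_per_point * max(n, 1)
    while len(pts) < n:
        if tries > budget:
            raise ValueError(
                f"cannot place {n} points with separation {min_sep} in {shape}: density cap exceeded"
            )
        tries += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep * min_sep for pr, pc in pts):
            pts.append((r, c))
    return np.asarray(pts, dtype=float).reshape(n, 2)


# ---------------------------------------------------------------------
# monolayer time-lapse (2D, one focal plane)


def generate_monolayer_timelapse(
    n_cells: int,
    basal_mean: float = 400.0,
    background_level: float = 100.0,
    f_o: float = 1.3,
    f_f: float = 0.4,
    noise_cv: float = 0.05,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    nucleus_sigma: float = 4.0,
    hoechst_amp: float = 900.0,
    hoechst_background: float = 20.0,
    read_noise_sd: float = 2.0,
    timepoints: list[TimepointInfo] | None = None,
    well: str = "B02",
    n_fields: int = 1,
) -> tuple[PlateImageSet, GroundTruth]:
    """Simulate a 2D monolayer TMRM time-lapse with known kinetics.

    The Hoechst channel carries ``n_cells`` Gaussian nuclei per field on
    a low uniform background.  The TMRM channel carries, per cell, a
    flat perinuclear annulus of amplitude ``basal_mean`` above the
    uniform ``background_level``, scaled by ``f_o`` at oligomycin and
    ``f_f`` at FCCP timepoints.  Per-pixel noise is multiplicative
    log-normal with CV ``noise_cv`` plus additive read noise.
    """
    rng = np.random.default_rng(seed)
    tps = timepoints or DEFAULT_TIMEPOINTS
    factors = {"basal": 1.0, "oligomycin": f_o, "fccp": f_f}
    if f_o <= 0 or f_f < 0:
        raise ValueError("f_o must be > 0 and f_f >= 0")

    nuc_rad = 3 * nucleus_sigma
    annulus_w = 4.0
    min_sep = 2 * (nuc_rad + annulus_w) + 3
    pset = PlateImageSet(
        wells=[well], fields_per_well=n_fields, channels=["hoechst", "tmrm"],
        timepoints=tps, planes=1,
    )
    records = []
    for fld in range(n_fields):
        centers = _place_points(rng, n_cells, shape, min_sep, margin=nuc_rad + annulus_w + 2)
        for oid, (r, c) in enumerate(centers, start=1):
            records.append({
                "well": well, "field": fld, "object_id": oid, "row": r, "col": c,
                "f_o": f_o, "f_f": f_f, "basal_signal": basal_mean,
            })
        hoechst_clean = np.full(shape, hoechst_background, dtype=np.float32)
        for r, c in centers:
            _add_gaussian_spot(hoechst_clean, r, c, nucleus_sigma, hoechst_amp)
        for tp in tps:
            fac = factors[tp.treatment]
            tmrm_clean = np.full(shape, background_level, dtype=np.float32)
            for r, c in centers:
                # perinuclear annulus hugging the visible nucleus footprint
                _add_annulus(tmrm_clean, r, c, 2.2 * nucleus_sigma,
                             2.2 * nucleus_sigma + annulus_w, basal_mean * fac)
            pset.images[(well, fld, "hoechst", tp.index, 0)] = _apply_noise(
                hoechst_clean, rng, noise_cv, read_noise_sd)
            pset.images[(well, fld, "tmrm", tp.index, 0)] = _apply_noise(
                tmrm_clean, rng, noise_cv, read_noise_sd)
    pset.validate()
    gt = GroundTruth(
        objects=pd.DataFrame(records),
        latents={
            "basal_mean": basal_mean, "background_level": background_level,
            "f_o": f_o, "f_f": f_f, "noise_cv": noise_cv,
            "nucleus_sigma": nucleus_sigma, "annulus_width": annulus_w,
            "hoechst_background": hoechst_background, "hoechst_amp": hoechst_amp,
        },
    )
    return pset, gt


def generate_coculture_timelapse(
    n_a: int,
    n_b: int,
    factors_a: tuple[float, float] = (1.3, 0.4),
    factors_b: tuple[float, float] = (1.1, 0.7),
    basal_mean_a: float = 400.0,
    basal_mean_b: float = 300.0,
    background_level: float = 100.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    shape: tuple[int, int] = (640, 640),
    well: str = "B02",
) -> tuple[PlateImageSet, GroundTruth]:
    """Two co-cultured populations distinguishable by nuclear appearance only.

    Population A nuclei are small, bright and smooth; population B
    nuclei are larger, dimmer and carry a chromatin-like speckle
    texture.  Each population has its own basal TMRM amplitude and
    oligomycin/FCCP response factors, mimicking two cell types sharing
    a well without any surface marker.
    """
    rng = np.random.default_rng(seed)
    tps = DEFAULT_TIMEPOINTS
    pop_params = {
        "A": dict(sigma=4.0, amp=900.0, speckle=0.05, basal=basal_mean_a,
                  f_o=factors_a[0], f_f=factors_a[1]),
        "B": dict(sigma=6.0, amp=520.0, speckle=0.45, basal=basal_mean_b,
                  f_o=factors_b[0], f_f=factors_b[1]),
    }
    annulus_w = 4.0
    max_rad = 3 * max(p["sigma"] for p in pop_params.values())
    centers = _place_points(rng, n_a + n_b, shape, 2 * (max_rad + annulus_w) + 3,
                            margin=max_rad + annulus_w + 2)
    labels = np.array(["A"] * n_a + ["B"] * n_b)
    rng.shuffle(labels)

    records = []
    textures = {}
    for oid, ((r, c), lab) in enumerate(zip(centers, labels), start=1):
        p = pop_params[lab]
        records.append({
            "well": well, "field": 0, "object_id": oid, "row": r, "col": c,
            "population_label": lab, "f_o": p["f_o"], "f_f": p["f_f"],
            "basal_signal": p["basal"], "nucleus_sigma": p["sigma"],
        })
        # frozen per-nucleus chromatin speckle so all timepoints agree
        rad = int(np.ceil(3 * p["sigma"]))
        speck = 1.0 + p["speckle"] * gaussian_filter(
            rng.normal(0, 1, (2 * rad + 1, 2 * rad + 1)), 1.0) * 3.0
        textures[oid] = np.clip(speck, 0.2, None).astype(np.float32)

    pset = PlateImageSet(wells=[well], fields_per_well=1, channels=["hoechst", "tmrm"],
                         timepoints=tps, planes=1)
    factors = {"basal": lambda p: 1.0, "oligomycin": lambda p: p["f_o"], "fccp": lambda p: p["f_f"]}
    hoechst_clean = np.full(shape, 20.0, dtype=np.float32)
    for oid, ((r, c), lab) in enumerate(zip(centers, labels), start=1):
        p = pop_params[lab]
        _add_gaussian_spot(hoechst_clean, r, c, p["sigma"], p["amp"], texture=textures[oid])
    for tp in tps:
        tmrm_clean = np.full(shape, background_level, dtype=np.float32)
        for (r, c), lab in zip(centers, labels):
            p = pop_params[lab]
            fac = factors[tp.treatment](p)
            _add_annulus(tmrm_clean, r, c, 2.2 * p["sigma"], 2.2 * p["sigma"] + annulus_w,
                         p["basal"] * fac)
        pset.images[(well, 0, "hoechst", tp.index, 0)] = _apply_noise(hoechst_clean, rng, noise_cv, 2.0)
        pset.images[(well, 0, "tmrm", tp.index, 0)] = _apply_noise(tmrm_clean, rng, noise_cv, 2.0)
    pset.validate()
    gt = GroundTruth(objects=pd.DataFrame(records),
                     latents={"background_level": background_level, "noise_cv": noise_cv,
                              "pop_params": {k: dict(v) for k, v in pop_params.items()}})
    return pset, gt


# ---------------------------------------------------------------------
# aggregation field (LUHMES-style structures, Z-stack)

DEFAULT_AREA_PARAMS = {
    "single": {"n_nuclei": (1, 1)},
    "grouped": {"n_nuclei": (4, 5)},
    "aggregate": {"n_nuclei": (20, 26)},
    "spheroid": {"diameter": (150, 180)},
}

DEFAULT_CLASS_FACTORS = {
    "single": (1.3, 0.4), "grouped": (1.3, 0.4),
    "aggregate": (1.2, 0.5), "spheroid": (1.15, 0.55),
}


def _nominal_area_range(params: dict, nucleus_area: float) -> tuple[float, float]:
    if "n_nuclei" in params:
        lo, hi = params["n_nuclei"]
        # touching nuclei overlap; projected cluster area is ~75-100% of the sum
        return 0.7 * lo * nucleus_area, 1.05 * hi * nucleus_area
    lo, hi = params["diameter"]
    return np.pi * (lo / 2) ** 2 * 0.9, np.pi * (hi / 2) ** 2 * 1.1


def generate_aggregation_field(
    counts_per_class: dict[str, int],
    area_params: dict | None = None,
    planes: int = 5,
    plane_spacing_um: float = 13.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    nucleus_sigma: float = 2.5,
    class_factors: dict | None = None,
    noise_cv: float = 0.05,
    basal_mean: float = 400.0,
    background_level: float = 100.0,
    well: str = "B02",
) -> tuple[PlateImageSet, GroundTruth]:
    """Field of nuclei arranged at four aggregation scales, as a Z-stack.

    Classes — single cells, grouped cells, big aggregates, spheroids —
    are realised with disjoint projected-area ranges (checked, error on
    overlap).  Each structure is sharp in one focal plane and blurred
    in the others proportionally to plane distance; spheroids are
    rendered as filled discs with granular nuclear texture.  TMRM
    signal covers each structure with class-specific kinetic factors.
    """
    rng = np.random.default_rng(seed)
    area_params = area_params or DEFAULT_AREA_PARAMS
    class_factors = class_factors or DEFAULT_CLASS_FACTORS
    tps = DEFAULT_TIMEPOINTS
    nuc_rad = 3 * nucleus_sigma
    # area unit = footprint above 10% of peak (the rendering's visible disc),
    # radius σ·sqrt(2·ln 10) ≈ 2.146σ
    nucleus_area = np.pi * (nucleus_sigma * np.sqrt(2 * np.log(10))) ** 2

    ranges = {}
    for cls, cnt in counts_per_class.items():
        if cls not in AGGREGATION_CLASSES:
            raise ValueError(f"unknown aggregation class {cls!r}")
        if cnt > 0:
            ranges[cls] = _nominal_area_range(area_params[cls], nucleus_area)
    ordered = [c for c in AGGREGATION_CLASSES if c in ranges]
    for a, b in zip(ordered, ordered[1:]):
        if ranges[a][1] >= ranges[b][0]:
            raise ValueError(f"class area ranges overlap: {a} {ranges[a]} vs {b} {ranges[b]}")

    # cluster footprint radius per class, for collision-free placement
    def footprint(cls):
        p = area_params[cls]
        if "diameter" in p:
            return p["diameter"][1] / 2 + 5
        return nuc_rad * (1 + 1.1 * np.sqrt(p["n_nuclei"][1])) + 5

    clusters = []
    for cls in AGGREGATION_CLASSES:
        for _ in range(counts_per_class.get(cls, 0)):
            clusters.append(cls)
    # place large structures first; pairwise clearance uses per-cluster radii
    clusters.sort(key=footprint, reverse=True)
    radii = [footprint(c) for c in clusters]
    centers = []
    tries, budget = 0, 400 * max(len(clusters), 1)
    for cls, rad in zip(clusters, radii):
        while True:
            if tries > budget:
                raise ValueError(
                    f"cannot place {len(clusters)} structures in {shape}: density cap exceeded")
            tries += 1
            r = rng.uniform(rad + 3, shape[0] - rad - 3)
            c = rng.uniform(rad + 3, shape[1] - rad - 3)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= (rad + prad + 8) ** 2
                   for (pr, pc), prad in zip(centers, radii[:len(centers)])):
                centers.append((r, c))
                break

    focus = planes // 2
    hoechst_planes = [np.full(shape, 20.0, dtype=np.float32) for _ in range(planes)]
    records = []
    tmrm_sig = {tp.index: np.zeros(shape, dtype=np.float32) for tp in tps}
    factors = {"basal": 1.0}

    for cid, (cls, (r, c)) in enumerate(zip(clusters, centers), start=1):
        p = area_params[cls]
        render = np.zeros(shape, dtype=np.float32)
        if "diameter" in p:
            diam = rng.uniform(*p["diameter"])
            rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
            d = np.sqrt((rr - r) ** 2 + (cc - c) ** 2)
            disc = np.clip((diam / 2 + 1 - d), 0, 1).astype(np.float32)  # soft 1 px edge
            tex = np.clip(1 + 0.3 * gaussian_filter(rng.normal(0, 1, shape), 2.0) * 3, 0.3, None)
            render += 800.0 * disc * tex.astype(np.float32)
            n_nuc = int(np.pi * (diam / 2) ** 2 / nucleus_area)
        else:
            n_nuc = int(rng.integers(p["n_nuclei"][0], p["n_nuclei"][1] + 1))
            if n_nuc == 1:
                pts = [(r, c)]
            else:
                # pack touching nuclei on a jittered spiral inside the footprint
                pts = []
                spacing = 1.9 * nuc_rad
                golden = np.pi * (3 - np.sqrt(5))
                for k in range(n_nuc):
                    rad_k = spacing * np.sqrt(k) * 0.55
                    ang = k * golden + rng.uniform(-0.1, 0.1)
                    pts.append((r + rad_k * np.cos(ang), c + rad_k * np.sin(ang)))
            for pr, pc in pts:
                _add_gaussian_spot(render, pr, pc, nucleus_sigma, 900.0)
        fg = render > 90.0  # 10% of nominal amplitude
        proj_area = int(fg.sum())
        fp = int(rng.integers(0, planes))
        f_o, f_f = class_factors[cls]
        records.append({
            "well": well, "field": 0, "object_id": cid, "row": r, "col": c,
            "object_class": cls, "projected_area_px": proj_area, "n_nuclei": n_nuc,
            "focus_plane": fp, "f_o": f_o, "f_f": f_f,
        })
        for z in range(planes):
            blur = 1.8 * abs(z - fp)
            hoechst_planes[z] += gaussian_filter(render, blur) if blur > 0 else render
        for tp in tps:
            fac = {"basal": 1.0, "oligomycin": f_o, "fccp": f_f}[tp.treatment]
            tmrm_sig[tp.index][fg] += basal_mean * fac

    pset = PlateImageSet(wells=[well], fields_per_well=1, channels=["hoechst", "tmrm"],
                         timepoints=tps, planes=planes, plane_spacing_um=plane_spacing_um)
    for tp in tps:
        for z in range(planes):
            pset.images[(well, 0, "hoechst", tp.index, z)] = _apply_noise(
                hoechst_planes[z], rng, noise_cv, 2.0)
            pset.images[(well, 0, "tmrm", tp.index, z)] = _apply_noise(
                tmrm_sig[tp.index] + background_level, rng, noise_cv, 2.0)
    pset.validate()
    gt = GroundTruth(objects=pd.DataFrame(records),
                     latents={"nucleus_sigma": nucleus_sigma, "nucleus_area": nucleus_area,
                              "basal_mean": basal_mean, "background_level": background_level,
                              "class_factors": {k: list(v) for k, v in class_factors.items()}})
    return pset, gt


# ---------------------------------------------------------------------
# isolated myofiber Z-stacks (brightfield + TMRM)


def generate_fiber_stack(
    n_fibers: int,
    length_px: float = 300.0,
    width_px: float = 24.0,
    striation_period_px: float = 12.0,
    n_debris: int = 5,
    step_um: float = 45.0,
    seed: int = 0,
    planes: int = 3,
    shape: tuple[int, int] = (512, 512),
    background: float = 1000.0,
    illumination_amplitude: float = 200.0,
    fiber_contrast: float = 350.0,
    tmrm_background: float = 150.0,
    tmrm_signal: float = 650.0,
    f_o: float = 1.3,
    f_f: float = 0.4,
    noise_cv: float = 0.03,
    well: str = "B02",
) -> tuple[PlateImageSet, GroundTruth]:
    """Brightfield+TMRM Z-stacks of striated cylindrical fibers plus debris.

    Each fiber is a capsule of length ``length_px`` and width
    ``width_px`` with sinusoidal axial striation, rendered sharp in one
    randomly chosen focal plane; debris are small round blobs without
    striation.  Brightfield planes carry a smooth parabolic
    illumination dome (center brighter than corners by
    ``illumination_amplitude``).  TMRM co-localises with fibers and
    follows the oligomycin/FCCP factors.
    """
    if length_px <= width_px:
        raise ValueError("length_px must exceed width_px")
    rng = np.random.default_rng(seed)
    tps = DEFAULT_TIMEPOINTS
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float32)
    d2 = (rr - H / 2) ** 2 + (cc - W / 2) ** 2
    dome = illumination_amplitude * (1 - d2 / d2.max())

    half_len = length_px / 2
    # rejection-sample capsule axes so no two objects touch
    placed_segs: list[tuple] = []  # (p0, p1, half_width)

    def seg_dist(p0, p1, q0, q1):
        # min distance between two segments (0 when they cross)
        def cross(o, a, b):
            return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])
        d1, d2 = cross(q0, q1, p0), cross(q0, q1, p1)
        d3, d4 = cross(p0, p1, q0), cross(p0, p1, q1)
        if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
            return 0.0
        def pt_seg(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-12), 0, 1)
            return np.linalg.norm(p - (a + t * ab))
        return min(pt_seg(p0, q0, q1), pt_seg(p1, q0, q1), pt_seg(q0, p0, p1), pt_seg(q1, p0, p1))

    def place(seg_half_len, half_width, clearance=12.0, tries=4000):
        for _ in range(tries):
            theta = rng.uniform(0, np.pi)
            dvec = np.array([np.sin(theta), np.cos(theta)])
            m = half_width + 4
            lo = seg_half_len * np.abs(dvec) + m
            ctr = np.array([rng.uniform(lo[0], shape[0] - lo[0]),
                            rng.uniform(lo[1], shape[1] - lo[1])])
            p0, p1 = ctr - seg_half_len * dvec, ctr + seg_half_len * dvec
            if all(seg_dist(p0, p1, q0, q1) >= half_width + qw + clearance
                   for q0, q1, qw in placed_segs):
                placed_segs.append((p0, p1, half_width))
                return ctr, theta
        raise ValueError("cannot place fiber/debris: density cap exceeded")

    fiber_recs = []
    bf_sig = [np.zeros(shape, dtype=np.float32) for _ in range(planes)]
    tmrm_sig = {tp.index: np.zeros(shape, dtype=np.float32) for tp in tps}

    for oid in range(1, n_fibers + n_debris + 1):
        is_fiber = oid <= n_fibers
        fp = int(rng.integers(0, planes))
        if is_fiber:
            (r, c), theta = place(half_len, width_px / 2)
            dr, dc = np.sin(theta), np.cos(theta)
            u = (rr - r) * dr + (cc - c) * dc       # along axis
            v = -(rr - r) * dc + (cc - c) * dr      # across axis
            inside = (np.abs(u) <= half_len) & (np.abs(v) <= width_px / 2)
            stri = 1 + 0.45 * np.sin(2 * np.pi * u / striation_period_px)
            prof = np.cos(np.clip(v / (width_px / 2), -1, 1) * np.pi / 2)  # cylindrical shading
            sig = np.where(inside, fiber_contrast * stri * prof, 0.0).astype(np.float32)
            bf_sig[fp] += sig
            for tp in tps:
                fac = {"basal": 1.0, "oligomycin": f_o, "fccp": f_f}[tp.treatment]
                tmrm_sig[tp.index][inside] += tmrm_signal * fac
            fiber_recs.append({
                "fiber_id": oid, "is_fiber": True,
                "r0": r - half_len * dr, "c0": c - half_len * dc,
                "r1": r + half_len * dr, "c1": c + half_len * dc,
                "row": r, "col": c, "length_px": length_px, "width_px": width_px,
                "striation_period_px": striation_period_px, "focus_plane": fp,
                "f_o": f_o, "f_f": f_f, "tmrm_signal": tmrm_signal,
            })
        else:
            rad = rng.uniform(0.8, 1.4) * width_px / 2
            (r, c), _ = place(0.0, rad)
            blob = np.exp(-d2_blob(rr, cc, r, c) / (2 * (rad / 2) ** 2))
            blob[d2_blob(rr, cc, r, c) > (1.5 * rad) ** 2] = 0
            bf_sig[fp] += (fiber_contrast * blob).astype(np.float32)
            fiber_recs.append({
                "fiber_id": oid, "is_fiber": False, "r0": r, "c0": c, "r1": r, "c1": c,
                "row": r, "col": c, "length_px": 2 * rad, "width_px": 2 * rad,
                "striation_period_px": 0.0, "focus_plane": fp,
                "f_o": 1.0, "f_f": 1.0, "tmrm_signal": 0.0,
            })

    pset = PlateImageSet(wells=[well], fields_per_well=1, channels=["brightfield", "tmrm"],
                         timepoints=tps, planes=planes, plane_spacing_um=step_um)
    for tp in tps:
        for z in range(planes):
            bf = background + dome + bf_sig[z]
            pset.images[(well, 0, "brightfield", tp.index, z)] = _apply_noise(bf, rng, noise_cv, 2.0)
            pset.images[(well, 0, "tmrm", tp.index, z)] = _apply_noise(
                tmrm_sig[tp.index] + tmrm_background, rng, noise_cv, 2.0)
    pset.validate()
    gt = GroundTruth(fibers=pd.DataFrame(fiber_recs),
                     latents={"background": background, "illumination_amplitude": illumination_amplitude,
                              "fiber_contrast": fiber_contrast, "tmrm_background": tmrm_background,
                              "tmrm_signal": tmrm_signal, "f_o": f_o, "f_f": f_f,
                              "striation_period_px": striation_period_px})
    return pset, gt


def d2_blob(rr, cc, r, c):
    return (rr - r) ** 2 + (cc - c) ** 2


# ---------------------------------------------------------------------
# tabular generators

_BASE_FEATURE_NAMES = [
    "area", "perimeter", "roundness", "axial_ratio", "solidity",
    "intensity_mean", "intensity_sd", "intensity_q05", "intensity_q25",
    "intensity_q50", "intensity_q75", "intensity_q95", "intensity_integrated",
    "glcm_contrast_o1", "glcm_correlation_o1", "glcm_entropy_o1", "glcm_homogeneity_o1",
    "glcm_contrast_o2", "glcm_correlation_o2", "glcm_entropy_o2", "glcm_homogeneity_o2",
    "glcm_contrast_o4", "glcm_correlation_o4", "glcm_entropy_o4", "glcm_homogeneity_o4",
    "symmetry_asymmetry", "compact_k1.2", "compact_k1.5",
]


def generate_feature_table(
    n_per_class: int,
    class_shift: float = 2.0,
    n_features: int = 30,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-population nuclear feature table with controlled separability.

    Both populations are Gaussian in feature space; population B is
    offset by ``class_shift`` on a random ~1/3 subset of features.
    ``class_shift=0`` makes labels and features independent.  The
    informative feature indices are recorded in ``table.attrs``.
    Returns ``(table, labels)`` with labels "A"/"B".
    """
    if n_features < 5:
        raise ValueError("n_features must be >= 5 (classifier input contract)")
    rng = np.random.default_rng(seed)
    names = list(_BASE_FEATURE_NAMES[:n_features])
    for k in range(len(names), n_features):
        names.append(f"extra_feature_{k:02d}")
    n_info = max(1, round(n_features / 3))
    informative = np.sort(rng.choice(n_features, size=n_info, replace=False))
    base_mean = rng.uniform(-1, 1, n_features)
    n = 2 * n_per_class
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    rng.shuffle(labels)
    X = base_mean + rng.normal(0.0, noise_sd, (n, n_features))
    X[np.where(labels == "B")[0][:, None], informative[None, :]] += class_shift
    table = pd.DataFrame(X, columns=names)
    table.insert(0, "object_id", np.arange(1, n + 1))
    table.attrs["informative_features"] = informative.tolist()
    return table, labels


def generate_dna_content(
    n: int,
    frac_g1: float = 0.6,
    frac_s: float = 0.1,
    frac_g2m: float = 0.3,
    cv: float = 0.05,
    seed: int = 0,
    g1_mode: float = 1000.0,
    s_band: tuple[float, float] = (1.45, 1.70),
) -> tuple[np.ndarray, GroundTruth]:
    """Per-cell integrated Hoechst intensities for a cell-cycle mixture.

    G0/G1 cells sit at the mode ``g1_mode`` (2N), G2/M at twice that
    (4N), S-phase cells uniformly inside ``s_band`` (as multiples of the
    mode), all under multiplicative noise of CV ``cv``.  The S band
    defaults to the central part of the 2N-4N doubling so that
    interval gates bracket it cleanly.
    """
    fr = np.array([frac_g1, frac_s, frac_g2m], dtype=float)
    if (fr < 0).any():
        raise ValueError("phase fractions must be nonnegative")
    if abs(fr.sum() - 1) > 1e-9:
        raise ValueError(f"phase fractions must sum to 1, got {fr.sum()}")
    rng = np.random.default_rng(seed)
    phases = rng.choice(np.array(["G0/G1", "S", "G2/M"]), size=n, p=fr)
    latent = np.empty(n)
    latent[phases == "G0/G1"] = g1_mode
    latent[phases == "G2/M"] = 2 * g1_mode
    n_s = int((phases == "S").sum())
    latent[phases == "S"] = g1_mode * rng.uniform(s_band[0], s_band[1], n_s)
    values = latent * _mult_noise(rng, n, cv)
    gt = GroundTruth(
        objects=pd.DataFrame({"object_id": np.arange(1, n + 1), "phase": phases,
                              "dna_content": latent / g1_mode * 2.0}),
        latents={"g1_mode": g1_mode, "fractions": fr.tolist(), "cv": cv, "s_band": list(s_band)},
    )
    return values, gt
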