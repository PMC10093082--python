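"""End-to-end workflow orchestration: one config in, an output bundle out.

Each workflow chains the per-stage modules the way the four
experimental models are analysed: *monolayer* (segment → ring
photometry → well traces), *aggregates* (Z-projection → cluster
classing → per-class traces), *fibers* (brightfield detection → gates
→ per-fiber traces), *coculture* (features → dense-net scores → score
filter → per-population traces), *cellcycle* (integrated intensity →
phase gates) and *synth* (write a synthetic plate to disk).  Every run
emits a provenance JSON (config, seed, package version) sufficient to
re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .io import PlateImageSet, read_plate, write_plate, write_table
from . import synth
from .segmentation import (SegmentationParams, segment_nuclei, define_measurement_regions,
                           measure_object_intensities)
from .kinetics import build_traces, normalize_to_basal, summarize_response, traces_to_frame
from .aggregates import (AggregationClassScheme, project_zstack, detect_clusters,
                         median_single_nucleus_area, classify_aggregates)
from .fibers import (FiberDetectParams, FiberFilterParams, basic_flatfield, sliding_parabola,
                     detect_fiber_candidates, filter_true_fibers, measure_fiber_tmrm)
from .features import compute_nuclear_features
from .classifier import (ClassifierSpec, train_classifier, score_cells, filter_by_score)
from .cellcycle import integrated_nuclear_intensity, gate_cell_cycle

logger = logging.getLogger(__name__)

WORKFLOWS = ("synth", "monolayer", "aggregates", "fibers", "coculture", "cellcycle")


@dataclass
class RunConfig:
    workflow: str
    seed: int = 0
    outdir: str | Path | None = None
    input_dir: str | Path | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.workflow not in WORKFLOWS:
            raise ValueError(f"unknown workflow {self.workflow!r}; expected one of {WORKFLOWS}")


class StageError(RuntimeError):
    """An error in a named pipeline stage, with object context."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


# ---------------------------------------------------------------------
# shared measurement helpers


def measure_plate(pset: PlateImageSet, seg_params: SegmentationParams | None = None,
                  r_cell: float = 8, r_gap: float = 2, r_ring: float = 5,
                  channel: str = "tmrm") -> pd.DataFrame:
    """Segment the Hoechst channel per (well, field, timepoint) and measure
    ring-corrected intensities of ``channel``.  Multi-plane sets are
    max-projected first."""
    seg_params = seg_params or SegmentationParams()
    tables = []
    for well in pset.wells:
        for fld in range(pset.fields_per_well):
            for tp in pset.timepoints:
                hoechst = project_zstack(pset.stack(well, fld, "hoechst", tp.index), "max")
                lm = segment_nuclei(hoechst, seg_params)
                regions = define_measurement_regions(lm, r_cell, r_gap, r_ring)
                signal = project_zstack(pset.stack(well, fld, channel, tp.index), "max")
                tables.append(measure_object_intensities(regions, signal, tp.index, well, fld))
    out = pd.concat([t for t in tables if len(t)], ignore_index=True) if tables else pd.DataFrame()
    return out


def _treatments(pset: PlateImageSet) -> dict[int, str]:
    return {tp.index: tp.treatment for tp in pset.timepoints}


# ---------------------------------------------------------------------
# workflows


@_stage("monolayer")
def workflow_monolayer(pset: PlateImageSet, grouping: str = "well", **measure_kwargs) -> dict:
    table = measure_plate(pset, **measure_kwargs)
    traces = build_traces(table, grouping=grouping, treatments=_treatments(pset))
    traces = normalize_to_basal(traces)
    summaries = [summarize_response(t) for t in traces if not t.incomplete]
    return {"object_table": table, "traces": traces, "summaries": summaries}


@_stage("aggregates")
def workflow_aggregates(pset: PlateImageSet, scheme: AggregationClassScheme | None = None,
                        seg_params: SegmentationParams | None = None,
                        projection: str = "max") -> dict:
    well, fld = pset.wells[0], 0
    basal_tp = pset.timepoints[0].index
    hoechst = project_zstack(pset.stack(well, fld, "hoechst", basal_tp), projection)
    med_area = median_single_nucleus_area(hoechst, seg_params)
    if scheme is None:
        scheme = AggregationClassScheme(median_nucleus_area_px=med_area)
    else:
        scheme = dataclasses.replace(scheme, median_nucleus_area_px=med_area)
    clusters = detect_clusters(hoechst, seg_params)
    classes = classify_aggregates(clusters, scheme)
    regions = define_measurement_regions(clusters, r_cell=2, r_gap=2, r_ring=6)
    tables = []
    for tp in pset.timepoints:
        tmrm = project_zstack(pset.stack(well, fld, "tmrm", tp.index), projection)
        t = measure_object_intensities(regions, tmrm, tp.index, well, fld)
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    table = table.merge(classes[["object_id", "aggregation_class"]], on="object_id", how="left")
    traces = build_traces(table, grouping="aggregation_class", treatments=_treatments(pset))
    traces = normalize_to_basal(traces)
    summaries = [summarize_response(t) for t in traces if not t.incomplete]
    return {"clusters": clusters, "classes": classes, "object_table": table,
            "traces": traces, "summaries": summaries, "scheme": scheme}


@_stage("fibers")
def workflow_fibers(pset: PlateImageSet, detect_params: FiberDetectParams | None = None,
                    filter_params: FiberFilterParams | None = None) -> dict:
    well, fld = pset.wells[0], 0
    basal_tp = pset.timepoints[0].index
    stack = pset.stack(well, fld, "brightfield", basal_tp)
    detect_params = detect_params or FiberDetectParams()
    candidates = detect_fiber_candidates(stack, detect_params)
    flat = np.max([sliding_parabola(basic_flatfield(p), detect_params.curvature,
                                    detect_params.parabola_scale) for p in stack], axis=0)
    records = filter_true_fibers(candidates, flat, filter_params)
    tmrm_images = {tp.index: project_zstack(pset.stack(well, fld, "tmrm", tp.index), "max")
                   for tp in pset.timepoints}
    table = measure_fiber_tmrm(records, tmrm_images, well=well, field_idx=fld)
    result = {"candidates": candidates, "fibers": records, "object_table": table}
    if len(table):
        traces = build_traces(table, grouping="well", treatments=_treatments(pset))
        traces = normalize_to_basal(traces)
        result["traces"] = traces
        result["summaries"] = [summarize_response(t) for t in traces if not t.incomplete]
    return result


def _coculture_features(pset: PlateImageSet, seg_params: SegmentationParams) -> tuple:
    """Segment the basal Hoechst image and compute per-nucleus features."""
    well, fld = pset.wells[0], 0
    basal_tp = pset.timepoints[0].index
    hoechst = project_zstack(pset.stack(well, fld, "hoechst", basal_tp), "max")
    lm = segment_nuclei(hoechst, seg_params)
    feats = compute_nuclear_features(lm, hoechst)
    return lm, feats


@_stage("coculture")
def workflow_coculture(pset_mono_a: PlateImageSet, pset_mono_b: PlateImageSet,
                       pset_cocult: PlateImageSet,
                       spec: ClassifierSpec | None = None,
                       threshold: float = 0.6,
                       seg_params: SegmentationParams | None = None) -> dict:
    """Marker-free co-culture analysis.

    The classifier is trained on nuclear features from the two
    monoculture wells (whose identities are known by construction, as
    in the wet protocol), then applied to the co-culture well; cells
    scoring in the ambiguous band are discarded, and per-population
    ring-corrected TMRM traces are built from the assigned cells only.
    """
    # relative threshold keeps nucleus footprints comparable between
    # monoculture and co-culture fields with different brightness mixes
    seg_params = seg_params or SegmentationParams(threshold_method="relative")
    _, feats_a = _coculture_features(pset_mono_a, seg_params)
    _, feats_b = _coculture_features(pset_mono_b, seg_params)
    train_feats = pd.concat([feats_a, feats_b], ignore_index=True)
    train_feats["object_id"] = np.arange(1, len(train_feats) + 1)
    labels = np.array(["A"] * len(feats_a) + ["B"] * len(feats_b))
    model, history = train_classifier(train_feats, labels, spec=spec)

    lm_co, feats_co = _coculture_features(pset_cocult, seg_params)
    scores = score_cells(model, feats_co)
    assignments = filter_by_score(scores, threshold)

    table = measure_plate(pset_cocult, seg_params=seg_params)
    # objects are re-detected per timepoint: propagate the basal assignment
    # to every timepoint row by nearest basal centroid
    basal_tp = pset_cocult.timepoints[0].index
    basal_rows = table[table["timepoint_index"] == basal_tp]
    merged_basal = basal_rows.merge(assignments, on="object_id", how="left")
    from scipy.spatial import cKDTree
    tree = cKDTree(basal_rows[["centroid_row", "centroid_col"]].to_numpy())
    d, nearest = tree.query(table[["centroid_row", "centroid_col"]].to_numpy())
    table = table.copy()
    table["assigned"] = merged_basal["assigned"].to_numpy()[nearest]
    table.loc[d > 15, "assigned"] = "discarded"
    kept = table[table["assigned"].isin(["A", "B"])].rename(columns={"assigned": "condition"})
    traces = build_traces(kept, grouping="condition", treatments=_treatments(pset_cocult))
    traces = normalize_to_basal(traces)
    summaries = [summarize_response(t) for t in traces if not t.incomplete]
    return {"model": model, "history": history, "features": feats_co, "label_map": lm_co,
            "scores": scores, "assignments": assignments, "object_table": table,
            "traces": traces, "summaries": summaries}


@_stage("cellcycle")
def workflow_cellcycle(pset: PlateImageSet, t1: float = 1.4, t2: float = 1.75,
                       seg_params: SegmentationParams | None = None) -> dict:
    well, fld = pset.wells[0], 0
    basal_tp = pset.timepoints[0].index
    hoechst = project_zstack(pset.stack(well, fld, "hoechst", basal_tp), "max")
    lm = segment_nuclei(hoechst, seg_params or SegmentationParams())
    values = integrated_nuclear_intensity(lm, hoechst)
    summary = gate_cell_cycle(values, t1=t1, t2=t2)
    return {"values": values, "summary": summary, "label_map": lm}


# ---------------------------------------------------------------------
# config-driven entry point


def _load_inputs(config: RunConfig) -> PlateImageSet:
    if config.input_dir is not None:
        layout = Path(config.input_dir) / "layout.yaml"
        return read_plate(config.input_dir, layout)
    gen = config.params.get("generator", "monolayer")
    p = dict(config.params.get("generator_params", {}))
    p.setdefault("seed", config.seed)
    if gen == "monolayer":
        p.setdefault("n_cells", 50)
        pset, _ = synth.generate_monolayer_timelapse(**p)
    elif gen == "aggregation":
        p.setdefault("counts_per_class", {"single": 5, "grouped": 3, "aggregate": 2, "spheroid": 1})
        pset, _ = synth.generate_aggregation_field(**p)
    elif gen == "fibers":
        p.setdefault("n_fibers", 3)
        pset, _ = synth.generate_fiber_stack(**p)
    else:
        raise ValueError(f"unknown generator {gen!r}")
    return pset


def run_workflow(config: RunConfig) -> dict:
    """Execute the configured workflow and write the output bundle.

    Outputs (tables as CSV, summaries and provenance as JSON) are
    written to ``config.outdir`` when set; the result dict is returned
    either way.  Identical config + seed produce identical outputs.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    if config.workflow == "synth":
        pset = _load_inputs(config)
        result = {"plate": pset}
        if outdir:
            write_plate(pset, outdir / "images")
    elif config.workflow == "monolayer":
        result = workflow_monolayer(_load_inputs(config))
    elif config.workflow == "aggregates":
        cfg = dict(config.params)
        cfg.setdefault("generator", "aggregation")
        result = workflow_aggregates(_load_inputs(dataclasses.replace(config, params=cfg)))
    elif config.workflow == "fibers":
        cfg = dict(config.params)
        cfg.setdefault("generator", "fibers")
        result = workflow_fibers(_load_inputs(dataclasses.replace(config, params=cfg)))
    elif config.workflow == "coculture":
        p = dict(config.params.get("generator_params", {}))
        n_a = p.pop("n_a", 30)
        n_b = p.pop("n_b", 30)
        spec = config.params.get("classifier_spec") or ClassifierSpec(
            hidden_layers=tuple(config.params.get("hidden_layers", (350, 224, 128, 96, 96))),
            seed=config.seed)
        mono_a, _ = synth.generate_coculture_timelapse(n_a=n_a, n_b=0, seed=config.seed, **p)
        mono_b, _ = synth.generate_coculture_timelapse(n_a=0, n_b=n_b, seed=config.seed + 1, **p)
        cocult, gt = synth.generate_coculture_timelapse(n_a=n_a, n_b=n_b, seed=config.seed + 2, **p)
        result = workflow_coculture(mono_a, mono_b, cocult, spec=spec,
                                    threshold=config.params.get("threshold", 0.6))
        result["ground_truth"] = gt
    elif config.workflow == "cellcycle":
        p = dict(config.params.get("generator_params", {}))
        p.setdefault("n", 5000)
        p.setdefault("seed", config.seed)
        values, gt = synth.generate_dna_content(**p)
        summary = gate_cell_cycle(values, t1=config.params.get("t1", 1.4),
                                  t2=config.params.get("t2", 1.75))
        result = {"values": values, "summary": summary, "ground_truth": gt}
    else:  # pragma: no cover - guarded by RunConfig
        raise ValueError(config.workflow)

    if outdir:
        _write_bundle(result, config, outdir)
    return result


def _write_bundle(result: dict, config: RunConfig, outdir: Path) -> None:
    if isinstance(result.get("object_table"), pd.DataFrame):
        write_table(result["object_table"], outdir / "object_table.csv")
    if "traces" in result:
        write_table(traces_to_frame(result["traces"]), outdir / "traces.csv")
    if "summaries" in result:
        payload = [dataclasses.asdict(s) for s in result["summaries"]]
        (outdir / "response_summaries.json").write_text(json.dumps(payload, indent=2))
    if "summary" in result:
        s = result["summary"]
        (outdir / "cellcycle_summary.json").write_text(json.dumps(dataclasses.asdict(s), indent=2))
    if "classes" in result:
        write_table(result["classes"], outdir / "aggregation_classes.csv")
    if "assignments" in result:
        write_table(result["assignments"], outdir / "score_assignments.csv")
    provenance = {
        "package_version": _pkg_version,
        "workflow": config.workflow,
        "seed": config.seed,
        "params": _jsonable(config.params),
        "input_dir": str(config.input_dir) if config.input_dir else None,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
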