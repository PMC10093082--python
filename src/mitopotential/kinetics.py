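"""Basal-normalised TMRM kinetic traces and treatment-response summaries.

Per-object background-corrected intensities are averaged into group
traces (per object, well, condition or aggregation class), divided by
the basal value of a reference trace (itself by default), and summarised
as the mean normalised level under oligomycin (hyperpolarisation if
> 1) and under FCCP (depolarisation if < 1).  Negative corrected
intensities are retained before averaging — clipping would bias
low-signal wells — but a non-positive group basal aborts normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPINGS = ("object", "aggregation_class", "well", "condition")

#: maximum nearest-centroid displacement (px) when linking objects across timepoints
MAX_LINK_DISPLACEMENT = 15.0


@dataclass
class KineticTrace:
    group_id: str
    timepoints: list[int]
    treatments: list[str]
    corrected: list[float]
    normalized: list[float] = field(default_factory=list)
    reference_condition: str = "self"
    incomplete: bool = False
    n_objects: int = 1


@dataclass
class ResponseSummary:
    group_id: str
    oligo_ratio: float
    fccp_ratio: float
    hyperpolarized: bool
    depolarized: bool


def _link_objects(table: pd.DataFrame) -> pd.DataFrame:
    """Assign a stable track ID per object across timepoints by nearest centroid.

    Objects are re-detected independently at each timepoint; a track
    continues when the nearest centroid at the next timepoint lies
    within ``MAX_LINK_DISPLACEMENT`` px, otherwise a new track starts.
    """
    from scipy.spatial.distance import cdist
    from scipy.optimize import linear_sum_assignment

    table = table.copy()
    table["track_id"] = -1
    next_track = 0
    for (well, fld), sub in table.groupby(["well", "field"], sort=False):
        tps = sorted(sub["timepoint_index"].unique())
        prev_idx, prev_pos, prev_tracks = None, None, None
        for tp in tps:
            cur = sub[sub["timepoint_index"] == tp]
            pos = cur[["centroid_row", "centroid_col"]].to_numpy()
            tracks = np.full(len(cur), -1, dtype=int)
            if prev_pos is not None and len(prev_pos) and len(pos):
                d = cdist(pos, prev_pos)
                ri, ci = linear_sum_assignment(d)
                for i, j in zip(ri, ci):
                    if d[i, j] <= MAX_LINK_DISPLACEMENT:
                        tracks[i] = prev_tracks[j]
            for i in range(len(tracks)):
                if tracks[i] < 0:
                    tracks[i] = next_track
                    next_track += 1
            table.loc[cur.index, "track_id"] = tracks
            prev_pos, prev_tracks = pos, tracks
    return table


def build_traces(object_table: pd.DataFrame, grouping: str = "well",
                 treatments: dict[int, str] | None = None) -> list[KineticTrace]:
    """Aggregate a per-object intensity table into per-group kinetic traces.

    ``grouping`` is one of object / aggregation_class / well /
    condition; the per-group corrected value at each timepoint is the
    mean over member objects.  With ``grouping="object"`` objects are
    linked across timepoints by nearest centroid.  A group missing any
    timepoint is flagged ``incomplete`` (excluded from summaries).
    ``treatments`` maps timepoint index → treatment name.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    tps = sorted(object_table["timepoint_index"].unique())
    if len(tps) < 2:
        raise ValueError("need at least 2 timepoints to build traces")
    treatments = treatments or {}

    if grouping == "object":
        if "centroid_row" not in object_table.columns:
            raise ValueError("object grouping requires centroid columns for linking")
        table = _link_objects(object_table)
        key = "track_id"
    elif grouping == "aggregation_class":
        if "aggregation_class" not in object_table.columns:
            raise ValueError("table has no aggregation_class column")
        table, key = object_table, "aggregation_class"
    elif grouping == "condition":
        if "condition" not in object_table.columns:
            raise ValueError("table has no condition column")
        table, key = object_table, "condition"
    else:
        table, key = object_table, "well"

    traces = []
    for gid, sub in table.groupby(key, sort=True):
        means = sub.groupby("timepoint_index")["corrected_intensity"].mean()
        corrected = [float(means[tp]) if tp in means.index else np.nan for tp in tps]
        traces.append(KineticTrace(
            group_id=str(gid), timepoints=list(tps),
            treatments=[treatments.get(tp, "") for tp in tps],
            corrected=corrected,
            incomplete=any(np.isnan(corrected)),
            n_objects=int(sub["object_id"].nunique() if "object_id" in sub else len(sub)),
        ))
    return traces


def normalize_to_basal(traces: list[KineticTrace],
                       reference: str | KineticTrace | None = None) -> list[KineticTrace]:
    """Fill ``normalized`` by dividing by a single basal reference value.

    By default each trace is normalised to its own basal timepoint
    (the first timepoint labelled basal, else the first timepoint);
    pass a reference trace (or its group_id) to normalise a co-culture
    trace to, e.g., the monoculture basal.  A basal value ≤ 0 raises,
    naming the trace.
    """
    def basal_value(tr: KineticTrace) -> float:
        if "basal" in tr.treatments:
            idx = tr.treatments.index("basal")
        else:
            idx = 0
        return tr.corrected[idx]

    ref_trace = None
    if isinstance(reference, KineticTrace):
        ref_trace = reference
    elif isinstance(reference, str) and reference != "self":
        matches = [t for t in traces if t.group_id == reference]
        if not matches:
            raise KeyError(f"reference trace {reference!r} not found")
        ref_trace = matches[0]

    out = []
    for tr in traces:
        denom_trace = ref_trace if ref_trace is not None else tr
        denom = basal_value(denom_trace)
        if not denom > 0:
            raise ValueError(
                f"basal value of trace {denom_trace.group_id!r} is {denom}; cannot normalize")
        out.append(KineticTrace(
            group_id=tr.group_id, timepoints=tr.timepoints, treatments=tr.treatments,
            corrected=tr.corrected,
            normalized=[c / denom for c in tr.corrected],
            reference_condition=denom_trace.group_id if ref_trace is not None else "self",
            incomplete=tr.incomplete, n_objects=tr.n_objects,
        ))
    return out


def summarize_response(trace: KineticTrace,
                       timepoint_treatments: dict[int, str] | None = None) -> ResponseSummary:
    """Mean normalised level per treatment; hyper/depolarisation flags.

    ``oligo_ratio`` is the mean normalised value over oligomycin
    timepoints and ``fccp_ratio`` over FCCP timepoints; flags are
    strict comparisons with 1.
    """
    if not trace.normalized:
        raise ValueError("trace must be normalized first")
    treatments = (list(timepoint_treatments.get(tp, "") for tp in trace.timepoints)
                  if timepoint_treatments else trace.treatments)
    oligo = [v for v, t in zip(trace.normalized, treatments) if t == "oligomycin"]
    fccp = [v for v, t in zip(trace.normalized, treatments) if t == "fccp"]
    if not oligo or not fccp:
        raise ValueError("trace needs at least one oligomycin and one FCCP timepoint")
    oligo_ratio = float(np.mean(oligo))
    fccp_ratio = float(np.mean(fccp))
    return ResponseSummary(
        group_id=trace.group_id, oligo_ratio=oligo_ratio, fccp_ratio=fccp_ratio,
        hyperpolarized=oligo_ratio > 1, depolarized=fccp_ratio < 1,
    )


def traces_to_frame(traces: list[KineticTrace]) -> pd.DataFrame:
    """Long-format trace table: group, timepoint, treatment, corrected, normalized."""
    rows = []
    for tr in traces:
        for i, tp in enumerate(tr.timepoints):
            rows.append({
                "group": tr.group_id, "timepoint_index": tp,
                "treatment": tr.treatments[i] if tr.treatments else "",
                "corrected": tr.corrected[i],
                "normalized": tr.normalized[i] if tr.normalized else np.nan,
                "reference": tr.reference_condition, "n_objects": tr.n_objects,
            })
    return pd.DataFrame(rows)
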