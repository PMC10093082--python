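"""Plate image and table I/O plus the experiment metadata model.

A plate acquisition is a dense grid (well, field, channel, timepoint,
plane) of single-plane TIFF images.  The grid and the treatment applied
at each timepoint come from a YAML layout file; filenames follow the
documented ``r{row}c{col}f{field}ch{channel}t{time}z{plane}.tiff``
pattern unless the layout overrides it.  Intensities are held as
float32 internally regardless of the on-disk integer dtype, because
background correction produces non-integers.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

CHANNELS = ("brightfield", "hoechst", "tmrm")
TREATMENTS = ("basal", "oligomycin", "fccp")

#: default filename pattern; row/col parsed from well IDs like "B02"
DEFAULT_PATTERN = "r{row:02d}c{col:02d}f{field:02d}ch{channel}t{time:02d}z{plane:02d}.tiff"


@dataclass(frozen=True)
class TimepointInfo:
    """One acquisition timepoint and the treatment present in the well."""

    index: int
    treatment: str
    time_s: float = 0.0

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}")


def _check_treatment_order(timepoints: Sequence[TimepointInfo]) -> None:
    order = {t: i for i, t in enumerate(TREATMENTS)}
    ranks = [order[tp.treatment] for tp in timepoints]
    if ranks != sorted(ranks):
        raise ValueError("treatments must appear in order basal -> oligomycin -> fccp")
    if order["basal"] not in ranks:
        raise ValueError("at least one basal timepoint is required")


@dataclass
class PlateImageSet:
    """In-memory plate acquisition: a dense image grid plus metadata.

    ``images`` maps ``(well, field, channel, timepoint_index, plane)`` to a
    2-D nonnegative float array; every key of the declared grid must be
    present and all images share one shape.
    """

    wells: list[str]
    fields_per_well: int
    channels: list[str]
    timepoints: list[TimepointInfo]
    planes: int = 1
    plane_spacing_um: float = 0.0
    pixel_size_um: float = 1.0
    images: dict[tuple, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for ch in self.channels:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
        _check_treatment_order(self.timepoints)
        if self.planes > 1 and self.plane_spacing_um <= 0:
            raise ValueError("plane_spacing_um must be > 0 for multi-plane sets")
        if self.images:
            self.validate()

    # -- grid helpers -------------------------------------------------
    def grid_keys(self):
        for well in self.wells:
            for fld in range(self.fields_per_well):
                for ch in self.channels:
                    for tp in self.timepoints:
                        for z in range(self.planes):
                            yield (well, fld, ch, tp.index, z)

    def validate(self) -> None:
        shape = None
        for key in self.grid_keys():
            if key not in self.images:
                raise KeyError(f"missing image for grid key {key}")
            img = self.images[key]
            if img.ndim != 2 or np.min(img) < 0:
                raise ValueError(f"image at {key} must be 2-D nonnegative")
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(f"image shape mismatch at {key}: {img.shape} != {shape}")

    def get(self, well, fld, channel, timepoint, plane=0) -> np.ndarray:
        return self.images[(well, fld, channel, timepoint, plane)]

    def stack(self, well, fld, channel, timepoint) -> np.ndarray:
        """All planes for one (well, field, channel, timepoint), shape (planes, H, W)."""
        return np.stack([self.get(well, fld, channel, timepoint, z) for z in range(self.planes)])

    def treatment_of(self, timepoint_index: int) -> str:
        for tp in self.timepoints:
            if tp.index == timepoint_index:
                return tp.treatment
        raise KeyError(f"no timepoint with index {timepoint_index}")


# ---------------------------------------------------------------------
# layout config


_WELL_RE = re.compile(r"^([A-P])(\d{2})$")


def well_to_rowcol(well: str) -> tuple[int, int]:
    m = _WELL_RE.match(well)
    if not m:
        raise ValueError(f"well ID {well!r} not of form letter+2 digits (e.g. 'B02')")
    return ord(m.group(1)) - ord("A") + 1, int(m.group(2))


def _layout_to_imageset(layout: Mapping) -> PlateImageSet:
    tps = [
        TimepointInfo(index=t["index"], treatment=t["treatment"], time_s=float(t.get("time_s", 0.0)))
        for t in layout["timepoints"]
    ]
    return PlateImageSet(
        wells=list(layout["wells"]),
        fields_per_well=int(layout["fields_per_well"]),
        channels=list(layout["channels"]),
        timepoints=tps,
        planes=int(layout.get("planes", 1)),
        plane_spacing_um=float(layout.get("plane_spacing_um", 0.0)),
        pixel_size_um=float(layout.get("pixel_size_um", 1.0)),
    )


def image_filename(layout: Mapping, well: str, fld: int, channel: str, timepoint: int, plane: int) -> str:
    pattern = layout.get("pattern", DEFAULT_PATTERN)
    row, col = well_to_rowcol(well)
    ch_num = list(layout["channels"]).index(channel) + 1
    return pattern.format(row=row, col=col, field=fld + 1, channel=ch_num, time=timepoint, plane=plane)


def read_layout(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_plate(directory, layout_config) -> PlateImageSet:
    """Read a plate image set from ``directory`` as declared by the layout.

    ``layout_config`` is a mapping or a path to a YAML file declaring
    wells, fields_per_well, channels, timepoints (with treatments),
    planes and the filename pattern.  Every declared grid key must
    resolve to a file; a missing file raises ``FileNotFoundError``
    naming the grid key.
    """
    directory = Path(directory)
    if not isinstance(layout_config, Mapping):
        layout_config = read_layout(layout_config)
    pset = _layout_to_imageset(layout_config)
    shape = None
    for key in pset.grid_keys():
        well, fld, ch, tpi, z = key
        fname = image_filename(layout_config, well, fld, ch, tpi, z)
        fpath = directory / fname
        if not fpath.exists():
            raise FileNotFoundError(f"missing image for grid key {key}: {fpath}")
        img = np.asarray(tifffile.imread(fpath), dtype=np.float32)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"image shape mismatch at {key}: {img.shape} != {shape}")
        pset.images[key] = img
    pset.validate()
    return pset


def write_plate(pset: PlateImageSet, directory, pattern: str = DEFAULT_PATTERN) -> dict:
    """Write all images as TIFFs plus a ``layout.yaml``; returns the layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layout = {
        "wells": list(pset.wells),
        "fields_per_well": pset.fields_per_well,
        "channels": list(pset.channels),
        "timepoints": [
            {"index": tp.index, "treatment": tp.treatment, "time_s": tp.time_s} for tp in pset.timepoints
        ],
        "planes": pset.planes,
        "plane_spacing_um": pset.plane_spacing_um,
        "pixel_size_um": pset.pixel_size_um,
        "pattern": pattern,
    }
    for key in pset.grid_keys():
        well, fld, ch, tpi, z = key
        fname = image_filename(layout, well, fld, ch, tpi, z)
        tifffile.imwrite(directory / fname, np.asarray(pset.images[key], dtype=np.float32))
    with open(directory / "layout.yaml", "w") as fh:
        yaml.safe_dump(layout, fh, sort_keys=False)
    return layout


# ---------------------------------------------------------------------
# tables

#: canonical column order for per-object intensity tables
OBJECT_TABLE_COLUMNS = [
    "well",
    "field",
    "timepoint_index",
    "object_id",
    "roi_mean_intensity",
    "ring_mean_intensity",
    "corrected_intensity",
    "object_area_px",
]


def write_table(table: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a table as CSV or JSON, losslessly for numeric columns.

    JSON goes through the stdlib encoder (``repr``-exact floats); pandas'
    own JSON writer truncates doubles.  Columns absent from the table
    (e.g. ``aggregation_class``) are simply not emitted.
    """
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "json":
        records = table.to_dict(orient="list")
        clean = {
            k: [v if not (isinstance(v, float) and np.isnan(v)) else None for v in vals]
            for k, vals in records.items()
        }
        path.write_text(json.dumps({"columns": list(table.columns), "data": clean}))
    else:
        raise ValueError(f"unsupported table format {format!r}; expected 'csv' or 'json'")


def read_table(path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["data"], columns=payload["columns"])
    raise ValueError(f"unsupported table format {format!r}")
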