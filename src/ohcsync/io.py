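"""File formats: traces CSV, cell-map JSON, wave-catalog JSON, TIFF movies,
run reports.

Trace CSV layout: commented header lines carrying the frame rate and units,
then a header row ``id,x_um,y_um,row,f0,f1,...`` and one row per cell.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .containers import CellMap, FluorescenceMovie, TraceMatrix
from .waves import WaveCatalog

_META_COLS = ["id", "x_um", "y_um", "row"]


def write_traces_csv(traces: TraceMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz: {traces.frame_rate_hz}\n")
        fh.write(f"# units: {traces.units}\n")
        frame_cols = [f"f{i}" for i in range(traces.n_frames)]
        fh.write(",".join(_META_COLS + frame_cols) + "\n")
        n = traces.n_cells
        if traces.cells is not None:
            meta = traces.cells[_META_COLS].to_numpy(object)
        else:
            meta = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n),
                                    np.ones(n, dtype=int)]).astype(object)
        for k in range(n):
            row = [str(v) for v in meta[k]]
            row += [format(v, ".6g") for v in traces.values[k]]
            fh.write(",".join(row) + "\n")


def read_traces_csv(path) -> TraceMatrix:
    path = Path(path)
    frame_rate = None
    units = "raw"
    header = None
    meta_rows, value_rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("frame_rate_hz:"):
                    frame_rate = float(body.split(":", 1)[1])
                elif body.startswith("units:"):
                    units = body.split(":", 1)[1].strip()
                continue
            fields = line.split(",")
            if header is None:
                header = fields
                if header[: len(_META_COLS)] != _META_COLS:
                    raise ValueError(
                        f"{path}: line {lineno}: expected header starting "
                        f"with {_META_COLS}")
                continue
            if len(fields) != len(header):
                raise ValueError(f"{path}: ragged row at line {lineno} "
                                 f"({len(fields)} fields, expected {len(header)})")
            meta_rows.append(fields[: len(_META_COLS)])
            value_rows.append([float(v) for v in fields[len(_META_COLS):]])
    if header is None or not value_rows:
        raise ValueError(f"{path}: no trace rows found")
    if frame_rate is None:
        raise ValueError(f"{path}: missing '# frame_rate_hz:' header line")
    cells = pd.DataFrame(meta_rows, columns=_META_COLS)
    cells["x_um"] = cells["x_um"].astype(float)
    cells["y_um"] = cells["y_um"].astype(float)
    cells["row"] = cells["row"].astype(int)
    try:
        cells["id"] = cells["id"].astype(int)
    except ValueError:
        pass
    return TraceMatrix(np.asarray(value_rows, dtype=float), frame_rate,
                       units=units, cells=cells)


def write_cell_map_json(cell_map: CellMap, path) -> None:
    d = {
        "field_um": cell_map.field_um,
        "cells": cell_map.cells[_META_COLS].to_dict(orient="records"),
    }
    if cell_map.ger_band_um is not None:
        d["ger_band"] = {"y_min_um": cell_map.ger_band_um[0],
                         "y_max_um": cell_map.ger_band_um[1]}
    Path(path).write_text(json.dumps(d, indent=1))


def read_cell_map_json(path) -> CellMap:
    d = json.loads(Path(path).read_text())
    cells = pd.DataFrame(d["cells"])
    band = None
    if "ger_band" in d:
        band = (d["ger_band"]["y_min_um"], d["ger_band"]["y_max_um"])
    return CellMap(cells, field_um=d["field_um"], ger_band_um=band)


def write_movie_tiff(movie: FluorescenceMovie, path,
                     dtype=np.uint16) -> None:
    """Write a movie as a multi-page TIFF, scaled into the integer range.

    dF/F0 is a ratio, so the scaling cancels downstream; the scale and
    acquisition metadata travel in the TIFF description tag.
    """
    frames = np.asarray(movie.frames, dtype=float)
    lo, hi = float(frames.min()), float(frames.max())
    span = hi - lo if hi > lo else 1.0
    maxval = np.iinfo(dtype).max
    scaled = ((frames - lo) / span * maxval).astype(dtype)
    meta = {"frame_rate_hz": movie.frame_rate_hz,
            "pixel_size_um": movie.pixel_size_um,
            "y_offset_um": movie.y_offset_um,
            "scale_lo": lo, "scale_hi": hi}
    tifffile.imwrite(path, scaled, description=json.dumps(meta))


def read_movie_tiff(path, frame_rate_hz: Optional[float] = None,
                    pixel_size_um: Optional[float] = None) -> FluorescenceMovie:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = {}
        desc = tf.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    fr = frame_rate_hz or meta.get("frame_rate_hz")
    px = pixel_size_um or meta.get("pixel_size_um")
    if fr is None or px is None:
        raise ValueError("frame rate / pixel size neither given nor in TIFF metadata")
    frames = frames.astype(float)
    if "scale_lo" in meta:
        maxval = np.iinfo(np.uint16).max if frames.max() > 255 else 255
        frames = meta["scale_lo"] + frames / maxval * (meta["scale_hi"] - meta["scale_lo"])
    return FluorescenceMovie(frames, float(fr), float(px),
                             y_offset_um=float(meta.get("y_offset_um", 0.0)))


def write_wave_catalog_json(catalog: WaveCatalog, path) -> None:
    d = {
        "duration_s": catalog.duration_s,
        "events_per_min": catalog.events_per_min,
        "events": [
            {
                "onset_frame": e.onset_frame,
                "peak_frame": e.peak_frame,
                "extension_um": e.extension_um,
                "censored": e.extension_censored,
                "amplitude": e.amplitude,
                "mask_bbox_px": list(e.mask_bbox_px),
            }
            for e in catalog.events
        ],
    }
    Path(path).write_text(json.dumps(d, indent=1))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
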