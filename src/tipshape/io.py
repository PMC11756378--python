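"""Readers and writers for the plain-text interchange formats.

Contour tables (one row per traced PF point) and kymograph trace tables
(one row per traced segment) are CSV with required headers; validation
errors name the offending row.  Writers round-trip losslessly through the
readers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .kymo_dynamics import Calibration, EndHistory, KymoSegment, segments_to_events
from .pf_geometry import MTEndRecord, PFTrace

__all__ = [
    "SchemaError",
    "CONTOUR_COLUMNS",
    "KYMO_COLUMNS",
    "read_contour_table",
    "write_contour_table",
    "read_kymo_table",
    "write_kymo_table",
]

CONTOUR_COLUMNS = ["grid_id", "mt_id", "polarity", "cap_state", "n_pf", "pf_id",
                   "point_index", "x_nm", "y_nm", "z_nm", "origin_index"]
KYMO_COLUMNS = ["mt_id", "segment_index", "dx_px", "dt_frames", "tip_marker"]


class SchemaError(ValueError):
    """A table violates the expected schema; the message names the row."""


def _require_columns(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_contour_table(path: str | Path) -> list[MTEndRecord]:
    """Read PF contour models from CSV into MT-end records.

    Rows are grouped by (grid_id, mt_id); within a PF, points are ordered
    by ``point_index`` (0-based, consecutive).  Row order in the file does
    not matter.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CONTOUR_COLUMNS, path)
    bad_pol = df.loc[~df["polarity"].isin(MTEndRecord._POLARITIES)]
    if len(bad_pol):
        raise SchemaError(f"{path}: unknown polarity {bad_pol['polarity'].iloc[0]!r} "
                          f"at row {bad_pol.index[0] + 2}")
    bad_cap = df.loc[~df["cap_state"].isin(MTEndRecord._CAP_STATES)]
    if len(bad_cap):
        raise SchemaError(f"{path}: unknown cap_state {bad_cap['cap_state'].iloc[0]!r} "
                          f"at row {bad_cap.index[0] + 2}")
    records = []
    for (grid_id, mt_id), end_df in df.groupby(["grid_id", "mt_id"], sort=True):
        traces = []
        for pf_id, pf_df in end_df.groupby("pf_id", sort=True):
            pf_df = pf_df.sort_values("point_index")
            idx = pf_df["point_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                row = pf_df.index[0] + 2
                raise SchemaError(f"{path}: non-consecutive point_index for PF "
                                  f"{pf_id!r} of {mt_id!r} (near row {row})")
            pts = pf_df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
            traces.append(PFTrace(grid_id=str(grid_id), mt_id=str(mt_id),
                                  pf_id=str(pf_id), points=pts,
                                  origin_index=int(pf_df["origin_index"].iloc[0])))
        first = end_df.iloc[0]
        records.append(MTEndRecord(grid_id=str(grid_id), mt_id=str(mt_id),
                                   polarity=str(first["polarity"]),
                                   cap_state=str(first["cap_state"]),
                                   n_pf=int(first["n_pf"]), traces=traces))
    return records


def write_contour_table(ends: Iterable[MTEndRecord], path: str | Path) -> None:
    rows = []
    for end in ends:
        for tr in end.traces:
            for i, (x, y, z) in enumerate(tr.points):
                rows.append({"grid_id": end.grid_id, "mt_id": end.mt_id,
                             "polarity": end.polarity, "cap_state": end.cap_state,
                             "n_pf": end.n_pf, "pf_id": tr.pf_id, "point_index": i,
                             "x_nm": x, "y_nm": y, "z_nm": z,
                             "origin_index": tr.origin_index})
    pd.DataFrame(rows, columns=CONTOUR_COLUMNS).to_csv(path, index=False)


def read_kymo_table(path: str | Path, calib: Calibration,
                    observation_span: float | None = None) -> list[EndHistory]:
    """Read traced kymograph segments and build per-MT event histories.

    Events are pre-classification (sign rule + pause rule applied per
    segment); run :func:`tipshape.kymo_dynamics.classify_pauses` on each
    history's events for merged pauses.  An empty file returns an empty
    list.  *observation_span* defaults to the summed duration per MT.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        return []
    _require_columns(df, KYMO_COLUMNS, path)
    bad = df.loc[df["dt_frames"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: non-positive dt_frames at row {bad.index[0] + 2}")
    histories = []
    for mt_id, mt_df in df.groupby("mt_id", sort=True):
        mt_df = mt_df.sort_values("segment_index")
        segments = [KymoSegment(mt_id=str(mt_id), dx=float(r.dx_px),
                                dt=float(r.dt_frames),
                                tip_marker_present=bool(r.tip_marker))
                    for r in mt_df.itertuples()]
        events = segments_to_events(segments, calib)
        total = sum(e.duration for e in events)
        span = observation_span if observation_span is not None else total
        histories.append(EndHistory(mt_id=str(mt_id), events=events,
                                    observation_span=max(span, total)))
    return histories


def write_kymo_table(segments: Iterable[KymoSegment], path: str | Path) -> None:
    rows = []
    counters: dict[str, int] = {}
    for seg in segments:
        i = counters.get(seg.mt_id, 0)
        counters[seg.mt_id] = i + 1
        rows.append({"mt_id": seg.mt_id, "segment_index": i, "dx_px": seg.dx,
                     "dt_frames": seg.dt, "tip_marker": int(seg.tip_marker_present)})
    pd.DataFrame(rows, columns=KYMO_COLUMNS).to_csv(path, index=False)
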