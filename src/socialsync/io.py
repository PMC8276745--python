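"""Plain-text readers and writers for every pipeline artifact.

Dialect: UTF-8 TSV, '.' decimal, with ``#``-prefixed ``key=value`` metadata
lines before the header row. All writers round-trip exactly with their
readers on valid files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ConfoundBundle,
    EventTable,
    ROIRoster,
    ROITimeSeries,
    ValidationError,
)

_FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    """Raised when a file cannot be parsed; names the offending line."""


# --------------------------------------------------------------------------
# low-level helpers
# --------------------------------------------------------------------------

def _read_tsv_lines(path: str | Path) -> tuple[dict[str, str], list[str], list[list[str]], list[int]]:
    """Split a TSV file into metadata, header and body rows.

    Returns (meta, header, rows, line_numbers) where line numbers are
    1-based positions of the body rows in the file.
    """
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    linenos: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                continue
            rows.append(cells)
            linenos.append(lineno)
    if header is None:
        raise ParseError(f"{path}: no header row found")
    width = len(header)
    for cells, lineno in zip(rows, linenos):
        if len(cells) != width:
            raise ParseError(
                f"{path}: line {lineno}: expected {width} columns, got {len(cells)}"
            )
    return meta, header, rows, linenos


def _to_float(cell: str, path, lineno: int, col: str) -> float:
    try:
        value = float(cell)
    except ValueError as exc:
        raise ParseError(f"{path}: line {lineno}: non-numeric cell in {col!r}: {cell!r}") from exc
    if np.isnan(value):
        raise ParseError(f"{path}: line {lineno}: missing value (NaN) in column {col!r}")
    return value


def _write_tsv(path: str | Path, meta: dict, header: list[str], columns: list[np.ndarray]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write("\t".join(header) + "\n")
        n = len(columns[0]) if columns else 0
        for r in range(n):
            cells = []
            for col in columns:
                v = col[r]
                cells.append(_FLOAT_FMT % v if isinstance(v, (float, np.floating)) else str(v))
            fh.write("\t".join(cells) + "\n")


# --------------------------------------------------------------------------
# ROI time series
# --------------------------------------------------------------------------

def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    meta = {
        "tr_s": _FLOAT_FMT % ts.tr_s,
        "run_boundaries": ",".join(str(b) for b in ts.run_starts),
    }
    cols = [ts.values[:, k] for k in range(ts.n_rois)]
    _write_tsv(path, meta, list(ts.roi_labels), cols)


def read_timeseries(path: str | Path) -> ROITimeSeries:
    meta, header, rows, linenos = _read_tsv_lines(path)
    if "tr_s" not in meta:
        raise ParseError(f"{path}: missing '# tr_s=' metadata line")
    tr_s = float(meta["tr_s"])
    run_starts = [int(x) for x in meta.get("run_boundaries", "0").split(",") if x != ""]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ParseError(f"{path}: duplicate ROI labels {dupes}")
    values = np.empty((len(rows), len(header)), dtype=float)
    for r, (cells, lineno) in enumerate(zip(rows, linenos)):
        for c, cell in enumerate(cells):
            values[r, c] = _to_float(cell, path, lineno, header[c])
    try:
        return ROITimeSeries(values=values, tr_s=tr_s, roi_labels=header, run_starts=run_starts)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------

def write_events(events: EventTable, path: str | Path) -> None:
    df = events.frame
    cols = [
        df["onset_s"].to_numpy(dtype=float),
        df["duration_s"].to_numpy(dtype=float),
        df["category"].to_numpy(dtype=object),
        df["n_actors"].astype(str).to_numpy(dtype=object),
    ]
    _write_tsv(path, {}, ["onset_s", "duration_s", "category", "n_actors"], cols)


def read_events(path: str | Path) -> EventTable:
    _, header, rows, linenos = _read_tsv_lines(path)
    required = ["onset_s", "duration_s", "category", "n_actors"]
    if header[: len(required)] != required:
        raise ParseError(f"{path}: header must start with {required}, got {header}")
    idx = {name: header.index(name) for name in required}
    records = []
    for cells, lineno in zip(rows, linenos):
        records.append(
            {
                "onset_s": _to_float(cells[idx["onset_s"]], path, lineno, "onset_s"),
                "duration_s": _to_float(cells[idx["duration_s"]], path, lineno, "duration_s"),
                "category": cells[idx["category"]],
                "n_actors": cells[idx["n_actors"]],
            }
        )
    try:
        return EventTable(pd.DataFrame.from_records(records, columns=required))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# confounds (volume-level file + sibling frame-level file)
# --------------------------------------------------------------------------

def _frames_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + "_frames" + path.suffix)


def write_confounds(bundle: ConfoundBundle, path: str | Path) -> None:
    """Write volume-level series to ``path`` and frame-level series to a
    sibling ``*_frames.tsv`` file."""
    meta = {
        "frame_rate_hz": _FLOAT_FMT % bundle.frame_rate_hz,
        "reward_times_s": ",".join(_FLOAT_FMT % t for t in bundle.reward_times_s),
    }
    _write_tsv(path, meta, ["fixation_frac", "csf"], [bundle.fixation_frac, bundle.csf])
    _write_tsv(
        _frames_path(path),
        {},
        ["luminance", "motion", "gaze_x", "gaze_y"],
        [bundle.luminance, bundle.motion, bundle.gaze_xy[:, 0], bundle.gaze_xy[:, 1]],
    )


def read_confounds(path: str | Path) -> ConfoundBundle:
    meta, header, rows, linenos = _read_tsv_lines(path)
    vol = {name: np.empty(len(rows)) for name in header}
    for r, (cells, lineno) in enumerate(zip(rows, linenos)):
        for c, name in enumerate(header):
            vol[name][r] = _to_float(cells[c], path, lineno, name)
    fpath = _frames_path(path)
    _, fheader, frows, flinenos = _read_tsv_lines(fpath)
    frame = {name: np.empty(len(frows)) for name in fheader}
    for r, (cells, lineno) in enumerate(zip(frows, flinenos)):
        for c, name in enumerate(fheader):
            frame[name][r] = _to_float(cells[c], fpath, lineno, name)
    rewards = [float(x) for x in meta.get("reward_times_s", "").split(",") if x != ""]
    try:
        return ConfoundBundle(
            luminance=frame["luminance"],
            motion=frame["motion"],
            gaze_xy=np.column_stack([frame["gaze_x"], frame["gaze_y"]]),
            fixation_frac=vol["fixation_frac"],
            csf=vol["csf"],
            reward_times_s=np.asarray(rewards),
            frame_rate_hz=float(meta.get("frame_rate_hz", 25.0)),
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# ROI roster
# --------------------------------------------------------------------------

def write_roster(roster: ROIRoster, path: str | Path) -> None:
    header = ["label", "hemisphere", "group"]
    cols: list[np.ndarray] = [
        np.asarray(roster.labels, dtype=object),
        np.asarray(roster.hemispheres, dtype=object),
        np.asarray(roster.groups, dtype=object),
    ]
    if roster.coords_mm is not None:
        header += ["x", "y", "z"]
        cols += [roster.coords_mm[:, k] for k in range(3)]
    _write_tsv(path, {}, header, cols)


def read_roster(path: str | Path) -> ROIRoster:
    _, header, rows, linenos = _read_tsv_lines(path)
    need = ["label", "hemisphere", "group"]
    if header[:3] != need:
        raise ParseError(f"{path}: header must start with {need}")
    labels = [cells[0] for cells in rows]
    hemis = [cells[1] for cells in rows]
    groups = [cells[2] for cells in rows]
    coords = None
    if header[3:6] == ["x", "y", "z"]:
        coords = np.array(
            [
                [_to_float(cells[3 + k], path, lineno, "xyz"[k]) for k in range(3)]
                for cells, lineno in zip(rows, linenos)
            ]
        )
    try:
        return ROIRoster(labels=labels, hemispheres=hemis, groups=groups, coords_mm=coords)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# generic frames and manifests
# --------------------------------------------------------------------------

def write_frame(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write an arbitrary tidy DataFrame in the pipeline TSV dialect."""
    cols = []
    for name in df.columns:
        s = df[name]
        if pd.api.types.is_float_dtype(s):
            cols.append(s.to_numpy(dtype=float))
        else:
            cols.append(s.to_numpy(dtype=object))
    _write_tsv(path, meta or {}, [str(c) for c in df.columns], cols)


def read_frame(path: str | Path) -> pd.DataFrame:
    _, header, rows, _ = _read_tsv_lines(path)
    df = pd.DataFrame(rows, columns=header)
    for name in header:
        try:
            converted = df[name].astype(float)
        except ValueError:
            continue
        if (converted.dropna() == converted.dropna().astype(int)).all() and not converted.isna().any():
            converted = converted.astype(int)
        df[name] = converted
    return df


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
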