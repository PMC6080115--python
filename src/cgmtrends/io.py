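"""Readers and writers for the study file dialects.

All files are plain delimited text with a header row:

* traces:  ``sensor_id,participant_id,system,time_min,glucose_mgdl``
  (the BG reference uses the same dialect with ``system=BG``)
* diary:   ``participant_id,system,sensor_id,time_min,arrow,visit``
  (``visit`` is 1/2/3 or ``home``; ``arrow`` uses the ASCII alias table)
* events:  ``participant_id,time_min,kind,amount``
* manifest: YAML echo of the generating config and bookkeeping counts.

``read_study`` validates schemas and values; in lenient mode malformed rows
are skipped and logged with their row number instead of aborting.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .concordance import DiaryRecord
from .errors import SchemaError, TrendParseError
from .events import EVENT_KINDS, TherapyEvent
from .profiles import PROFILES, arrow_symbol, parse_arrow_symbol
from .simulate import Study
from .traces import GlucoseTrace

__all__ = ["write_study", "read_study", "STUDY_FILES"]

logger = logging.getLogger(__name__)

STUDY_FILES = {
    "traces": "traces.csv",
    "bg": "bg.csv",
    "diary": "diary.csv",
    "events": "events.csv",
    "manifest": "manifest.yaml",
}

_TRACE_COLS = ["sensor_id", "participant_id", "system", "time_min", "glucose_mgdl"]
_DIARY_COLS = ["participant_id", "system", "sensor_id", "time_min", "arrow", "visit"]
_EVENT_COLS = ["participant_id", "time_min", "kind", "amount"]


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Emit a study to ``out_dir`` in the standard dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in STUDY_FILES.items()}

    rows = []
    for sensor_id, trace in sorted(study.traces.items()):
        pid, system = study.trace_meta[sensor_id]
        rows.append(
            pd.DataFrame(
                {
                    "sensor_id": sensor_id,
                    "participant_id": pid,
                    "system": system,
                    "time_min": trace.times,
                    "glucose_mgdl": np.round(trace.values, 6),
                }
            )
        )
    _concat(rows, _TRACE_COLS).to_csv(paths["traces"], index=False)

    rows = []
    for pid, trace in sorted(study.bg.items()):
        rows.append(
            pd.DataFrame(
                {
                    "sensor_id": trace.sensor_id,
                    "participant_id": pid,
                    "system": "BG",
                    "time_min": trace.times,
                    "glucose_mgdl": np.round(trace.values, 6),
                }
            )
        )
    _concat(rows, _TRACE_COLS).to_csv(paths["bg"], index=False)

    diary = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in study.diary],
            "system": [r.system for r in study.diary],
            "sensor_id": [r.sensor_id for r in study.diary],
            "time_min": [r.time for r in study.diary],
            "arrow": [arrow_symbol(r.recorded) for r in study.diary],
            "visit": [r.visit if r.visit is not None else "home" for r in study.diary],
        },
        columns=_DIARY_COLS,
    )
    diary.to_csv(paths["diary"], index=False)

    events = pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in study.events],
            "time_min": [e.time for e in study.events],
            "kind": [e.kind for e in study.events],
            "amount": [e.amount if e.amount is not None else "" for e in study.events],
        },
        columns=_EVENT_COLS,
    )
    events.to_csv(paths["events"], index=False)

    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(study.manifest, fh, sort_keys=True)
    return paths


def _concat(frames: list[pd.DataFrame], cols: list[str]) -> pd.DataFrame:
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing required column(s): {', '.join(missing)}")


def read_study(study_dir: str | Path, lenient: bool = False) -> Study:
    """Load a study directory written by :func:`write_study`.

    In strict mode (default) any malformed row aborts with an error naming
    the problem; with ``lenient=True`` malformed diary/event rows are
    skipped and logged with their row numbers.
    """
    d = Path(study_dir)
    traces, trace_meta = _read_traces(d / STUDY_FILES["traces"])
    bg_traces, bg_meta = _read_traces(d / STUDY_FILES["bg"])
    bg = {bg_meta[sid][0]: tr for sid, tr in bg_traces.items()}
    diary = _read_diary(d / STUDY_FILES["diary"], lenient=lenient)
    events = _read_events(d / STUDY_FILES["events"], lenient=lenient)
    manifest = {}
    mpath = d / STUDY_FILES["manifest"]
    if mpath.exists():
        with open(mpath) as fh:
            manifest = yaml.safe_load(fh) or {}
    return Study(diary=diary, traces=traces, trace_meta=trace_meta, bg=bg,
                 events=events, manifest=manifest)


def _read_traces(path: Path) -> tuple[dict[str, GlucoseTrace], dict[str, tuple[str, str]]]:
    df = pd.read_csv(path)
    _require_columns(df, _TRACE_COLS, "trace")
    traces: dict[str, GlucoseTrace] = {}
    meta: dict[str, tuple[str, str]] = {}
    for sensor_id, grp in df.groupby("sensor_id", sort=True):
        times = grp["time_min"].to_numpy(dtype=float)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise SchemaError(f"trace {sensor_id}: time_min must be strictly increasing")
        traces[str(sensor_id)] = GlucoseTrace(
            sensor_id=str(sensor_id),
            times=times,
            values=grp["glucose_mgdl"].to_numpy(dtype=float),
        )
        meta[str(sensor_id)] = (str(grp["participant_id"].iloc[0]), str(grp["system"].iloc[0]))
    return traces, meta


def _read_diary(path: Path, lenient: bool) -> list[DiaryRecord]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _DIARY_COLS, "diary")
    records: list[DiaryRecord] = []
    if df.empty:
        logger.warning("diary file %s contains a header but no records", path)
        return records
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            system = str(row.system)
            if system not in PROFILES:
                raise SchemaError(f"unknown system {system!r}")
            recorded = parse_arrow_symbol(str(row.arrow), PROFILES[system])
            visit_raw = str(row.visit)
            visit = None if visit_raw.lower() == "home" else int(visit_raw)
            records.append(
                DiaryRecord(
                    participant_id=str(row.participant_id),
                    system=system,
                    sensor_id=str(row.sensor_id),
                    time=float(row.time_min),
                    recorded=recorded,
                    visit=visit,
                )
            )
        except (ValueError, TrendParseError, SchemaError) as exc:
            if lenient:
                logger.warning("diary row %d skipped: %s", i, exc)
            else:
                raise
    return records


def _read_events(path: Path, lenient: bool) -> list[TherapyEvent]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _EVENT_COLS, "events")
    events: list[TherapyEvent] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            kind = str(row.kind)
            if kind not in EVENT_KINDS:
                raise SchemaError(f"unknown event kind {kind!r}")
            amount_raw = row.amount
            amount = None
            if amount_raw is not None and str(amount_raw).strip() not in ("", "nan"):
                amount = float(amount_raw)
            events.append(
                TherapyEvent(
                    participant_id=str(row.participant_id),
                    time=float(row.time_min),
                    kind=kind,
                    amount=amount,
                )
            )
        except (ValueError, SchemaError) as exc:
            if lenient:
                logger.warning("events row %d skipped: %s", i, exc)
            else:
                raise
    return events
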