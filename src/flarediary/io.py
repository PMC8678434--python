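"""Reading and writing diary and baseline CSV files.

Two diary dialects are accepted, auto-detected from the header:

* long (canonical): ``participant_id,date,variable,score`` — one row per
  scored variable per participant-day;
* wide: ``participant_id,date,<petal>,<petal>,...`` — one row per
  participant-day, empty cells meaning "not scored".

Dates are ISO-8601 (YYYY-MM-DD). Validation is strict: out-of-range scores,
unknown variable names, malformed dates and duplicate
(participant, date, variable) triples are rejected with the offending row
named, never silently dropped. Parsing never imputes.
"""
from __future__ import annotations

import csv
import datetime as _dt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalogue import DEFAULT_CATALOGUE, PetalCatalogue
from .data import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    BaselineRecord,
    DailyEntry,
    DiaryValidationError,
    ParticipantSeries,
)

LONG_COLUMNS = ("participant_id", "date", "variable", "score")


def _parse_date(raw: str, row_no: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(raw.strip())
    except ValueError as exc:
        raise DiaryValidationError(f"row {row_no}: malformed date {raw!r}") from exc


def _parse_score(raw: str, row_no: int, variable: str) -> int:
    raw = raw.strip()
    try:
        value = int(raw)
    except ValueError as exc:
        raise DiaryValidationError(
            f"row {row_no}: non-integer score {raw!r} for {variable!r}"
        ) from exc
    if not 1 <= value <= 5:
        raise DiaryValidationError(
            f"row {row_no}: score {value} outside 1..5 for {variable!r}"
        )
    return value


def read_daily_entries(
    path: str | Path, catalogue: PetalCatalogue = DEFAULT_CATALOGUE
) -> list[ParticipantSeries]:
    """Read a diary CSV (long or wide dialect) into per-participant series.

    Returns one :class:`ParticipantSeries` per distinct participant id,
    sorted by id, with entries sorted by date.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"diary file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DiaryValidationError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if header[:2] != ["participant_id", "date"]:
            raise DiaryValidationError(
                f"{path}: header must start with participant_id,date "
                f"(got {header[:2]})"
            )
        if header == list(LONG_COLUMNS):
            cells = _read_long(reader, catalogue)
        else:
            cells = _read_wide(reader, header, catalogue)
    return _build_series(cells, catalogue)


def _read_long(reader, catalogue) -> dict[tuple[str, _dt.date], dict[str, int]]:
    cells: dict[tuple[str, _dt.date], dict[str, int]] = {}
    for row_no, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 4:
            raise DiaryValidationError(f"row {row_no}: expected 4 columns, got {len(row)}")
        pid, raw_date, variable, raw_score = (c.strip() for c in row)
        variable = variable.lower()
        if variable not in catalogue:
            raise DiaryValidationError(f"row {row_no}: unknown variable {variable!r}")
        date = _parse_date(raw_date, row_no)
        score = _parse_score(raw_score, row_no, variable)
        day = cells.setdefault((pid, date), {})
        if variable in day:
            raise DiaryValidationError(
                f"row {row_no}: duplicate score for ({pid}, {date}, {variable})"
            )
        day[variable] = score
    return cells


def _read_wide(reader, header, catalogue) -> dict[tuple[str, _dt.date], dict[str, int]]:
    variables = [h.lower() for h in header[2:]]
    for v in variables:
        if v not in catalogue:
            raise DiaryValidationError(f"header: unknown variable column {v!r}")
    if len(set(variables)) != len(variables):
        raise DiaryValidationError("header: duplicate variable columns")
    cells: dict[tuple[str, _dt.date], dict[str, int]] = {}
    for row_no, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        pid = row[0].strip()
        date = _parse_date(row[1], row_no)
        if (pid, date) in cells:
            raise DiaryValidationError(f"row {row_no}: duplicate day ({pid}, {date})")
        day: dict[str, int] = {}
        for v, raw in zip(variables, row[2:]):
            if raw.strip() == "":
                continue
            day[v] = _parse_score(raw, row_no, v)
        cells[(pid, date)] = day
    return cells


def _build_series(cells, catalogue) -> list[ParticipantSeries]:
    by_pid: dict[str, list[DailyEntry]] = {}
    for (pid, date), scores in cells.items():
        entry = DailyEntry(pid, date, dict(sorted(scores.items())))
        entry.validate(catalogue)
        by_pid.setdefault(pid, []).append(entry)
    out = []
    for pid in sorted(by_pid):
        entries = by_pid[pid]
        optional = frozenset(
            v
            for e in entries
            for v in e.scores
            if v in catalogue.optional_variables
        )
        out.append(ParticipantSeries(pid, entries, chosen_optional=optional))
    return out


def write_daily_entries(
    series: Iterable[ParticipantSeries], path: str | Path
) -> None:
    """Write series to the canonical long CSV dialect."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LONG_COLUMNS)
        for s in series:
            for e in s.entries:
                for variable, score in e.scores.items():
                    writer.writerow([s.participant_id, e.date.isoformat(), variable, score])


# --------------------------------------------------------------------------
# Baseline covariates
# --------------------------------------------------------------------------

_BASELINE_COLUMNS = ("participant_id",) + CONTINUOUS_COVARIATES + BINARY_COVARIATES


def read_baseline(path: str | Path) -> list[BaselineRecord]:
    """Read the baseline covariate CSV (one row per participant).

    Columns follow the documented dictionary (``basmi``, ``basdai``, ...,
    ``female``, ``current_smoker``, ...); any subset of covariate columns is
    allowed but unknown columns are an error. Empty cells become missing
    values, never zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"baseline file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "participant_id" not in frame.columns:
        raise DiaryValidationError(f"{path}: missing participant_id column")
    unknown = [c for c in frame.columns if c not in _BASELINE_COLUMNS]
    if unknown:
        raise DiaryValidationError(f"{path}: unknown baseline columns {unknown}")
    records = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        row = row._asdict()
        continuous: dict[str, float | None] = {}
        binary: dict[str, int | None] = {}
        for name in CONTINUOUS_COVARIATES:
            if name not in row:
                continue
            raw = str(row[name]).strip()
            continuous[name] = float(raw) if raw else None
        for name in BINARY_COVARIATES:
            if name not in row:
                continue
            raw = str(row[name]).strip()
            if not raw:
                binary[name] = None
                continue
            try:
                value = int(float(raw))
            except ValueError as exc:
                raise DiaryValidationError(
                    f"row {row_no}: non-numeric value {raw!r} for {name!r}"
                ) from exc
            binary[name] = value
        record = BaselineRecord(str(row["participant_id"]), continuous, binary)
        try:
            record.validate()
        except DiaryValidationError as exc:
            raise DiaryValidationError(f"row {row_no}: {exc}") from None
        records.append(record)
    return records


def write_baseline(records: Iterable[BaselineRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_BASELINE_COLUMNS)
        for r in records:
            row: list[object] = [r.participant_id]
            for name in CONTINUOUS_COVARIATES:
                v = r.continuous.get(name)
                row.append("" if v is None else repr(float(v)))
            for name in BINARY_COVARIATES:
                v = r.binary.get(name)
                row.append("" if v is None else int(v))
            writer.writerow(row)


def series_to_frame(series: Sequence[ParticipantSeries]) -> pd.DataFrame:
    """Long-format DataFrame view (participant_id, date, variable, score)."""
    rows = [
        (s.participant_id, e.date, v, score)
        for s in series
        for e in s.entries
        for v, score in e.scores.items()
    ]
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


def frame_to_series(
    frame: pd.DataFrame, catalogue: PetalCatalogue = DEFAULT_CATALOGUE
) -> list[ParticipantSeries]:
    """Build participant series from a long-format DataFrame."""
    cells: dict[tuple[str, _dt.date], dict[str, int]] = {}
    for pid, date, variable, score in frame[list(LONG_COLUMNS)].itertuples(index=False):
        if isinstance(date, str):
            date = _dt.date.fromisoformat(date)
        elif isinstance(date, pd.Timestamp):
            date = date.date()
        key = (str(pid), date)
        day = cells.setdefault(key, {})
        if variable in day:
            raise DiaryValidationError(f"duplicate score for ({pid}, {date}, {variable})")
        day[str(variable)] = int(score)
    return _build_series(cells, catalogue)
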