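"""Readers and writers for register-style delimited files and YAML configuration."""
from __future__ import annotations

import csv
import logging
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .model import CensoringRecord, PrescriptionRecord, StudyConfig

log = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "atc": "atc",
    "date": "date",
    "quantity": "quantity",
}


def normalize_records(records: Iterable[PrescriptionRecord]) -> list[PrescriptionRecord]:
    """Deduplicate on (patient, product, date) and sort by patient then date."""
    return sorted(set(records))


def read_register(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[PrescriptionRecord]:
    """Read a redemption register from delimited text.

    The file must have a header naming at least the patient, ATC and date
    columns (ISO-8601 dates); a quantity column is optional. Rows with an
    unparseable date or an empty ATC code are rejected with a logged row
    number; exact duplicates on (patient, ATC, date) are collapsed.
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    path = Path(path)
    records: list[PrescriptionRecord] = []
    n_rows = 0
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty register file")
        for required in ("patient_id", "atc", "date"):
            if cols[required] not in reader.fieldnames:
                raise ValueError(f"{path}: missing required column {cols[required]!r}")
        has_qty = cols["quantity"] in reader.fieldnames
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            n_rows += 1
            atc = (row[cols["atc"]] or "").strip()
            raw_date = (row[cols["date"]] or "").strip()
            try:
                when = date.fromisoformat(raw_date)
            except ValueError:
                log.warning("%s row %d: unparseable date %r - row rejected", path, i, raw_date)
                continue
            if not atc:
                log.warning("%s row %d: empty ATC code - row rejected", path, i)
                continue
            qty = None
            if has_qty and (row[cols["quantity"]] or "").strip():
                qty = int(row[cols["quantity"]])
            records.append(PrescriptionRecord(row[cols["patient_id"]].strip(), when, atc, qty))
    if n_rows == 0:
        raise ValueError(f"{path}: register contains no data rows")
    out = normalize_records(records)
    log.info("%s: %d rows read, %d records after parsing/dedup", path, n_rows, len(out))
    return out


def write_register(
    records: Sequence[PrescriptionRecord],
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write records as CSV in canonical (deduplicated, sorted) order."""
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([cols["patient_id"], cols["atc"], cols["date"], cols["quantity"]])
        for rec in normalize_records(records):
            writer.writerow([
                rec.patient_id,
                rec.atc_code,
                rec.redemption_date.isoformat(),
                "" if rec.quantity is None else rec.quantity,
            ])


def to_relative_days(
    records: Iterable[PrescriptionRecord],
    index_dates: Mapping[str, date],
    followup_days: int,
) -> tuple[list[tuple[str, str, int]], int]:
    """Convert calendar redemptions to day indices relative to each patient's index date.

    Day 0 is the index date. Records beyond day ``followup_days - 1`` are
    dropped (their count is returned); a record before the index date is an
    error, because cohort construction should already have excluded it.
    Returns ``(rows, n_dropped)`` with rows ``(patient_id, atc_code, day)``.
    """
    rows: list[tuple[str, str, int]] = []
    dropped = 0
    for rec in records:
        if rec.patient_id not in index_dates:
            raise KeyError(f"no index date for patient {rec.patient_id!r}")
        day = (rec.redemption_date - index_dates[rec.patient_id]).days
        if day < 0:
            raise ValueError(
                f"record for {rec.patient_id!r} on {rec.redemption_date} precedes its index date"
            )
        if day >= followup_days:
            dropped += 1
            continue
        rows.append((rec.patient_id, rec.atc_code, day))
    if dropped:
        log.info("dropped %d redemptions beyond the follow-up window", dropped)
    return rows, dropped


def read_fdc_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a fixed-dose-combination map: ``fdc_atc, component_1, component_2, ...``."""
    out: dict[str, frozenset[str]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty FDC map")
        for i, row in enumerate(reader, start=2):
            cells = [c.strip() for c in row if c.strip()]
            if not cells:
                continue
            if len(cells) < 3:
                raise ValueError(f"{path} row {i}: an FDC needs >= 2 components")
            out[cells[0]] = frozenset(cells[1:])
    return out


def write_fdc_map(fdc_map: Mapping[str, frozenset[str]], path: str | Path) -> None:
    width = max((len(v) for v in fdc_map.values()), default=2)
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fdc_atc"] + [f"component_{i + 1}" for i in range(width)])
        for code in sorted(fdc_map):
            comps = sorted(fdc_map[code])
            writer.writerow([code] + comps + [""] * (width - len(comps)))


def read_censoring(path: str | Path) -> list[CensoringRecord]:
    """Read censoring records: ``patient_id, censor_day, cause``."""
    out: list[CensoringRecord] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CensoringRecord(
                    row["patient_id"].strip(),
                    int(row["censor_day"]),
                    (row.get("cause") or "end_of_followup").strip(),
                )
            )
    return out


def write_censoring(records: Iterable[CensoringRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "censor_day", "cause"])
        for rec in sorted(records, key=lambda r: r.patient_id):
            writer.writerow([rec.patient_id, rec.censor_day, rec.cause])


def load_config(path: str | Path) -> StudyConfig:
    """Load a :class:`StudyConfig` from YAML; keys mirror the dataclass fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("study_window", "enrollment_window"):
        if key in raw:
            lo, hi = raw[key]
            raw[key] = (_as_date(lo), _as_date(hi))
    if "calendar_bins" in raw:
        raw["calendar_bins"] = tuple((int(a), int(b)) for a, b in raw["calendar_bins"])
    if "index_atc_prefixes" in raw:
        raw["index_atc_prefixes"] = tuple(raw["index_atc_prefixes"])
    return StudyConfig(**raw)


def _as_date(value: object) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))
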