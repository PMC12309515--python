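"""Reading, writing and validating the external file formats.

Canonical containers: radiology reports travel as JSONL (one object per
line: report_id, patient_id, scan_date, text) because free text embeds
commas and newlines; EHR tables are plain CSV files (``ct_events.csv``,
``diagnoses.csv``, ``orders.csv``, ``demographics.csv``, ``outcomes.csv``);
fitted models are versioned, human-inspectable JSON documents. All dates
are ISO-8601 calendar dates and window arithmetic elsewhere is in integer
days.

Validation is total: every input either loads, loads with logged warnings,
or fails with a located error — nothing is silently discarded.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import IntegrityError, ParseError

logger = logging.getLogger("ctsurveil")

__all__ = [
    "ReportRecord",
    "EHRBundle",
    "read_reports",
    "write_reports",
    "read_ehr_tables",
    "write_ehr_tables",
    "write_predictions",
    "read_predictions",
    "save_model",
    "load_model",
    "study_to_bundle",
    "write_study",
]

REQUIRED_REPORT_FIELDS = ("report_id", "patient_id", "scan_date", "text")

EHR_TABLES = {
    "ct_events": ("patient_id", "date", "report_id"),
    "diagnoses": ("patient_id", "date", "icd_code"),
    "orders": ("report_id", "provider_specialty"),
    "demographics": ("patient_id", "sex", "race_ethnicity", "stage", "histology"),
    "outcomes": ("patient_id", "time_origin_date", "last_followup_date", "death_indicator"),
}

#: diagnoses dated before this floor are implausible; warned, row retained
DEFAULT_DATE_FLOOR = "1900-01-01"


@dataclass
class ReportRecord:
    report_id: str
    patient_id: str
    scan_date: str  # ISO-8601
    text: str


def _check_date(value: str, where: str) -> None:
    try:
        pd.Timestamp(value)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{where}: unparseable date {value!r}") from exc


def read_reports(path, column_map: dict[str, str] | None = None) -> list[ReportRecord]:
    """Load a report corpus from JSONL (default) or CSV.

    ``column_map`` maps the canonical field names to CSV column headers when
    reading CSV. Malformed lines raise :class:`ParseError` naming the line;
    duplicate report ids raise :class:`IntegrityError` listing the ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ReportRecord] = []
    if path.suffix.lower() == ".csv":
        column_map = column_map or {f: f for f in REQUIRED_REPORT_FIELDS}
        with open(path, newline="") as fh:
            for lineno, row in enumerate(csv.DictReader(fh), start=2):
                try:
                    records.append(ReportRecord(*(str(row[column_map[f]]) for f in
                                                  REQUIRED_REPORT_FIELDS)))
                except KeyError as exc:
                    raise ParseError(f"{path}:{lineno}: missing field {exc}") from exc
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path}:{lineno}: invalid JSON ({exc.msg})") from exc
                missing = [f for f in REQUIRED_REPORT_FIELDS if f not in obj]
                if missing:
                    raise ParseError(f"{path}:{lineno}: missing fields {missing}")
                records.append(ReportRecord(
                    str(obj["report_id"]), str(obj["patient_id"]),
                    str(obj["scan_date"]), str(obj["text"]),
                ))
    seen: dict[str, int] = {}
    dupes = []
    for rec in records:
        _check_date(rec.scan_date, f"report {rec.report_id}")
        seen[rec.report_id] = seen.get(rec.report_id, 0) + 1
    dupes = sorted(rid for rid, k in seen.items() if k > 1)
    if dupes:
        raise IntegrityError(f"duplicate report_id values: {dupes}")
    if not records:
        logger.warning("report corpus at %s is empty", path)
    return records


def write_reports(records, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            obj = rec if isinstance(rec, dict) else {
                "report_id": rec.report_id, "patient_id": rec.patient_id,
                "scan_date": rec.scan_date, "text": rec.text,
            }
            fh.write(json.dumps(obj) + "\n")


@dataclass
class EHRBundle:
    """Structured EHR tables for one cohort, with referential validation."""

    ct_events: pd.DataFrame
    diagnoses: pd.DataFrame
    orders: pd.DataFrame
    demographics: pd.DataFrame
    outcomes: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def validate(self, reports: list[ReportRecord] | None = None,
                 date_floor: str = DEFAULT_DATE_FLOOR) -> "EHRBundle":
        for name, required in EHR_TABLES.items():
            frame = getattr(self, name)
            missing = [c for c in required if c not in frame.columns]
            if missing:
                raise ParseError(f"table {name!r} missing columns {missing}")
        dup = self.demographics["patient_id"][self.demographics["patient_id"].duplicated()]
        if len(dup):
            raise IntegrityError(f"duplicate demographics rows for patients: {sorted(set(dup))}")
        if reports is not None:
            known = {r.report_id for r in reports}
            orphans = sorted(set(self.ct_events["report_id"]) - known)
            if orphans:
                raise IntegrityError(f"ct_events reference unknown report_id values: {orphans[:10]}")
        for col in ("time_origin_date", "last_followup_date"):
            self.outcomes[col].map(lambda v: _check_date(v, f"outcomes.{col}"))
        origin = pd.to_datetime(self.outcomes["time_origin_date"])
        last = pd.to_datetime(self.outcomes["last_followup_date"])
        bad = self.outcomes["patient_id"][last < origin]
        if len(bad):
            raise IntegrityError(
                f"last_followup_date precedes time_origin_date for patients: {sorted(bad)[:10]}"
            )
        if len(self.diagnoses):
            self.diagnoses["date"].map(lambda v: _check_date(v, "diagnoses.date"))
            floor = pd.Timestamp(date_floor)
            early = pd.to_datetime(self.diagnoses["date"]) < floor
            if early.any():
                msg = (f"{int(early.sum())} diagnosis rows dated before {date_floor}; "
                       "rows retained")
                self.warnings.append(msg)
                logger.warning(msg)
        return self


def read_ehr_tables(directory) -> EHRBundle:
    """Load and validate the five CSV tables from a directory."""
    directory = Path(directory)
    frames = {}
    for name in EHR_TABLES:
        fp = directory / f"{name}.csv"
        if not fp.exists():
            raise FileNotFoundError(fp)
        frames[name] = pd.read_csv(fp, dtype=str).fillna("")
    for name in ("death_indicator",):
        frames["outcomes"][name] = frames["outcomes"][name].astype(int)
    return EHRBundle(**frames).validate()


def write_ehr_tables(bundle: EHRBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in EHR_TABLES:
        getattr(bundle, name).to_csv(directory / f"{name}.csv", index=False)


PREDICTION_COLUMNS = ("report_id", "patient_id", "scan_date", "probability", "label")


def write_predictions(predictions: pd.DataFrame, path) -> None:
    """Write the per-report prediction CSV with a stable column order."""
    missing = [c for c in PREDICTION_COLUMNS if c not in predictions.columns]
    if missing:
        raise ParseError(f"predictions missing columns {missing}")
    probs = predictions["probability"].astype(float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    predictions.loc[:, list(PREDICTION_COLUMNS)].to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"report_id": str, "patient_id": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"predictions file missing columns {missing}")
    return frame


def save_model(model, path) -> None:
    """Serialize a fitted indication model to versioned JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(model.to_json_dict(), fh, indent=2)


def load_model(path):
    from .model import IndicationModel

    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            from .errors import SchemaError

            raise SchemaError(f"model file {path} is not valid JSON: {exc.msg}") from exc
    return IndicationModel.from_json_dict(payload)


# ---------------------------------------------------------------------------
# bridging the synthetic study to the on-disk formats


def study_to_bundle(study) -> tuple[list[ReportRecord], EHRBundle]:
    records = [ReportRecord(**r) for r in study.reports]
    demo_cols = ["patient_id", "sex", "race_ethnicity", "age_at_diagnosis",
                 "stage", "histology", "smoking", "surgery", "comorbidity"]
    bundle = EHRBundle(
        ct_events=study.ct_events[["patient_id", "date", "report_id"]].copy(),
        diagnoses=study.diagnoses.copy(),
        orders=study.orders.copy(),
        demographics=study.patients[demo_cols].copy(),
        outcomes=study.outcomes.copy(),
    )
    return records, bundle.validate(records)


def write_study(study, directory) -> None:
    """Emit reports JSONL, the EHR CSV tables, and the ground-truth CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records, bundle = study_to_bundle(study)
    write_reports(records, directory / "reports.jsonl")
    write_ehr_tables(bundle, directory)
    study.truth.report_labels.to_csv(directory / "truth_report_labels.csv", index=False)
    study.truth.patient_exposure.to_csv(directory / "truth_patient_exposure.csv", index=False)
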