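"""Structured-EHR predictors for each CT scan.

Four named predictors: time since the previous chest CT (binarized at six
months := 183 days, closed window), ordering-provider specialty (closed
category set), and counts of symptom-related and lung-disease-related ICD
codes in the 183 days up to and including the scan date. Additional
variables can be appended through configuration; they are never invented
silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError

__all__ = [
    "CodeSet",
    "StructuredFeatureVector",
    "DEFAULT_SYMPTOM_CODES",
    "DEFAULT_LUNGDX_CODES",
    "SPECIALTY_CATEGORIES",
    "DEFAULT_SPECIALTY_MAPPING",
    "STRUCTURED_FEATURE_NAMES",
    "interval_feature",
    "count_codes_in_window",
    "specialty_feature",
    "assemble_structured_features",
    "featurize_bundle",
]

SIX_MONTHS_DAYS = 183

_ICD_PREFIX_RE = re.compile(r"^[A-TV-Z][0-9][0-9A-Z](\.[0-9A-Z]{0,4})?$|^[0-9]{3}(\.[0-9]{0,2})?$")


@dataclass(frozen=True)
class CodeSet:
    """Named set of ICD code prefixes (prefix match, dot-insensitive)."""

    name: str
    prefixes: tuple[str, ...]
    icd_version: str = "10"
    version: str = "default-1"

    def __post_init__(self):
        for p in self.prefixes:
            if not _ICD_PREFIX_RE.match(p):
                raise ConfigurationError(f"{self.name}: invalid ICD prefix {p!r}")

    def matches(self, codes: pd.Series) -> np.ndarray:
        norm = codes.astype(str).str.upper().str.replace(".", "", regex=False)
        out = np.zeros(len(norm), dtype=bool)
        for p in self.prefixes:
            out |= norm.str.startswith(p.replace(".", "")).to_numpy()
        return out


# stand-in defaults for the unavailable institutional code tables; fully
# configurable through CodeSet
DEFAULT_SYMPTOM_CODES = CodeSet(
    "symptoms", ("R05", "R07", "R06.0", "R04.2", "R63.4"))
DEFAULT_LUNGDX_CODES = CodeSet(
    "lung_disease",
    ("J12", "J13", "J14", "J15", "J16", "J17", "J18", "J90", "J91", "J44"),
)

SPECIALTY_CATEGORIES = (
    "oncology",
    "pulmonology",
    "primary_care",
    "emergency_or_inpatient",
    "radiology",
    "other",
)

DEFAULT_SPECIALTY_MAPPING = {
    "medical oncology": "oncology",
    "oncology": "oncology",
    "hematology/oncology": "oncology",
    "radiation oncology": "oncology",
    "pulmonology": "pulmonology",
    "pulmonary medicine": "pulmonology",
    "internal medicine": "primary_care",
    "family medicine": "primary_care",
    "primary care": "primary_care",
    "primary_care": "primary_care",
    "emergency medicine": "emergency_or_inpatient",
    "emergency_or_inpatient": "emergency_or_inpatient",
    "hospital medicine": "emergency_or_inpatient",
    "inpatient": "emergency_or_inpatient",
    "radiology": "radiology",
    "other": "other",
}

#: versioned numeric feature order ("other" specialty is the reference level)
STRUCTURED_FEATURE_NAMES = (
    "interval_ge_6mo",
    "n_symptom_icd_6mo",
    "n_lungdx_icd_6mo",
    "specialty_oncology",
    "specialty_pulmonology",
    "specialty_primary_care",
    "specialty_emergency_or_inpatient",
    "specialty_radiology",
)
STRUCTURED_FEATURE_VERSION = "structured-v1"


@dataclass
class StructuredFeatureVector:
    report_id: str
    interval_ge_6mo: int
    interval_days: float | None  # None when no earlier CT exists
    first_scan: bool
    provider_specialty: str
    specialty_missing: bool
    n_symptom_icd_6mo: int
    n_lungdx_icd_6mo: int
    extras: dict[str, float] = field(default_factory=dict)
    version: str = STRUCTURED_FEATURE_VERSION

    def numeric(self) -> dict[str, float]:
        out = {
            "interval_ge_6mo": float(self.interval_ge_6mo),
            "n_symptom_icd_6mo": float(self.n_symptom_icd_6mo),
            "n_lungdx_icd_6mo": float(self.n_lungdx_icd_6mo),
        }
        for cat in SPECIALTY_CATEGORIES[:-1]:
            out[f"specialty_{cat}"] = float(self.provider_specialty == cat)
        out.update(self.extras)
        return out


def interval_feature(ct_events: pd.DataFrame, report_id: str) -> tuple[float | None, int, bool]:
    """Days since the nearest earlier chest CT of the same patient.

    Returns ``(days, binary, first_scan)``; binary is 1 when days >= 183 or
    no earlier CT exists (first-scan convention, flagged).
    """
    rows = ct_events[ct_events["report_id"] == report_id]
    if rows.empty:
        raise KeyError(f"index scan {report_id!r} not found in ct_events")
    row = rows.iloc[0]
    dates = pd.to_datetime(ct_events.loc[ct_events["patient_id"] == row["patient_id"], "date"])
    index_date = pd.Timestamp(row["date"])
    earlier = dates[dates < index_date]
    if earlier.empty:
        return None, 1, True
    days = float((index_date - earlier.max()).days)
    return days, int(days >= SIX_MONTHS_DAYS), False


def count_codes_in_window(
    diagnoses: pd.DataFrame,
    code_set: CodeSet,
    index_date,
    window_days: int = SIX_MONTHS_DAYS,
    patient_id: str | None = None,
) -> int:
    """Count diagnoses matching ``code_set`` in [index - window, index], closed
    at both ends."""
    if window_days < 0:
        raise ConfigurationError(f"window_days must be non-negative, got {window_days}")
    if diagnoses.empty:
        return 0
    frame = diagnoses
    if patient_id is not None:
        frame = frame[frame["patient_id"] == patient_id]
        if frame.empty:
            return 0
    index_date = pd.Timestamp(index_date)
    dates = pd.to_datetime(frame["date"])
    in_window = (dates >= index_date - pd.Timedelta(days=window_days)) & (dates <= index_date)
    return int((in_window.to_numpy() & code_set.matches(frame["icd_code"])).sum())


def specialty_feature(
    orders: pd.DataFrame,
    report_id: str,
    mapping: dict[str, str] | None = None,
) -> tuple[str, bool]:
    """Normalize the ordering-provider specialty to the closed category set.

    Unmapped or missing raw strings map to ``other`` with a missingness flag.
    """
    mapping = mapping or DEFAULT_SPECIALTY_MAPPING
    rows = orders[orders["report_id"] == report_id] if len(orders) else orders
    if len(rows) == 0:
        return "other", True
    raw = str(rows.iloc[0]["provider_specialty"]).strip().lower()
    if raw in mapping:
        return mapping[raw], False
    return "other", True


def assemble_structured_features(
    bundle,
    report_id: str,
    symptom_codes: CodeSet = DEFAULT_SYMPTOM_CODES,
    lungdx_codes: CodeSet = DEFAULT_LUNGDX_CODES,
    specialty_mapping: dict[str, str] | None = None,
    extra_features: dict[str, float] | None = None,
) -> StructuredFeatureVector:
    """Compute the structured feature vector for one scan of a validated bundle."""
    rows = bundle.ct_events[bundle.ct_events["report_id"] == report_id]
    if rows.empty:
        raise KeyError(f"index scan {report_id!r} not found in ct_events")
    row = rows.iloc[0]
    if row["patient_id"] not in set(bundle.demographics["patient_id"]):
        raise IntegrityError(f"patient {row['patient_id']!r} absent from demographics")
    days, binary, first = interval_feature(bundle.ct_events, report_id)
    specialty, missing = specialty_feature(bundle.orders, report_id, specialty_mapping)
    return StructuredFeatureVector(
        report_id=report_id,
        interval_ge_6mo=binary,
        interval_days=days,
        first_scan=first,
        provider_specialty=specialty,
        specialty_missing=missing,
        n_symptom_icd_6mo=count_codes_in_window(
            bundle.diagnoses, symptom_codes, row["date"], patient_id=row["patient_id"]),
        n_lungdx_icd_6mo=count_codes_in_window(
            bundle.diagnoses, lungdx_codes, row["date"], patient_id=row["patient_id"]),
        extras=dict(extra_features or {}),
    )


def featurize_bundle(
    bundle,
    report_ids=None,
    symptom_codes: CodeSet = DEFAULT_SYMPTOM_CODES,
    lungdx_codes: CodeSet = DEFAULT_LUNGDX_CODES,
    specialty_mapping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Vectorized structured features for many scans; one row per report_id."""
    mapping = specialty_mapping or DEFAULT_SPECIALTY_MAPPING
    events = bundle.ct_events.copy()
    events["_date"] = pd.to_datetime(events["date"])
    if report_ids is None:
        report_ids = list(events["report_id"])
    wanted = set(report_ids)

    # previous-scan interval per patient
    events = events.sort_values(["patient_id", "_date", "report_id"], kind="mergesort")
    prev = events.groupby("patient_id")["_date"].shift(1)
    events["interval_days"] = (events["_date"] - prev).dt.days
    events["interval_ge_6mo"] = (
        events["interval_days"].isna() | (events["interval_days"] >= SIX_MONTHS_DAYS)
    ).astype(int)

    # per-patient sorted diagnosis dates for each code set
    diag = bundle.diagnoses
    diag_dates: dict[str, dict[str, np.ndarray]] = {"symptom": {}, "lung_dx": {}}
    if len(diag):
        dts = pd.to_datetime(diag["date"]).to_numpy()
        for key, cs in (("symptom", symptom_codes), ("lung_dx", lungdx_codes)):
            mask = cs.matches(diag["icd_code"])
            sub = pd.DataFrame({"patient_id": diag["patient_id"].to_numpy()[mask],
                                "dt": dts[mask]})
            for pid, grp in sub.groupby("patient_id"):
                diag_dates[key][pid] = np.sort(grp["dt"].to_numpy())

    specialty_by_report = {}
    if len(bundle.orders):
        for rid, raw in zip(bundle.orders["report_id"], bundle.orders["provider_specialty"]):
            specialty_by_report[rid] = mapping.get(str(raw).strip().lower(), "other")

    window = np.timedelta64(SIX_MONTHS_DAYS, "D")
    rows = []
    for _, ev in events.iterrows():
        if ev["report_id"] not in wanted:
            continue
        counts = {}
        for key, name in (("symptom", "n_symptom_icd_6mo"), ("lung_dx", "n_lungdx_icd_6mo")):
            arr = diag_dates[key].get(ev["patient_id"])
            if arr is None:
                counts[name] = 0
            else:
                d = np.datetime64(ev["_date"])
                counts[name] = int(
                    np.searchsorted(arr, d, side="right")
                    - np.searchsorted(arr, d - window, side="left")
                )
        specialty = specialty_by_report.get(ev["report_id"], "other")
        row = {
            "report_id": ev["report_id"],
            "patient_id": ev["patient_id"],
            "interval_ge_6mo": int(ev["interval_ge_6mo"]),
            **counts,
        }
        for cat in SPECIALTY_CATEGORIES[:-1]:
            row[f"specialty_{cat}"] = float(specialty == cat)
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.set_index("report_id").loc[list(report_ids)].reset_index()
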