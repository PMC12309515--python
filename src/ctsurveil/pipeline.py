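"""Feature fusion and corpus-level convenience wrappers.

Joins the 11 NLP-derived report features with the structured-EHR scan
features into one table per report, and applies a fitted indication model
across a corpus.
"""

from __future__ import annotations

import pandas as pd

from .io import EHRBundle, ReportRecord
from .nlp import FEATURE_NAMES, ConceptLexicon, NLPConfig, featurize_report
from .structured import STRUCTURED_FEATURE_NAMES, featurize_bundle

__all__ = [
    "NLP_FEATURES",
    "STRUCTURED_FEATURES",
    "ALL_FEATURES",
    "build_feature_table",
    "predict_corpus",
]

NLP_FEATURES = tuple(FEATURE_NAMES)
STRUCTURED_FEATURES = tuple(STRUCTURED_FEATURE_NAMES)
ALL_FEATURES = NLP_FEATURES + STRUCTURED_FEATURES


def build_feature_table(
    reports: list[ReportRecord],
    bundle: EHRBundle,
    lexicon: ConceptLexicon | None = None,
    nlp_config: NLPConfig | None = None,
) -> pd.DataFrame:
    """One row per report: identifiers, the 11 NLP features and the
    structured features, in the versioned column order."""
    lexicon = lexicon or ConceptLexicon.default()
    nlp_config = nlp_config or NLPConfig()
    rows = []
    for rec in reports:
        vec = featurize_report(rec, lexicon, nlp_config)
        rows.append({
            "report_id": rec.report_id,
            "patient_id": rec.patient_id,
            "scan_date": rec.scan_date,
            **vec.as_dict(),
        })
    nlp_frame = pd.DataFrame(rows)
    structured = featurize_bundle(bundle, report_ids=list(nlp_frame["report_id"]))
    merged = nlp_frame.merge(
        structured.drop(columns=["patient_id"]), on="report_id", validate="1:1"
    )
    ordered = ["report_id", "patient_id", "scan_date", *ALL_FEATURES]
    return merged[ordered]


def build_calibrated_dataset(
    cal,
    lexicon: ConceptLexicon | None = None,
    nlp_config: NLPConfig | None = None,
) -> pd.DataFrame:
    """Feature table + true labels for a calibrated-scan draw.

    NLP features default to lossless extraction (no salience filtering) so
    measured counts equal the generated Poisson counts and fitted odds
    ratios are comparable to the configured truths; pass an ``NLPConfig``
    explicitly to study the effect of salience filtering.
    """
    lexicon = lexicon or ConceptLexicon.default()
    nlp_config = nlp_config or NLPConfig().lossless()
    index_ids = set(cal.labels["report_id"])
    rows = []
    for rec in cal.reports:
        if rec["report_id"] not in index_ids:
            continue
        vec = featurize_report((rec["report_id"], rec["text"]), lexicon, nlp_config)
        rows.append({"report_id": rec["report_id"], **vec.as_dict()})
    nlp_frame = pd.DataFrame(rows)

    demographics = pd.DataFrame({
        "patient_id": cal.labels["patient_id"],
        "sex": "female", "race_ethnicity": "white",
        "stage": "I", "histology": "adenocarcinoma",
    })
    outcomes = pd.DataFrame({
        "patient_id": cal.labels["patient_id"],
        "time_origin_date": "2012-06-01",
        "last_followup_date": "2022-06-01",
        "death_indicator": 0,
    })
    bundle = EHRBundle(
        ct_events=cal.ct_events,
        diagnoses=cal.diagnoses,
        orders=pd.DataFrame(columns=["report_id", "provider_specialty"]),
        demographics=demographics,
        outcomes=outcomes,
    )
    structured = featurize_bundle(bundle, report_ids=list(nlp_frame["report_id"]))
    return (
        nlp_frame.merge(structured.drop(columns=["patient_id"]),
                        on="report_id", validate="1:1")
        .merge(cal.labels, on="report_id", validate="1:1")
    )


def predict_corpus(model, feature_table: pd.DataFrame) -> pd.DataFrame:
    """Per-report predicted probability and label in the predictions schema."""
    pred = model.predict(feature_table)
    return pd.DataFrame({
        "report_id": feature_table["report_id"],
        "patient_id": feature_table["patient_id"],
        "scan_date": feature_table["scan_date"],
        "probability": pred["probability"].to_numpy(),
        "label": pred["label"].to_numpy(),
    })
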