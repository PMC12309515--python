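"""Fully synthetic EHR generator: patients, CT timelines, report texts, ICD
events and survival outcomes with known ground truth.

The generator emulates a cohort of long-term lung-cancer survivors followed
from a fixed time origin (the five-year survival anniversary): demographic
margins mirror a typical single-institution survivor cohort, surveillance
scans recur on a roughly annual rhythm, non-surveillance scans follow
symptom episodes whose intensity grows with comorbidity, report phrase usage
depends on the true indication through per-cluster Poisson rates, and
survival is exponential with multiplicative covariate effects and
administrative censoring.

Two generation modes are provided:

* ``simulate_study`` — a full cohort with timelines, reports, ICD events and
  outcomes, where exposure (ever receiving a surveillance CT) is confounded
  by stage and comorbidity.
* ``generate_calibrated_scans`` — one scan per synthetic patient with the
  label drawn first and every feature conditionally independent given the
  label, so the multivariate logistic model for the indication is exactly
  well-specified with known log odds ratios (Poisson count features have
  log-OR equal to the log rate ratio; the binary interval feature's OR is
  set directly). This mode backs coefficient-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .nlp import CLUSTER_NAMES

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "CTEvent",
    "SyntheticStudy",
    "generate_cohort",
    "generate_ct_timeline",
    "render_report",
    "generate_code_events",
    "generate_outcomes",
    "simulate_study",
    "generate_calibrated_scans",
    "TRUE_LOGODDS_NAMES",
]

DAYS_PER_YEAR = 365.25

STAGE_LEVEL = {"I": 0, "II": 1, "IIIA": 2, "IIIB/C": 3, "IV": 4, "missing": 1}

_DEFAULT_MARGINS = {
    "sex": {"male": 0.381, "female": 0.619},
    "race_ethnicity": {
        "white": 0.523,
        "black": 0.022,
        "hispanic": 0.044,
        "asian": 0.304,
        "other": 0.055,
        "missing": 0.052,
    },
    "stage": {
        "I": 0.504,
        "II": 0.077,
        "IIIA": 0.096,
        "IIIB/C": 0.075,
        "IV": 0.183,
        "missing": 0.065,
    },
    "histology": {
        "adenocarcinoma": 0.738,
        "nsclc": 0.048,
        "large_cell": 0.007,
        "small_cell": 0.010,
        "squamous_cell": 0.101,
        "other": 0.096,
    },
    "smoking": {"active": 0.038, "former": 0.485, "never": 0.460, "missing": 0.017},
    "surgery": {"yes": 0.670, "no": 0.328, "missing": 0.002},
}

# per-cluster expected phrase counts per report, by true indication; the
# implied per-count log odds ratio is log(rate_surveillance / rate_other)
_DEFAULT_PHRASE_RATES = {
    "surveillance": {
        "surveillance": 0.8 * 1.37,
        "follow_up": 0.9 * 1.68,
        "symptoms": 0.25,
        "recurrence": 0.30,
        "metastasis": 0.15,
        "treatment": 0.25,
        "medication": 0.20,
    },
    "other": {
        "surveillance": 0.8,
        "follow_up": 0.9,
        "symptoms": 1.50,
        "recurrence": 0.55,
        "metastasis": 0.60,
        "treatment": 0.60,
        "medication": 0.45,
    },
}

_DEFAULT_ICD_RATES = {
    "symptom": {"surveillance": 0.3, "other": 2.0},
    "lung_dx": {"surveillance": 0.2, "other": 1.2},
}

_DEFAULT_SPECIALTY_PROBS = {
    "surveillance": {
        "oncology": 0.60,
        "pulmonology": 0.15,
        "primary_care": 0.15,
        "radiology": 0.05,
        "other": 0.05,
    },
    "other": {
        "emergency_or_inpatient": 0.40,
        "primary_care": 0.20,
        "oncology": 0.15,
        "pulmonology": 0.15,
        "other": 0.10,
    },
}

SYMPTOM_CODES = ("R05", "R07.9", "R06.0", "R04.2", "R63.4")
LUNG_DX_CODES = ("J18.9", "J90", "J44.1", "J12.9")


@dataclass
class GeneratorConfig:
    n_patients: int = 585
    n_controls: int = 128
    seed: int = 0
    #: long-run fraction of surveillance scans for an engaged patient at
    #: average comorbidity; the other-scan rate is derived from it
    label_prevalence: float = 0.65
    phrase_rates: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_PHRASE_RATES.items()
    })
    #: inter-scan gap model in days: surveillance gaps are truncated normal,
    #: other-indication gaps are exponential with the stated mean at zero
    #: comorbidity (shortened by factor 1 + 0.5 * comorbidity)
    interval_model: dict = field(default_factory=lambda: {
        "surveillance": {"mean": 365.0, "sd": 90.0},
        "other": {"mean": 1020.0, "sd": 1020.0},
    })
    icd_rates: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_ICD_RATES.items()
    })
    specialty_probs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_SPECIALTY_PROBS.items()
    })
    #: log-odds model for surveillance engagement (the exposure)
    confounder_effects: dict = field(default_factory=lambda: {
        "intercept": 2.3, "stage_level": -0.5, "comorbidity": -0.4,
    })
    #: log-hazard effects of the confounders on survival
    hazard_effects: dict = field(default_factory=lambda: {
        "stage_level": 0.15, "comorbidity": 0.15,
    })
    #: conditional log hazard ratio of surveillance exposure on survival;
    #: covariate effects are kept modest so the marginal HR is within ~2%
    true_log_hr: float = math.log(0.6)
    baseline_hazard: float = 0.06  # events per year at reference covariates
    censoring_years: float = 10.0
    demographic_margins: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_MARGINS.items()
    })
    #: P(interval >= 6 months | indication) for the calibrated-scan mode;
    #: defaults give an interval odds ratio of exactly 5.5
    interval_binary_probs: dict = field(default_factory=lambda: {
        "surveillance": 0.75, "other": 6.0 / 17.0,
    })
    comparison_probs: dict = field(default_factory=lambda: {
        "surveillance": 0.9, "other": 0.6,
    })

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("n_patients and n_controls must be non-negative")
        if not 0.0 < self.label_prevalence < 1.0:
            raise ValueError("label_prevalence must be in (0, 1)")
        if self.censoring_years < 0:
            raise ValueError("censoring horizon must be non-negative")
        if self.baseline_hazard < 0:
            raise ValueError("baseline hazard must be non-negative")
        for indication, rates in self.phrase_rates.items():
            unknown = set(rates) - set(CLUSTER_NAMES)
            if unknown:
                raise ValueError(f"unknown phrase clusters {sorted(unknown)}")
            if any(r < 0 for r in rates.values()):
                raise ValueError(f"negative phrase rate for {indication!r}")
        for group, rates in self.icd_rates.items():
            if any(r < 0 for r in rates.values()):
                raise ValueError(f"negative ICD rate in {group!r}")
        for variable, margins in self.demographic_margins.items():
            total = sum(margins.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"margins for {variable!r} sum to {total:.6f}, expected 1"
                )
            if any(p < 0 for p in margins.values()):
                raise ValueError(f"negative margin in {variable!r}")

    def null_signal(self) -> "GeneratorConfig":
        """Copy with every indication-dependent rate made indication-independent."""
        flat_phrases = {
            c: 0.5 * (self.phrase_rates["surveillance"].get(c, 0.0)
                      + self.phrase_rates["other"].get(c, 0.0))
            for c in CLUSTER_NAMES
        }
        return replace(
            self,
            phrase_rates={"surveillance": dict(flat_phrases), "other": dict(flat_phrases)},
            icd_rates={g: {"surveillance": 0.5 * (r["surveillance"] + r["other"])}
                       | {"other": 0.5 * (r["surveillance"] + r["other"])}
                       for g, r in self.icd_rates.items()},
            interval_binary_probs={"surveillance": 0.5, "other": 0.5},
            comparison_probs={"surveillance": 0.75, "other": 0.75},
            specialty_probs={
                "surveillance": dict(self.specialty_probs["surveillance"]),
                "other": dict(self.specialty_probs["surveillance"]),
            },
        )

    def true_log_odds(self) -> dict[str, float]:
        """Per-feature conditional log odds ratios implied by the calibrated mode."""
        out = {}
        for c in CLUSTER_NAMES:
            s = self.phrase_rates["surveillance"].get(c, 0.0)
            o = self.phrase_rates["other"].get(c, 0.0)
            out[f"kp_{c}"] = math.log(s / o) if s > 0 and o > 0 else float("nan")
        q1 = self.interval_binary_probs["surveillance"]
        q0 = self.interval_binary_probs["other"]
        out["interval_ge_6mo"] = math.log(q1 / (1 - q1)) - math.log(q0 / (1 - q0))
        for group, name in (("symptom", "n_symptom_icd_6mo"), ("lung_dx", "n_lungdx_icd_6mo")):
            s, o = self.icd_rates[group]["surveillance"], self.icd_rates[group]["other"]
            out[name] = math.log(s / o) if s > 0 and o > 0 else float("nan")
        return out


TRUE_LOGODDS_NAMES = tuple(
    [f"kp_{c}" for c in CLUSTER_NAMES] + ["interval_ge_6mo", "n_symptom_icd_6mo", "n_lungdx_icd_6mo"]
)


@dataclass
class GroundTruth:
    report_labels: pd.DataFrame  # report_id, true_label
    patient_exposure: pd.DataFrame  # patient_id, exposed
    params: dict


@dataclass
class CTEvent:
    patient_id: str
    days: float
    indication: str  # "surveillance" | "other"
    report_id: str = ""


# ---------------------------------------------------------------------------
# cohort


def _sample_margin(rng, margins: dict[str, float], n: int) -> np.ndarray:
    keys = list(margins)
    probs = np.array([margins[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=n, p=probs)


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw demographics, comorbidity and surveillance engagement for every patient.

    Engagement (the exposure intent) follows a logistic model in stage level
    and comorbidity, inducing confounding of exposure with survival.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    cols = {"patient_id": [f"P{i:05d}" for i in range(n)]}
    for variable, margins in config.demographic_margins.items():
        cols[variable] = _sample_margin(rng, margins, n) if n else np.array([], dtype=object)
    df = pd.DataFrame(cols)
    if n == 0:
        df["age_at_diagnosis"] = pd.Series(dtype=float)
        df["comorbidity"] = pd.Series(dtype=int)
        df["stage_level"] = pd.Series(dtype=int)
        df["engaged"] = pd.Series(dtype=bool)
        df["time_origin_date"] = pd.Series(dtype=object)
        return df
    df["age_at_diagnosis"] = np.clip(rng.normal(65.5, 9.0, size=n).round(1), 30, 95)
    df["comorbidity"] = rng.poisson(1.0, size=n)
    df["stage_level"] = df["stage"].map(STAGE_LEVEL).astype(int)
    eff = config.confounder_effects
    logit = (
        eff["intercept"]
        + eff["stage_level"] * df["stage_level"].to_numpy()
        + eff["comorbidity"] * df["comorbidity"].to_numpy()
    )
    df["engaged"] = rng.random(n) < _invlogit(logit)
    origin = date(2010, 1, 1)
    offsets = rng.integers(0, 1096, size=n)
    df["time_origin_date"] = [origin + timedelta(days=int(d)) for d in offsets]
    return df


# ---------------------------------------------------------------------------
# outcomes


def generate_outcomes(
    cohort: pd.DataFrame,
    exposure: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential survival times with multiplicative covariate and exposure
    effects, administratively censored at the configured horizon."""
    if config.censoring_years < 0:
        raise ValueError("censoring horizon must be non-negative")
    n = len(cohort)
    exposure = np.asarray(exposure, dtype=bool)
    eff = config.hazard_effects
    log_rate = (
        math.log(config.baseline_hazard) if config.baseline_hazard > 0 else -np.inf
    )
    lp = (
        eff.get("stage_level", 0.0) * cohort["stage_level"].to_numpy()
        + eff.get("comorbidity", 0.0) * cohort["comorbidity"].to_numpy()
        + config.true_log_hr * exposure
    )
    rate = np.exp(log_rate + lp)  # events per year
    with np.errstate(divide="ignore"):
        t_event = rng.exponential(1.0 / np.where(rate > 0, rate, np.inf), size=n)
    horizon = config.censoring_years
    event = t_event <= horizon
    time_years = np.minimum(t_event, horizon)
    return pd.DataFrame({
        "patient_id": cohort["patient_id"].to_numpy(),
        "time_days": np.round(time_years * DAYS_PER_YEAR).astype(int),
        "event": event.astype(int),
    })


# ---------------------------------------------------------------------------
# CT timelines


def generate_ct_timeline(
    patient: pd.Series | dict,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[CTEvent]:
    """Dated CT events for one patient within [0, follow-up].

    Engaged patients receive surveillance scans on a roughly annual rhythm
    (the first capped at 90% of follow-up, so engagement always realizes as
    at least one surveillance scan when follow-up is positive);
    non-surveillance scans arrive as a Poisson process whose rate grows with
    comorbidity, emulating symptom-driven imaging.
    """
    follow_up = float(patient["follow_up_days"])
    if follow_up <= 0:
        return []
    pid = patient["patient_id"]
    events: list[CTEvent] = []
    surv = config.interval_model["surveillance"]
    if bool(patient.get("engaged", False)):
        t = min(rng.uniform(30.0, surv["mean"] + 30.0), 0.9 * follow_up)
        while t <= follow_up:
            events.append(CTEvent(pid, t, "surveillance"))
            gap = max(30.0, rng.normal(surv["mean"], surv["sd"]))
            t += gap
    other_mean = config.interval_model["other"]["mean"]
    if other_mean > 0 and math.isfinite(other_mean):
        c = float(patient.get("comorbidity", 0))
        eff_mean = other_mean / (1.0 + 0.5 * c)
        t = rng.exponential(eff_mean)
        while t <= follow_up:
            events.append(CTEvent(pid, t, "other"))
            t += rng.exponential(eff_mean)
    events.sort(key=lambda e: e.days)
    return events


# ---------------------------------------------------------------------------
# report rendering

_BASE_HISTORY = "History of lung cancer."

# each template embeds the phrase near other candidate terms (so it joins the
# co-occurrence graph) while never placing a candidate immediately before a
# potentially multiword phrase (so 3-term chunking cannot split a seed)
_PHRASE_TEMPLATES = {
    "surveillance": [
        "Routine {p} imaging of the chest.",
        "This is a {p} chest examination.",
    ],
    "follow_up": [
        "Annual {p} imaging of a known nodule.",
        "Recommend {p} imaging in one year.",
    ],
    "symptoms": [
        "{p} with acute onset is reported.",
        "The patient presents with {p} and mild distress.",
    ],
    "recurrence": [
        "Concern for local {p} of disease.",
        "No definite {p} is identified in the lungs.",
    ],
    "metastasis": [
        "Evaluate for pulmonary {p} involvement.",
        "No osseous {p} is seen.",
    ],
    "treatment": [
        "Status after {p} for lung cancer.",
        "Prior {p} changes are noted.",
    ],
    "medication": [
        "The patient is on {p} therapy currently.",
        "Ongoing {p} therapy is reported.",
    ],
}

#: where phrase sentences of each cluster may be placed (name, probability)
_PLACEMENT = {
    "surveillance": (("indication_history", 0.7), ("impression", 0.3)),
    "follow_up": (("indication_history", 0.6), ("impression", 0.4)),
    "symptoms": (("indication_history", 1.0),),
    "recurrence": (("findings", 0.5), ("impression", 0.5)),
    "metastasis": (("findings", 0.5), ("impression", 0.5)),
    "treatment": (("indication_history", 0.7), ("findings", 0.3)),
    "medication": (("indication_history", 1.0),),
}

_FILLER = (
    "The lungs are clear.",
    "No suspicious nodule is identified.",
    "Mediastinal contours are within normal limits.",
    "There is no pleural effusion.",
    "The airways are patent.",
)


@dataclass
class RenderedReport:
    text: str
    phrase_counts: dict[str, int]


def render_report(
    event: CTEvent,
    config: GeneratorConfig,
    rng: np.random.Generator,
    lexicon_phrases: dict[str, list[str]] | None = None,
) -> RenderedReport:
    """Templated sectioned report text for one CT event.

    Per-cluster phrase occurrence counts are Poisson with the
    indication-specific rate; each occurrence is rendered as its own sentence
    so downstream counting is exact. Sections use the canonical header names.
    """
    from .nlp import DEFAULT_LEXICON

    indication = event.indication
    if indication not in config.phrase_rates:
        raise ValueError(f"no phrase rates configured for indication {indication!r}")
    rates = config.phrase_rates[indication]
    unknown = set(rates) - set(CLUSTER_NAMES)
    if unknown:
        raise ValueError(f"unknown phrase clusters {sorted(unknown)}")
    phrases = lexicon_phrases or DEFAULT_LEXICON

    buckets = {"indication_history": [_BASE_HISTORY], "findings": [], "impression": []}
    counts: dict[str, int] = {}
    for cluster in CLUSTER_NAMES:
        k = int(rng.poisson(rates.get(cluster, 0.0)))
        counts[cluster] = k
        for _ in range(k):
            phrase = phrases[cluster][int(rng.integers(len(phrases[cluster])))]
            template = _PHRASE_TEMPLATES[cluster][
                int(rng.integers(len(_PHRASE_TEMPLATES[cluster])))
            ]
            placement = _PLACEMENT[cluster]
            section = _weighted_pick(
                rng, [n for n, _ in placement],
                np.cumsum([p for _, p in placement]),
            )
            buckets[section].append(template.format(p=phrase))

    n_filler = 1 + int(rng.integers(3))
    filler = list(rng.choice(_FILLER, size=n_filler, replace=False))
    buckets["findings"] = filler + buckets["findings"]
    if not buckets["impression"]:
        buckets["impression"].append("No significant change from prior examination.")

    has_comparison = rng.random() < config.comparison_probs.get(indication, 0.75)
    comparison = (
        "Comparison is made with prior examination."
        if has_comparison
        else "None available."
    )
    text = (
        "INDICATION: " + " ".join(buckets["indication_history"]) + "\n"
        "TECHNIQUE: Helical acquisition of the thorax was performed.\n"
        "COMPARISON: " + comparison + "\n"
        "FINDINGS: " + " ".join(buckets["findings"]) + "\n"
        "IMPRESSION: " + " ".join(buckets["impression"])
    )
    return RenderedReport(text=text, phrase_counts=counts)


# ---------------------------------------------------------------------------
# ICD code events and ordering specialty


def _weighted_pick(rng: np.random.Generator, names: list, probs: np.ndarray):
    return names[int(np.searchsorted(probs, rng.random()))]


def _code_event_rows(patient, timeline, config, rng):
    diag_rows, order_rows = [], []
    pid = patient["patient_id"]
    spec_cum = {
        ind: (list(p), np.cumsum(np.array(list(p.values())) / sum(p.values())))
        for ind, p in config.specialty_probs.items()
    }
    for event in timeline:
        for group, codes in (("symptom", SYMPTOM_CODES), ("lung_dx", LUNG_DX_CODES)):
            rate = config.icd_rates[group][event.indication]
            for _ in range(int(rng.poisson(rate))):
                offset = int(rng.integers(0, 184))  # window closed at both ends
                diag_rows.append({
                    "patient_id": pid,
                    "days": event.days - offset,
                    "icd_code": codes[int(rng.integers(len(codes)))],
                })
        names, cum = spec_cum[event.indication]
        order_rows.append({
            "report_id": event.report_id,
            "provider_specialty": _weighted_pick(rng, names, cum),
        })
    return diag_rows, order_rows


def generate_code_events(
    patient: pd.Series | dict,
    timeline: list[CTEvent],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symptom / lung-disease diagnosis rows in the 183 days before each scan,
    plus the ordering-provider specialty per scan."""
    diag_rows, order_rows = _code_event_rows(patient, timeline, config, rng)
    return (
        pd.DataFrame(diag_rows, columns=["patient_id", "days", "icd_code"]),
        pd.DataFrame(order_rows, columns=["report_id", "provider_specialty"]),
    )


# ---------------------------------------------------------------------------
# full study simulation


@dataclass
class SyntheticStudy:
    patients: pd.DataFrame
    reports: list[dict]  # report_id, patient_id, scan_date, text
    ct_events: pd.DataFrame
    diagnoses: pd.DataFrame
    orders: pd.DataFrame
    outcomes: pd.DataFrame
    truth: GroundTruth


def _to_date(origin: date, days: float) -> str:
    return (origin + timedelta(days=int(round(days)))).isoformat()


def simulate_study(config: GeneratorConfig) -> SyntheticStudy:
    """End-to-end simulation of a scan cohort plus a no-CT control cohort.

    Controls share the demographic and hazard model but receive no CT scans
    (their imaging happens elsewhere), providing the matched-control pool for
    the survival analyses.
    """
    rng = np.random.default_rng(config.seed)
    cohort = generate_cohort(config, seed=int(rng.integers(2**31)))
    exposure = cohort["engaged"].to_numpy(dtype=bool) if len(cohort) else np.array([], dtype=bool)
    outcomes = generate_outcomes(cohort, exposure, config, rng)
    cohort = cohort.merge(outcomes, on="patient_id") if len(cohort) else cohort.assign(
        time_days=pd.Series(dtype=int), event=pd.Series(dtype=int))
    cohort["follow_up_days"] = cohort.get("time_days", pd.Series(dtype=int))

    reports: list[dict] = []
    ct_rows, diag_rows_all, order_rows_all = [], [], []
    label_rows = []
    exposed_flags: list[bool] = []
    scanned_flags: list[bool] = []
    rid = 0
    for _, patient in cohort.iterrows():
        timeline = generate_ct_timeline(patient, config, rng)
        for event in timeline:
            event.report_id = f"R{rid:06d}"
            rid += 1
        d_rows, o_rows = _code_event_rows(patient, timeline, config, rng)
        for r in d_rows:
            diag_rows_all.append({
                "patient_id": r["patient_id"],
                "date": _to_date(patient["time_origin_date"], r["days"]),
                "icd_code": r["icd_code"],
            })
        order_rows_all.extend(o_rows)
        for event in timeline:
            scan_date = _to_date(patient["time_origin_date"], event.days)
            rendered = render_report(event, config, rng)
            reports.append({
                "report_id": event.report_id,
                "patient_id": event.patient_id,
                "scan_date": scan_date,
                "text": rendered.text,
            })
            ct_rows.append({
                "patient_id": event.patient_id,
                "date": scan_date,
                "report_id": event.report_id,
                "days_from_origin": round(event.days, 1),
            })
            label_rows.append({
                "report_id": event.report_id,
                "true_label": event.indication,
            })
        exposed_flags.append(any(e.indication == "surveillance" for e in timeline))
        scanned_flags.append(bool(timeline))

    # study inclusion mirrors the cohort definition: the scan cohort keeps
    # only patients with >=1 post-origin CT; patients without any scan are
    # not part of the study (their no-CT status is outcome-dependent here,
    # unlike the separately identified control cohort below)
    keep = np.asarray(scanned_flags, dtype=bool) if len(cohort) else np.array([], dtype=bool)
    cohort = cohort[keep].reset_index(drop=True)
    exposed_flags = [f for f, k in zip(exposed_flags, keep) if k]

    # no-CT control cohort: same population model, imaging elsewhere
    control_cfg = replace(config, n_patients=config.n_controls, n_controls=0)
    controls = generate_cohort(control_cfg, seed=int(rng.integers(2**31)))
    if len(controls):
        controls["patient_id"] = ["C" + p[1:] for p in controls["patient_id"]]
        controls["engaged"] = False
        ctrl_outcomes = generate_outcomes(
            controls, np.zeros(len(controls), dtype=bool), config, rng
        )
        controls = controls.merge(ctrl_outcomes, on="patient_id")
        controls["follow_up_days"] = controls["time_days"]
    patients = pd.concat([cohort, controls], ignore_index=True) if len(controls) else cohort

    exposure_df = pd.DataFrame({
        "patient_id": patients["patient_id"],
        "exposed": list(exposed_flags) + [False] * len(controls),
    })
    truth = GroundTruth(
        report_labels=pd.DataFrame(label_rows, columns=["report_id", "true_label"]),
        patient_exposure=exposure_df,
        params={"seed": config.seed, "true_log_hr": config.true_log_hr,
                "label_prevalence": config.label_prevalence},
    )
    outcomes_all = pd.DataFrame({
        "patient_id": patients["patient_id"],
        "time_origin_date": [d.isoformat() for d in patients["time_origin_date"]],
        "last_followup_date": [
            _to_date(o, t) for o, t in zip(patients["time_origin_date"], patients["time_days"])
        ],
        "death_indicator": patients["event"].astype(int),
    })
    return SyntheticStudy(
        patients=patients,
        reports=reports,
        ct_events=pd.DataFrame(
            ct_rows, columns=["patient_id", "date", "report_id", "days_from_origin"]
        ),
        diagnoses=pd.DataFrame(diag_rows_all, columns=["patient_id", "date", "icd_code"]),
        orders=pd.DataFrame(order_rows_all, columns=["report_id", "provider_specialty"]),
        outcomes=outcomes_all,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# calibrated-scan mode (exact logistic truth)


@dataclass
class CalibratedScans:
    reports: list[dict]
    ct_events: pd.DataFrame
    diagnoses: pd.DataFrame
    labels: pd.DataFrame  # report_id, true_label
    true_counts: pd.DataFrame  # report_id + kp_<cluster> ground-truth counts
    true_log_odds: dict[str, float]


def generate_calibrated_scans(
    config: GeneratorConfig, n_scans: int, seed: int
) -> CalibratedScans:
    """One scan per synthetic patient with features conditionally independent
    given the true indication, so logistic log odds ratios are known exactly.

    The >=6-month-interval feature is realized through actual prior-CT dates
    (200 vs 90 days before the index scan), cluster counts through Poisson
    draws rendered into report text, and ICD counts through diagnosis rows
    inside the 183-day window.
    """
    rng = np.random.default_rng(seed)
    origin = date(2012, 6, 1)
    p = config.label_prevalence
    q = config.interval_binary_probs

    reports, ct_rows, diag_rows, label_rows, count_rows = [], [], [], [], []
    for i in range(n_scans):
        label = "surveillance" if rng.random() < p else "other"
        pid = f"P{i:05d}"
        rid = f"R{i:06d}"
        scan_day = 400 + int(rng.integers(0, 1000))
        scan_date = _to_date(origin, scan_day)
        long_interval = rng.random() < q[label]
        prior_day = scan_day - (200 if long_interval else 90)
        prior_rid = f"Q{i:06d}"
        ct_rows.append({"patient_id": pid, "date": _to_date(origin, prior_day),
                        "report_id": prior_rid, "days_from_origin": prior_day})
        ct_rows.append({"patient_id": pid, "date": scan_date,
                        "report_id": rid, "days_from_origin": scan_day})
        reports.append({"report_id": prior_rid, "patient_id": pid,
                        "scan_date": _to_date(origin, prior_day),
                        "text": "INDICATION: History of lung cancer.\n"
                                "FINDINGS: The lungs are clear."})
        event = CTEvent(pid, float(scan_day), label, report_id=rid)
        rendered = render_report(event, config, rng)
        reports.append({"report_id": rid, "patient_id": pid,
                        "scan_date": scan_date, "text": rendered.text})
        for group, codes in (("symptom", SYMPTOM_CODES), ("lung_dx", LUNG_DX_CODES)):
            rate = config.icd_rates[group][label]
            for _ in range(int(rng.poisson(rate))):
                offset = int(rng.integers(0, 184))
                diag_rows.append({"patient_id": pid,
                                  "date": _to_date(origin, scan_day - offset),
                                  "icd_code": codes[int(rng.integers(len(codes)))]})
        label_rows.append({"report_id": rid, "patient_id": pid, "true_label": label})
        count_rows.append({"report_id": rid,
                           **{f"kp_{c}": rendered.phrase_counts[c] for c in CLUSTER_NAMES}})

    return CalibratedScans(
        reports=reports,
        ct_events=pd.DataFrame(ct_rows),
        diagnoses=pd.DataFrame(diag_rows, columns=["patient_id", "date", "icd_code"]),
        labels=pd.DataFrame(label_rows),
        true_counts=pd.DataFrame(count_rows),
        true_log_odds=config.true_log_odds(),
    )
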