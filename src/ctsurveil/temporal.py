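"""Patient-level temporal surveillance patterns from per-scan indications.

Timelines are measured in days from the time origin (the five-year survival
anniversary). The decade after the origin is discretized into 40 quarters of
365.25/4 days; each cell holds none / other / surveillance (surveillance
takes precedence when a quarter contains both). Annual-surveillance
adherence is detected with a sliding gap rule: a surveillance scan qualifies
when the gap to its predecessor — the previous surveillance scan, or the
time origin for the first one — lies within a tolerance band around the
365-day target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import ConfigurationError

__all__ = [
    "PatientTimeline",
    "QuarterlyIndicationMatrix",
    "AdherenceResult",
    "QUARTER_DAYS",
    "N_QUARTERS",
    "STATE_NONE",
    "STATE_OTHER",
    "STATE_SURVEILLANCE",
    "build_quarterly_matrix",
    "detect_annual_adherence",
    "cluster_timelines",
    "surveillance_prevalence_by_year",
    "timelines_from_predictions",
]

QUARTER_DAYS = 365.25 / 4.0  # exact 40-column decade
N_QUARTERS = 40

STATE_NONE = 0
STATE_OTHER = 1
STATE_SURVEILLANCE = 2


@dataclass
class PatientTimeline:
    patient_id: str
    events: list[tuple[float, str]]  # (days from origin, indication), sorted
    follow_up_days: float

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e[0], e[1]))
        for days, indication in self.events:
            if days < 0:
                raise ValueError(
                    f"{self.patient_id}: negative event time {days}")
            if indication not in ("surveillance", "other"):
                raise ValueError(
                    f"{self.patient_id}: unknown indication {indication!r}")

    def surveillance_days(self) -> list[float]:
        return [d for d, ind in self.events if ind == "surveillance"]


@dataclass
class QuarterlyIndicationMatrix:
    patient_ids: list[str]
    states: np.ndarray  # (n, 40) int8
    in_followup: np.ndarray  # (n, 40) bool censoring mask

    def __len__(self):
        return len(self.patient_ids)


def build_quarterly_matrix(timelines: list[PatientTimeline]) -> QuarterlyIndicationMatrix:
    """Quarter index = floor(days / 91.3125), clipped to [0, 39]; quarters
    holding both indications are marked surveillance."""
    n = len(timelines)
    states = np.zeros((n, N_QUARTERS), dtype=np.int8)
    mask = np.zeros((n, N_QUARTERS), dtype=bool)
    ids = []
    for i, tl in enumerate(timelines):
        ids.append(tl.patient_id)
        last_q = int(min(np.floor(tl.follow_up_days / QUARTER_DAYS), N_QUARTERS - 1))
        if tl.follow_up_days > 0:
            mask[i, : last_q + 1] = True
        for days, indication in tl.events:
            if days < 0:
                raise ValueError(f"{tl.patient_id}: negative event time {days}")
            q = int(min(np.floor(days / QUARTER_DAYS), N_QUARTERS - 1))
            state = STATE_SURVEILLANCE if indication == "surveillance" else STATE_OTHER
            states[i, q] = max(states[i, q], state)  # surveillance precedence
    return QuarterlyIndicationMatrix(patient_ids=ids, states=states, in_followup=mask)


@dataclass
class AdherenceResult:
    patient_id: str
    adherent: bool
    qualifying_pairs: list[tuple[float, float, float]] = field(default_factory=list)
    # (anchor day, predecessor day, gap in days); predecessor 0.0 = origin


def detect_annual_adherence(
    timeline: PatientTimeline,
    target: float = 365.0,
    tolerance: float = 92.0,
) -> AdherenceResult:
    """Flag patients keeping an approximately annual surveillance rhythm.

    Each surveillance scan is paired with its predecessor (the previous
    surveillance scan, or the time origin for the first); the pair qualifies
    when its gap lies in [target - tolerance, target + tolerance]. Adherent
    iff at least one pair qualifies. Widening the tolerance band can only
    add qualifying pairs, so adherence is monotone in the tolerance.
    """
    if tolerance >= target:
        raise ConfigurationError(
            f"tolerance ({tolerance}) must be smaller than target ({target})")
    lo, hi = target - tolerance, target + tolerance
    days = timeline.surveillance_days()
    pairs = []
    prev = 0.0  # the time origin is the first scan's virtual predecessor
    for d in days:
        gap = d - prev
        if lo <= gap <= hi:
            pairs.append((d, prev, gap))
        prev = d
    return AdherenceResult(timeline.patient_id, adherent=bool(pairs),
                           qualifying_pairs=pairs)


def cluster_timelines(
    matrix: QuarterlyIndicationMatrix,
    linkage_method: str = "average",
    k: int = 2,
) -> tuple[list[str], dict[str, int]]:
    """Agglomerative clustering of patients on Hamming distance over the 40
    categorical quarter states.

    Rows are canonicalized by patient id before clustering, so the result is
    invariant to input row order. Returns the dendrogram leaf ordering of
    patient ids and a patient -> cluster-label map (labels renumbered by
    first appearance in patient-id order).
    """
    n = len(matrix)
    if n == 0:
        return [], {}
    order = np.argsort(np.asarray(matrix.patient_ids, dtype=object))
    ids = [matrix.patient_ids[i] for i in order]
    states = matrix.states[order]
    if n == 1:
        return ids, {ids[0]: 1}
    dist = pdist(states.astype(float), metric="hamming")
    tree = linkage(dist, method=linkage_method)
    raw = fcluster(tree, t=min(k, n), criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = {}
    for pid, lab in zip(ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[pid] = relabel[lab]
    leaf_order = [ids[i] for i in leaves_list(tree)]
    return leaf_order, labels


def surveillance_prevalence_by_year(matrix: QuarterlyIndicationMatrix) -> np.ndarray:
    """Per-year (10 values) proportion of patients with >=1 surveillance scan,
    among patients whose follow-up covers any part of that year."""
    years = np.full(10, np.nan)
    for y in range(10):
        cols = slice(4 * y, 4 * y + 4)
        at_risk = matrix.in_followup[:, cols].any(axis=1)
        if at_risk.any():
            surv = (matrix.states[:, cols] == STATE_SURVEILLANCE).any(axis=1)
            years[y] = float(surv[at_risk].mean())
    return years


def plot_indication_heatmap(matrix: QuarterlyIndicationMatrix, ax=None,
                            row_order: list[str] | None = None):
    """Plain heat map of the patients x quarters indication states
    (white: no CT, blue: other-indication CT, orange: surveillance CT)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2, len(matrix) * 0.08)))
    states = matrix.states
    if row_order is not None:
        index = {pid: i for i, pid in enumerate(matrix.patient_ids)}
        states = states[[index[p] for p in row_order]]
    cmap = ListedColormap(["white", "#4477aa", "#ee8833"])
    ax.imshow(states, aspect="auto", cmap=cmap, vmin=0, vmax=2,
              interpolation="nearest")
    ax.set_xlabel("quarter after time origin")
    ax.set_ylabel("patient")
    return ax


def timelines_from_predictions(
    predictions: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> list[PatientTimeline]:
    """Assemble per-patient timelines from the predictions CSV (report_id,
    patient_id, scan_date, probability, label) and the outcomes table.

    Patients in ``outcomes`` without any scan get an empty timeline so they
    contribute to denominators downstream.
    """
    origin = {
        r["patient_id"]: pd.Timestamp(r["time_origin_date"])
        for _, r in outcomes.iterrows()
    }
    follow = {
        r["patient_id"]: float(
            (pd.Timestamp(r["last_followup_date"]) - pd.Timestamp(r["time_origin_date"])).days
        )
        for _, r in outcomes.iterrows()
    }
    events: dict[str, list[tuple[float, str]]] = {pid: [] for pid in origin}
    for _, row in predictions.iterrows():
        pid = row["patient_id"]
        if pid not in origin:
            continue
        days = float((pd.Timestamp(row["scan_date"]) - origin[pid]).days)
        events[pid].append((max(days, 0.0), str(row["label"])))
    return [
        PatientTimeline(pid, events[pid], follow_up_days=follow[pid])
        for pid in sorted(origin)
    ]
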