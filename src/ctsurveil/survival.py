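"""Propensity-weighted survival contrasts for CT-surveillance exposure.

Exposure groups are built from per-scan predicted indications (any CT,
>=1 predicted-surveillance CT, >=1 annual-adherent surveillance CT) against
patients with no CT after the time origin. Controls are matched on the
follow-up-duration distribution by decile-stratified sampling. Confounders
are balanced with stabilized, percentile-truncated inverse-probability-of-
treatment weights; effects come from a weighted Cox partial likelihood
(Efron ties, robust sandwich errors whenever weights differ from one) and a
weighted product-limit estimator. External standardization uses iterative
proportional fitting (raking) to reference category margins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .errors import ConfigurationError, IntegrityError

logger = logging.getLogger("ctsurveil")

__all__ = [
    "DEFAULT_CONFOUNDERS",
    "PropensityWeights",
    "CoxFit",
    "StandardizationWeights",
    "build_survival_records",
    "match_followup_controls",
    "fit_propensity_and_weights",
    "standardized_mean_differences",
    "weighted_cox",
    "weighted_km",
    "standardize_to_reference",
    "run_sensitivity_subsets",
]

DEFAULT_CONFOUNDERS = ("sex", "race_ethnicity", "stage", "histology")

EXPOSURE_DEFINITIONS = ("any", "surveillance", "annual")


def build_survival_records(
    bundle,
    predictions: pd.DataFrame,
    adherence: dict[str, bool] | None = None,
    exposure_def: str = "surveillance",
) -> pd.DataFrame:
    """One row per analyzable patient: exposure vs no-CT control, follow-up
    time in days from the time origin, death indicator and confounders.

    Patients with CT scans that do not meet the exposure definition (e.g.
    other-indication-only scans under ``surveillance``) are excluded rather
    than pooled with controls. Non-positive follow-up is excluded with a
    logged reason.
    """
    if exposure_def not in EXPOSURE_DEFINITIONS:
        raise ConfigurationError(
            f"exposure_def must be one of {EXPOSURE_DEFINITIONS}, got {exposure_def!r}")
    scanned = set(bundle.ct_events["patient_id"])
    surveilled = set(
        predictions.loc[predictions["label"] == "surveillance", "patient_id"])
    if exposure_def == "any":
        exposed_ids = scanned
    elif exposure_def == "surveillance":
        exposed_ids = surveilled
    else:
        if adherence is None:
            raise ConfigurationError("annual exposure requires adherence results")
        exposed_ids = {pid for pid, ok in adherence.items() if ok} & surveilled

    outcomes = bundle.outcomes
    origin = pd.to_datetime(outcomes["time_origin_date"])
    last = pd.to_datetime(outcomes["last_followup_date"])
    frame = pd.DataFrame({
        "patient_id": outcomes["patient_id"],
        "time_days": (last - origin).dt.days.astype(float),
        "event": outcomes["death_indicator"].astype(int),
    })
    frame = frame.merge(bundle.demographics, on="patient_id", how="left")
    if frame["sex"].isna().any():
        missing = frame.loc[frame["sex"].isna(), "patient_id"].tolist()
        raise IntegrityError(f"patients missing demographics: {missing[:10]}")

    frame["exposure"] = frame["patient_id"].isin(exposed_ids).astype(int)
    keep = (frame["exposure"] == 1) | ~frame["patient_id"].isin(scanned)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluded %d patients with CT not meeting exposure %r",
                    dropped, exposure_def)
    frame = frame[keep]
    nonpos = frame["time_days"] <= 0
    if nonpos.any():
        logger.info("excluded %d records with non-positive follow-up", int(nonpos.sum()))
        frame = frame[~nonpos]
    if "comorbidity" in frame.columns:
        frame["comorbidity"] = pd.to_numeric(frame["comorbidity"], errors="coerce").fillna(0.0)
    return frame.reset_index(drop=True)


def match_followup_controls(
    exposed_followup,
    control_pool: pd.DataFrame,
    strata: int = 10,
    seed: int = 0,
    followup_col: str = "time_days",
    target_size: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Select controls whose follow-up distribution matches the exposed.

    ``min(target_size or n_exposed, pool size)`` controls are sampled without
    replacement inside follow-up-decile strata of the exposed distribution,
    in the exposed strata proportions; an under-filled stratum borrows from
    the nearest strata with a warning. The post-match Kolmogorov-Smirnov
    distance never exceeds the pre-match one beyond sampling noise; both are
    returned as diagnostics.
    """
    if len(control_pool) == 0:
        raise ValueError("control pool is empty")
    exposed = np.asarray(exposed_followup, dtype=float)
    pool_fu = control_pool[followup_col].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    edges = np.quantile(exposed, np.linspace(0, 1, strata + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    exp_bins = np.clip(np.digitize(exposed, edges[1:-1]), 0, strata - 1)
    pool_bins = np.clip(np.digitize(pool_fu, edges[1:-1]), 0, strata - 1)
    props = np.bincount(exp_bins, minlength=strata) / len(exposed)

    m = min(len(control_pool), len(exposed)) if target_size is None else \
        min(int(target_size), len(control_pool))
    # largest-remainder allocation of the m slots to strata
    raw = m * props
    want = np.floor(raw).astype(int)
    for j in np.argsort(-(raw - want), kind="mergesort")[: m - want.sum()]:
        want[j] += 1

    pool_positions = {j: list(np.flatnonzero(pool_bins == j)) for j in range(strata)}
    take_idx: list[int] = []
    for j in range(strata):
        if want[j] == 0:
            continue
        have = list(pool_positions[j])
        if len(have) < want[j]:
            warnings.warn(
                f"stratum {j} has {len(have)} controls for {want[j]} slots; "
                "borrowing from nearest strata", UserWarning, stacklevel=2)
            for q in sorted(range(strata), key=lambda q: (abs(q - j), q))[1:]:
                while len(have) < want[j] and pool_positions[q]:
                    have.append(pool_positions[q].pop())
        chosen = rng.choice(len(have), size=min(want[j], len(have)), replace=False)
        picked = [have[c] for c in sorted(chosen)]
        for p in picked:
            if p in pool_positions[j]:
                pool_positions[j].remove(p)
        take_idx.extend(picked)

    matched = control_pool.iloc[sorted(set(take_idx))].reset_index(drop=True)
    ks_pre = float(stats.ks_2samp(exposed, pool_fu).statistic)
    ks_post = float(stats.ks_2samp(exposed, matched[followup_col].to_numpy(float)).statistic)
    return matched, {"ks_pre": ks_pre, "ks_post": ks_post, "n_matched": len(matched)}


# ---------------------------------------------------------------------------
# propensity weighting


@dataclass
class PropensityWeights:
    scores: np.ndarray
    weights: np.ndarray  # stabilized
    truncated: np.ndarray  # bool flags
    balance: pd.DataFrame  # per confounder: smd_unweighted, smd_weighted
    covariates: tuple[str, ...]


def _design(records: pd.DataFrame, covariates) -> pd.DataFrame:
    parts = []
    for cov in covariates:
        col = records[cov]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(cov).to_frame())
        else:
            parts.append(pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
                         .astype(float))
    if not parts:
        return pd.DataFrame(index=records.index)
    return pd.concat(parts, axis=1)


def _model_design(records: pd.DataFrame, covariates) -> pd.DataFrame:
    """Dummy design for model fitting; constant columns (categories absent or
    universal in this sample) are dropped with a warning."""
    X = _design(records, covariates)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant design columns {constant}",
                      UserWarning, stacklevel=3)
        X = X.drop(columns=constant)
    return X


def standardized_mean_differences(
    records: pd.DataFrame,
    exposure: np.ndarray,
    covariates,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Max absolute standardized mean difference per confounder (over its
    dummy levels for categoricals); the denominator is the unweighted pooled
    standard deviation so weighted and unweighted SMDs are comparable."""
    X = _design(records, covariates)
    e = np.asarray(exposure, dtype=bool)
    w = np.ones(len(e)) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for cov in covariates:
        cols = [c for c in X.columns if c == cov or c.startswith(f"{cov}_")]
        smds = []
        for c in cols:
            x = X[c].to_numpy(float)
            sd = np.sqrt((np.var(x[e], ddof=1) + np.var(x[~e], ddof=1)) / 2.0)
            if sd == 0:
                continue
            m1 = np.average(x[e], weights=w[e])
            m0 = np.average(x[~e], weights=w[~e])
            smds.append(abs(m1 - m0) / sd)
        rows.append({"confounder": cov, "smd": max(smds) if smds else 0.0})
    return pd.DataFrame(rows)


def fit_propensity_and_weights(
    records: pd.DataFrame,
    covariates=DEFAULT_CONFOUNDERS,
    truncation: tuple[float, float] = (0.01, 0.99),
    exposure_col: str = "exposure",
) -> PropensityWeights:
    """Logistic propensity model and stabilized IPT weights.

    Scores are truncated at the given percentiles of the fitted score
    distribution before weighting; the balance table reports unweighted and
    weighted SMDs for every adjusted confounder.
    """
    e = records[exposure_col].to_numpy(dtype=float)
    if len(np.unique(e)) < 2:
        raise ValueError("both exposure arms must be present")
    X = _model_design(records, covariates)
    import statsmodels.api as sm

    from .model import _irls_ridge

    design = sm.add_constant(X.to_numpy(dtype=float))
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(e, design).fit(disp=0, maxiter=200)
            candidate = np.asarray(res.params)
            if np.all(np.isfinite(candidate)) and np.abs(candidate).max() < 30:
                params = candidate
        except Exception:
            pass
    if params is None:
        # sparse confounder cells can make the unpenalized Hessian singular;
        # a tiny-ridge IRLS fit stabilizes those without changing the scores
        params, _ = _irls_ridge(design, e, ridge=1e-6)
        if not np.all(np.isfinite(params)) or np.abs(params).max() >= 15:
            raise ValueError(
                "propensity model is separated; consider collapsing sparse "
                "confounder categories")
    ps = 1.0 / (1.0 + np.exp(-np.clip(design @ params, -30, 30)))
    lo, hi = np.quantile(ps, truncation)
    truncated = (ps < lo) | (ps > hi)
    ps_t = np.clip(ps, lo, hi)
    p_exposed = e.mean()
    w = np.where(e == 1, p_exposed / ps_t, (1 - p_exposed) / (1 - ps_t))

    bal_un = standardized_mean_differences(records, e == 1, covariates)
    bal_w = standardized_mean_differences(records, e == 1, covariates, weights=w)
    balance = bal_un.rename(columns={"smd": "smd_unweighted"})
    balance["smd_weighted"] = bal_w["smd"]
    return PropensityWeights(
        scores=ps, weights=w, truncated=truncated, balance=balance,
        covariates=tuple(covariates),
    )


# ---------------------------------------------------------------------------
# weighted Cox and Kaplan-Meier


@dataclass
class CoxFit:
    hazard_ratio: float
    ci: tuple[float, float]
    p_value: float
    log_hr: float
    se: float
    coefficients: dict[str, float]
    robust: bool
    n: int
    n_events: int
    balance: pd.DataFrame | None = field(default=None, repr=False)


def weighted_cox(
    records: pd.DataFrame,
    weights: np.ndarray | None = None,
    covariates=DEFAULT_CONFOUNDERS,
    exposure_col: str = "exposure",
    time_col: str = "time_days",
    event_col: str = "event",
) -> CoxFit:
    """Weighted Cox partial likelihood with Efron tie handling; sandwich
    (robust) standard errors whenever non-unit weights are supplied."""
    if records[event_col].sum() == 0:
        raise ValueError("no events in the data; Cox model undefined")
    for arm in (0, 1):
        if records.loc[records[exposure_col] == arm, event_col].sum() == 0:
            raise ValueError(f"no events in exposure arm {arm}")
    df = pd.concat(
        [records[[time_col, event_col, exposure_col]].reset_index(drop=True),
         _model_design(records, covariates).reset_index(drop=True)],
        axis=1,
    )
    robust = weights is not None and not np.allclose(weights, 1.0)
    if weights is not None:
        df["_w"] = np.asarray(weights, dtype=float)
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter.fit(
            df,
            duration_col=time_col,
            event_col=event_col,
            weights_col="_w" if weights is not None else None,
            robust=robust,
        )
    summary = fitter.summary
    row = summary.loc[exposure_col]
    return CoxFit(
        hazard_ratio=float(np.exp(row["coef"])),
        ci=(float(np.exp(row["coef lower 95%"])), float(np.exp(row["coef upper 95%"]))),
        p_value=float(row["p"]),
        log_hr=float(row["coef"]),
        se=float(row["se(coef)"]),
        coefficients={name: float(summary.loc[name, "coef"]) for name in summary.index},
        robust=robust,
        n=len(df),
        n_events=int(records[event_col].sum()),
    )


def weighted_km(
    records: pd.DataFrame,
    weights: np.ndarray | None = None,
    group_col: str = "exposure",
    time_col: str = "time_days",
    event_col: str = "event",
) -> dict[object, pd.DataFrame]:
    """Weighted product-limit survival curve per exposure arm.

    Curves start at S(0) = 1 and step only at event times:
    S(t) = prod over event times u <= t of (1 - d_w(u) / n_w(u)).
    """
    w = np.ones(len(records)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for arm, grp in records.groupby(group_col):
        gw = w[grp.index.to_numpy()] if weights is not None else np.ones(len(grp))
        t = grp[time_col].to_numpy(dtype=float)
        d = grp[event_col].to_numpy(dtype=int)
        order = np.argsort(t, kind="mergesort")
        t, d, gw = t[order], d[order], gw[order]
        times = [0.0]
        surv = [1.0]
        s = 1.0
        total = gw.sum()
        removed = 0.0
        for u in np.unique(t[d == 1]):
            at_risk = total - gw[t < u].sum()
            deaths = gw[(t == u) & (d == 1)].sum()
            if at_risk <= 0:
                break
            s *= 1.0 - deaths / at_risk
            times.append(float(u))
            surv.append(float(s))
            removed += deaths
        out[arm] = pd.DataFrame({"time": times, "survival": surv})
    return out


# ---------------------------------------------------------------------------
# external standardization (raking)


@dataclass
class StandardizationWeights:
    weights: np.ndarray
    achieved_margins: dict[str, dict[str, float]]
    reference_margins: dict[str, dict[str, float]]
    n_iter: int
    converged: bool


def standardize_to_reference(
    records: pd.DataFrame,
    reference_margins: dict[str, dict[str, float]],
    tol: float = 0.01,
    max_iter: int = 100,
) -> StandardizationWeights:
    """Iterative proportional fitting of per-patient weights so that weighted
    category margins match an external reference population.

    Weights are renormalized to sum to the cohort size; a reference category
    with positive target mass but zero cohort mass raises an error naming
    the cell.
    """
    n = len(records)
    for var, margins in reference_margins.items():
        total = sum(margins.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"reference margins for {var!r} sum to {total}")
        present = set(records[var].astype(str))
        for level, target in margins.items():
            if target > 0 and level not in present:
                raise ValueError(
                    f"reference cell ({var!r}={level!r}) has zero cohort mass")
    w = np.ones(n, dtype=float)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for var, margins in reference_margins.items():
            values = records[var].astype(str).to_numpy()
            for level, target in margins.items():
                mask = values == level
                current = w[mask].sum() / w.sum()
                if current > 0:
                    w[mask] *= target / current
        w *= n / w.sum()
        achieved = {
            var: {lvl: float(w[records[var].astype(str).to_numpy() == lvl].sum() / w.sum())
                  for lvl in margins}
            for var, margins in reference_margins.items()
        }
        worst = max(
            abs(achieved[var][lvl] - reference_margins[var][lvl])
            for var in reference_margins for lvl in reference_margins[var]
        )
        if worst <= tol:
            converged = True
            break
    return StandardizationWeights(
        weights=w, achieved_margins=achieved,
        reference_margins=reference_margins, n_iter=it, converged=converged,
    )


# ---------------------------------------------------------------------------
# sensitivity subsets


SUBSET_DEFINITIONS = {
    "all": lambda df: pd.Series(True, index=df.index),
    "early_stage": lambda df: df["stage"].isin(["I", "II", "IIIA"]),
    "surgical_stage12": lambda df: df["stage"].isin(["I", "II"])
    & (df.get("surgery", pd.Series("", index=df.index)) == "yes"),
}


def run_sensitivity_subsets(
    records: pd.DataFrame,
    subsets=("all", "early_stage"),
    covariates=DEFAULT_CONFOUNDERS,
    truncation: tuple[float, float] = (0.01, 0.99),
) -> dict[str, CoxFit]:
    """Re-run the full propensity + weighted-Cox pipeline inside each subset."""
    out = {}
    for name in subsets:
        if name not in SUBSET_DEFINITIONS:
            raise ConfigurationError(f"unknown subset {name!r}")
        mask = SUBSET_DEFINITIONS[name](records)
        sub = records[mask].reset_index(drop=True)
        if len(sub) == 0:
            raise ValueError(f"subset {name!r} is empty")
        pw = fit_propensity_and_weights(sub, covariates=covariates, truncation=truncation)
        fit = weighted_cox(sub, weights=pw.weights, covariates=covariates)
        fit.balance = pw.balance
        out[name] = fit
    return out
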