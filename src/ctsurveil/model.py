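"""Logistic indication classifier: univariate screening, forward feature
selection by cross-validated AUC, maximum-likelihood fitting with Wald
intervals, discrimination (tie-corrected rank AUC with DeLong or bootstrap
confidence intervals), threshold metrics and calibration, and the
three-variant comparison (NLP-only, structured-only, hybrid).

Splits and cross-validation folds are patient-grouped and label-stratified:
reports from one patient are correlated and must never straddle a split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedGroupKFold, train_test_split

from .errors import NotFittedError, SchemaError

__all__ = [
    "MODEL_SCHEMA_VERSION",
    "IndicationModel",
    "PerformanceReport",
    "auc_score",
    "delong_ci",
    "bootstrap_auc_ci",
    "evaluate_discrimination",
    "evaluate_threshold_and_calibration",
    "univariate_screen",
    "patient_grouped_split",
    "cv_fold_indices",
    "select_features",
    "fit_model",
    "compare_variants",
]

MODEL_SCHEMA_VERSION = 1
POSITIVE_LABEL = "surveillance"
RIDGE_EPS = 1e-8  # numerical guard against quasi-separation, not regularization


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == POSITIVE_LABEL).astype(float)
    return arr.astype(float)


# ---------------------------------------------------------------------------
# discrimination


def auc_score(scores, labels) -> float:
    """Tie-corrected rank AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_ci(scores, labels, conf_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC with DeLong variance-based confidence interval."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC requires both classes present")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # structural components for positives
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def bootstrap_auc_ci(
    scores, labels, n_boot: int = 2000, conf_level: float = 0.95, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Stratified bootstrap percentile interval for the AUC."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_pos, size=len(idx_pos), replace=True),
            rng.choice(idx_neg, size=len(idx_neg), replace=True),
        ])
        stats_[b] = auc_score(s[take], y[take])
    lo, hi = np.quantile(stats_, [(1 - conf_level) / 2, 0.5 + conf_level / 2])
    return auc_score(s, y), (float(lo), float(hi))


def evaluate_discrimination(
    predictions, labels, ci_method: str = "delong", **kwargs
) -> tuple[float, tuple[float, float]]:
    if ci_method == "delong":
        return delong_ci(predictions, labels, **kwargs)
    if ci_method == "bootstrap":
        return bootstrap_auc_ci(predictions, labels, **kwargs)
    raise ValueError(f"unknown ci_method {ci_method!r}")


# ---------------------------------------------------------------------------
# threshold metrics and calibration


@dataclass
class PerformanceReport:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    n: int
    prevalence: float
    calibration: pd.DataFrame = field(repr=False, default=None)
    roc: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "threshold": self.threshold,
            "n": self.n, "prevalence": self.prevalence,
        }


def evaluate_threshold_and_calibration(
    predictions, labels, threshold: float = 0.5, bins: int = 10,
    ci_method: str = "delong",
) -> PerformanceReport:
    """2x2-table metrics at the threshold (>= classifies positive) plus a
    decile calibration table; empty bins carry a null observed rate."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    y = _as_binary(labels)
    p = np.asarray(predictions, dtype=float)
    pred_pos = p >= threshold
    tp = int((pred_pos & (y == 1)).sum())
    tn = int((~pred_pos & (y == 0)).sum())
    fp = int((pred_pos & (y == 0)).sum())
    fn = int((~pred_pos & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(y)

    edges = np.linspace(0.0, 1.0, bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        mask = which == b
        rows.append({
            "bin": b,
            "lower": edges[b],
            "upper": edges[b + 1],
            "n": int(mask.sum()),
            "mean_predicted": float(p[mask].mean()) if mask.any() else np.nan,
            "observed_rate": float(y[mask].mean()) if mask.any() else np.nan,
        })
    order = np.argsort(-p, kind="mergesort")
    tps = np.cumsum(y[order])
    fps = np.cumsum(1 - y[order])
    roc = pd.DataFrame({
        "fpr": np.concatenate([[0.0], fps / max(fps[-1], 1)]),
        "tpr": np.concatenate([[0.0], tps / max(tps[-1], 1)]),
    })
    auc, ci = evaluate_discrimination(p, y, ci_method=ci_method)
    return PerformanceReport(
        auc=auc, auc_ci=ci, sensitivity=sens, specificity=spec, accuracy=acc,
        threshold=threshold, n=len(y), prevalence=float(y.mean()),
        calibration=pd.DataFrame(rows), roc=roc,
    )


# ---------------------------------------------------------------------------
# logistic fitting


def _irls_ridge(X: np.ndarray, y: np.ndarray, ridge: float = RIDGE_EPS,
                max_iter: int = 100, tol: float = 1e-10):
    """Newton/IRLS logistic fit with a tiny ridge term for numerical stability."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(k)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-12)
    cov = np.linalg.inv((X * w[:, None]).T @ X + ridge * np.eye(k))
    return beta, np.sqrt(np.diag(cov))


def _fit_logistic(X: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit (statsmodels), with a ridge-stabilized
    IRLS fallback when the unpenalized likelihood is unbounded."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params, bse = np.asarray(res.params), np.asarray(res.bse)
            if np.all(np.isfinite(params)) and np.all(np.isfinite(bse)) \
                    and np.abs(params).max() < 30:
                return params, bse, False
        except Exception:
            pass
    beta, bse = _irls_ridge(X, y)
    separated = bool(np.abs(beta).max() >= 15)
    return beta, bse, separated


@dataclass
class UnivariateScreenResult:
    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    separation: bool
    constant: bool


def univariate_screen(
    features: pd.DataFrame, labels, conf_level: float = 0.95
) -> list[UnivariateScreenResult]:
    """Single-predictor logistic fit per feature column.

    Constant columns and complete separation are flagged rather than reported
    as finite odds ratios.
    """
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("univariate screen requires both labels present")
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    out = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            out.append(UnivariateScreenResult(name, np.nan, np.nan, np.nan, np.nan,
                                              separation=False, constant=True))
            continue
        xs = np.std(x)
        identical = xs > 0 and abs(abs(np.corrcoef(x, y)[0, 1])) > 1 - 1e-12
        X = np.column_stack([np.ones_like(x), x])
        beta, bse, separated = _fit_logistic(X, y)
        separated = separated or identical
        if separated:
            out.append(UnivariateScreenResult(name, np.nan, np.nan, np.nan, np.nan,
                                              separation=True, constant=False))
            continue
        b, se = beta[1], bse[1]
        p = 2 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan
        out.append(UnivariateScreenResult(
            name, float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se)),
            float(p), separation=False, constant=False,
        ))
    return out


# ---------------------------------------------------------------------------
# splits and folds (patient-grouped, label-stratified)


def patient_grouped_split(
    patients, labels, test_fraction: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean train/test masks over reports, splitting at the patient level
    stratified by each patient's majority label."""
    patients = np.asarray(patients)
    y = _as_binary(labels)
    frame = pd.DataFrame({"patient": patients, "y": y})
    per_patient = frame.groupby("patient")["y"].mean() >= 0.5
    ids = per_patient.index.to_numpy()
    strata = per_patient.to_numpy().astype(int)
    train_ids, test_ids = train_test_split(
        ids, test_size=test_fraction, random_state=seed, stratify=strata
    )
    train_mask = np.isin(patients, train_ids)
    return train_mask, ~train_mask


def cv_fold_indices(
    patients, labels, folds: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-grouped, label-stratified K-fold index pairs."""
    y = _as_binary(labels)
    splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    X_dummy = np.zeros((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return list(splitter.split(X_dummy, y, groups=np.asarray(patients)))


def _cv_auc(features: pd.DataFrame, y: np.ndarray, cols: list[str], folds) -> float:
    X = features[cols].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    aucs = []
    for train_idx, test_idx in folds:
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            continue
        beta, _, _ = _fit_logistic(X[train_idx], y[train_idx])
        scores = X[test_idx] @ beta
        aucs.append(auc_score(scores, y[test_idx]))
    return float(np.mean(aucs)) if aucs else float("nan")


def select_features(
    features: pd.DataFrame,
    labels,
    patients,
    candidates: list[str] | None = None,
    folds: int = 10,
    seed: int = 0,
    min_improvement: float = 0.002,
) -> list[str]:
    """Forward stepwise selection maximizing mean cross-validated AUC.

    Stops when the best remaining candidate improves mean CV AUC by less
    than ``min_improvement``. Ties break by column order for determinism.
    """
    candidates = list(candidates if candidates is not None else features.columns)
    if not candidates:
        raise ValueError("empty candidate feature set")
    y = _as_binary(labels)
    fold_idx = cv_fold_indices(patients, y, folds=folds, seed=seed)
    selected: list[str] = []
    best = 0.5
    while candidates:
        trials = [(c, _cv_auc(features, y, selected + [c], fold_idx)) for c in candidates]
        name, score = max(trials, key=lambda t: (t[1], -candidates.index(t[0])))
        if not np.isfinite(score) or score < best + min_improvement:
            break
        selected.append(name)
        candidates.remove(name)
        best = score
    return selected


# ---------------------------------------------------------------------------
# the fitted model


@dataclass
class IndicationModel:
    feature_names: list[str]
    intercept: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)
    standard_errors: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.5
    cv: dict = field(default_factory=dict)
    lexicon_version: str = ""
    feature_version: str = ""
    fitted: bool = False
    schema_version: int = MODEL_SCHEMA_VERSION

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise SchemaError(f"feature vector missing model features {missing}")
        X = features[self.feature_names].to_numpy(dtype=float)
        beta = np.array([self.coefficients[f] for f in self.feature_names])
        return self.intercept + X @ beta

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("model is not fitted")
        return 1.0 / (1.0 + np.exp(-np.clip(self.linear_predictor(features), -30, 30)))

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        p = self.predict_proba(features)
        label = np.where(p >= self.threshold, POSITIVE_LABEL, "other")
        return pd.DataFrame({"probability": p, "label": label})

    def odds_ratios(self, conf_level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + conf_level / 2.0)
        rows = []
        for f in self.feature_names:
            b, se = self.coefficients[f], self.standard_errors.get(f, np.nan)
            rows.append({
                "feature": f, "log_or": b, "or": np.exp(b),
                "ci_low": np.exp(b - z * se), "ci_high": np.exp(b + z * se),
                "p_value": 2 * stats.norm.sf(abs(b / se)) if se and se > 0 else np.nan,
            })
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        if not self.fitted:
            raise NotFittedError("refusing to serialize an unfitted model")
        return {
            "schema_version": self.schema_version,
            "feature_names": self.feature_names,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "threshold": self.threshold,
            "cv": self.cv,
            "lexicon_version": self.lexicon_version,
            "feature_version": self.feature_version,
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "IndicationModel":
        if not isinstance(payload, dict) or "schema_version" not in payload:
            raise SchemaError("model document lacks a schema_version field")
        if payload["schema_version"] != MODEL_SCHEMA_VERSION:
            raise SchemaError(
                f"model schema {payload['schema_version']} != library schema "
                f"{MODEL_SCHEMA_VERSION}"
            )
        required = ("feature_names", "intercept", "coefficients", "threshold")
        missing = [k for k in required if k not in payload]
        if missing:
            raise SchemaError(f"model document missing keys {missing}")
        return cls(
            feature_names=list(payload["feature_names"]),
            intercept=float(payload["intercept"]),
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            standard_errors={k: float(v) for k, v in payload.get("standard_errors", {}).items()},
            threshold=float(payload["threshold"]),
            cv=dict(payload.get("cv", {})),
            lexicon_version=payload.get("lexicon_version", ""),
            feature_version=payload.get("feature_version", ""),
            fitted=True,
        )


def fit_model(
    features: pd.DataFrame,
    labels,
    feature_names: list[str],
    patients=None,
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    lexicon_version: str = "",
    feature_version: str = "",
) -> IndicationModel:
    """Maximum-likelihood logistic fit on the full training data, with
    patient-grouped stratified CV AUC recorded for model comparison.

    Constant feature columns are dropped with a warning.
    """
    y = _as_binary(labels)
    usable = []
    for f in feature_names:
        x = features[f].to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            warnings.warn(f"dropping constant feature column {f!r}", UserWarning,
                          stacklevel=2)
        else:
            usable.append(f)
    if not usable:
        raise ValueError("no non-constant features to fit")
    X = np.column_stack([np.ones(len(y))] + [features[f].to_numpy(dtype=float)
                                             for f in usable])
    beta, bse, separated = _fit_logistic(X, y)
    if separated:
        warnings.warn("quasi-complete separation detected; ridge-stabilized "
                      "estimates returned", UserWarning, stacklevel=2)
    cv_info: dict = {"folds": folds, "seed": seed}
    if patients is not None and folds > 1:
        fold_idx = cv_fold_indices(patients, y, folds=folds, seed=seed)
        cv_info["mean_auc"] = _cv_auc(features, y, usable, fold_idx)
    return IndicationModel(
        feature_names=usable,
        intercept=float(beta[0]),
        coefficients={f: float(b) for f, b in zip(usable, beta[1:])},
        standard_errors={f: float(s) for f, s in zip(usable, bse[1:])},
        threshold=threshold,
        cv=cv_info,
        lexicon_version=lexicon_version,
        feature_version=feature_version,
        fitted=True,
    )


def compare_variants(
    features: pd.DataFrame,
    labels,
    patients,
    nlp_features: list[str],
    structured_features: list[str],
    test_fraction: float = 0.3,
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict[str, PerformanceReport]:
    """Fit NLP-only, structured-only and hybrid models on one shared
    patient-grouped split and report held-out performance side by side."""
    y = _as_binary(labels)
    train, test = patient_grouped_split(patients, y, test_fraction=test_fraction, seed=seed)
    variants = {
        "nlp_only": list(nlp_features),
        "structured_only": list(structured_features),
        "hybrid": list(nlp_features) + list(structured_features),
    }
    out = {}
    train_pat = np.asarray(patients)[train]
    for name, cols in variants.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = fit_model(features.loc[train], y[train], cols,
                              patients=train_pat, folds=folds, seed=seed,
                              threshold=threshold)
        p = model.predict_proba(features.loc[test])
        out[name] = evaluate_threshold_and_calibration(p, y[test], threshold=threshold)
    return out
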