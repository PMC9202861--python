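"""Statistical layer over the geometric fingerprint table.

Implements the paper-style analysis of the two-class measurement table:
five-number group summaries, Welch's unequal-variance t-test, a
single-measurement threshold classifier on the helix-overlap RMSD, and an
L1-penalized (lasso) logistic regression over all geometric features with
cross-validated penalty selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "GroupSummary",
    "WelchResult",
    "ThresholdRule",
    "LassoModel",
    "StatsError",
    "summarize_groups",
    "welch_t_test",
    "fit_threshold",
    "lasso_fit",
    "predict",
    "load_measurements",
    "CAN_FORM",
    "CANNOT_FORM",
    "FEATURE_COLUMNS",
]

CAN_FORM = "can_form"
CANNOT_FORM = "cannot_form"

#: Geometric feature columns of the fingerprint table, in model order.
FEATURE_COLUMNS = (
    "rmsd_vs_1EMA",
    "rmsd_vs_2AWJ",
    "rmsd_vs_1H4U",
    "tight_turn",
    *[f"HD{k}" for k in range(1, 12)],
)


class StatsError(ValueError):
    """Raised for degenerate statistical input."""


@dataclass(frozen=True)
class GroupSummary:
    """Five-number summary plus mean/sd for one class (boxplot statistics)."""

    group: str
    n: int
    mean: float
    sd: float
    min: float
    q1: float
    median: float
    q3: float
    max: float


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""

    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ThresholdRule:
    """Single-measurement classifier: value <= cutoff (or >=) => can_form.

    A value exactly at the cutoff is assigned ``can_form`` (measure-zero
    convention, documented here once).
    """

    feature: str = "rmsd_vs_1EMA"
    cutoff: float = float("nan")
    direction: str = "below"  # below => can_form | above => can_form
    mode: str = "midpoint"  # how the cutoff was fitted


@dataclass
class LassoModel:
    """L1-penalized logistic classifier on standardized features.

    Coefficients are reported on the original feature scale; the
    standardization record (per-feature mean, sd) makes the fit reproducible.
    ``lambda_`` is the per-sample L1 penalty weight (1 / (C * n_samples) in
    scikit-learn's parameterization).
    """

    feature_names: list[str]
    coefficients: np.ndarray  # original scale
    intercept: float  # original scale
    lambda_: float
    standardization: dict[str, tuple[float, float]]
    dropped_features: list[str] = field(default_factory=list)
    lambda_path: pd.DataFrame | None = None

    @property
    def selected_features(self) -> list[str]:
        return [
            name
            for name, coef in zip(self.feature_names, self.coefficients)
            if coef != 0.0
        ]

    def coefficient_table(self) -> pd.DataFrame:
        rows = [{"feature": "(intercept)", "coefficient": self.intercept}]
        rows += [
            {"feature": n, "coefficient": float(c)}
            for n, c in zip(self.feature_names, self.coefficients)
        ]
        return pd.DataFrame(rows)


def _two_groups(values: Sequence[float], labels: Sequence[str]) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise StatsError("values and labels differ in length")
    groups = {g: values[labels == g] for g in (CAN_FORM, CANNOT_FORM)}
    for g, v in groups.items():
        if v.size == 0:
            raise StatsError(f"empty class: {g}")
    return groups


def summarize_groups(
    values: Sequence[float], labels: Sequence[str]
) -> dict[str, GroupSummary]:
    """Per-class mean, sd and five-number summary.

    Quartiles use linear interpolation (numpy default, R type-7), the
    convention matching standard boxplot software.
    """
    out: dict[str, GroupSummary] = {}
    for group, v in _two_groups(values, labels).items():
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[group] = GroupSummary(
            group=group,
            n=int(v.size),
            mean=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            min=float(np.min(v)),
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            max=float(np.max(v)),
        )
    return out


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (mean_x - mean_y) / sqrt(s²x/nx + s²y/ny), with Welch-Satterthwaite
    degrees of freedom (non-integer in general).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # identical constant samples: no evidence of difference
            return WelchResult(t=0.0, df=float(x.size + y.size - 2), p=1.0)
        raise StatsError("both sample variances are zero")
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def fit_threshold(
    values: Sequence[float],
    labels: Sequence[str],
    feature: str = "rmsd_vs_1EMA",
    mode: str = "midpoint",
) -> ThresholdRule:
    """Fit the single-measurement cutoff separating the two classes.

    ``midpoint`` (default): cutoff halfway between the two class means.
    ``minerror``: cutoff minimizing training misclassification; ties are
    broken by the midpoint of the best-scoring interval.
    The side of the cutoff assigned to ``can_form`` follows the class means
    (for helix RMSD vs the mature structure, chromophore formers sit lower).
    """
    groups = _two_groups(values, labels)
    m_can = float(np.mean(groups[CAN_FORM]))
    m_cannot = float(np.mean(groups[CANNOT_FORM]))
    if m_can == m_cannot:
        raise StatsError("degenerate separation: class means are identical")
    direction = "below" if m_can < m_cannot else "above"

    if mode == "midpoint":
        cutoff = 0.5 * (m_can + m_cannot)
    elif mode == "minerror":
        v = np.asarray(values, dtype=float)
        lab = np.asarray(labels)
        order = np.argsort(v)
        vs = v[order]
        candidates = np.concatenate(
            [[vs[0] - 1.0], (vs[:-1] + vs[1:]) / 2.0, [vs[-1] + 1.0]]
        )
        errors = np.array(
            [
                np.sum(
                    _apply_threshold(v, ThresholdRule(cutoff=c, direction=direction))
                    != lab
                )
                for c in candidates
            ]
        )
        best = candidates[errors == errors.min()]
        cutoff = float((best.min() + best.max()) / 2.0)
    else:
        raise StatsError(f"unknown threshold mode {mode!r}")
    return ThresholdRule(feature=feature, cutoff=float(cutoff), direction=direction, mode=mode)


def _apply_threshold(values: np.ndarray, rule: ThresholdRule) -> np.ndarray:
    if rule.direction == "below":
        can = values <= rule.cutoff
    else:
        can = values >= rule.cutoff
    return np.where(can, CAN_FORM, CANNOT_FORM)


def lasso_fit(
    features: pd.DataFrame,
    labels: Sequence[str] | Sequence[int],
    lambda_grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> LassoModel:
    """L1-penalized logistic regression with cross-validated penalty choice.

    The response codes ``can_form`` as 1 and ``cannot_form`` as 0. Features
    are standardized internally (mean 0, sd 1); constant features are
    dropped with a warning and recorded on the model. The penalty is chosen
    by stratified k-fold cross-validated binomial deviance over
    ``lambda_grid`` (per-sample penalty weights, descending strength), and
    the full coefficient path is retained.
    """
    y = _as_binary(labels)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise StatsError("need at least 2 samples per class")
    X = features.copy()
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    names = list(X.columns)
    missing_mask = X.isna().any()
    if missing_mask.any():
        raise StatsError(f"missing values in features: {list(X.columns[missing_mask])}")

    Xv = X.to_numpy(dtype=float)
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0, ddof=0)
    Z = (Xv - mu) / sd
    n = Xv.shape[0]

    if lambda_grid is None:
        lambda_grid = np.geomspace(1.0, 1e-4, 20)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    def fit_at(lam: float, Zs: np.ndarray, ys: np.ndarray) -> LogisticRegression:
        C = 1.0 / (lam * Zs.shape[0])
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="saga", max_iter=20000, tol=1e-7
        )
        clf.fit(Zs, ys)
        # the intercept is unpenalized: given the coefficients, its exact
        # optimum solves a 1-D score equation; polish it by Newton (a no-op
        # when the solver has fully converged, a fix at extreme penalties)
        eta0 = Zs @ clf.coef_[0]
        b = float(clf.intercept_[0])
        for _ in range(50):
            p = 1.0 / (1.0 + np.exp(-(eta0 + b)))
            grad = float(np.sum(p - ys))
            hess = float(np.sum(p * (1 - p)))
            if hess <= 0 or abs(grad) < 1e-12:
                break
            b -= grad / hess
        clf.intercept_[0] = b
        return clf

    n_splits = min(folds, int(y.sum()), int((1 - y).sum()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    deviance = np.zeros(len(lambda_grid))
    for train, test in cv.split(Z, y):
        for i, lam in enumerate(lambda_grid):
            clf = fit_at(lam, Z[train], y[train])
            p = np.clip(clf.predict_proba(Z[test])[:, 1], 1e-12, 1 - 1e-12)
            deviance[i] += -2.0 * np.sum(
                y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p)
            )
    best = int(np.argmin(deviance))
    lam = float(lambda_grid[best])

    path_rows = []
    for lam_i in lambda_grid:
        clf_i = fit_at(lam_i, Z, y)
        path_rows.append(
            {
                "lambda": float(lam_i),
                "n_nonzero": int(np.sum(clf_i.coef_[0] != 0.0)),
                **{f"coef_{nm}": float(c) for nm, c in zip(names, clf_i.coef_[0])},
            }
        )
    path = pd.DataFrame(path_rows)

    clf = fit_at(lam, Z, y)
    beta_std = clf.coef_[0]
    beta = beta_std / sd
    intercept = float(clf.intercept_[0] - np.sum(beta_std * mu / sd))
    return LassoModel(
        feature_names=names,
        coefficients=beta,
        intercept=intercept,
        lambda_=lam,
        standardization={nm: (float(m), float(s)) for nm, m, s in zip(names, mu, sd)},
        dropped_features=dropped,
        lambda_path=path,
    )


def _as_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "biuf":
        y = arr.astype(int)
        if not set(np.unique(y)) <= {0, 1}:
            raise StatsError("numeric labels must be 0/1")
        return y
    mapping = {CAN_FORM: 1, CANNOT_FORM: 0}
    try:
        return np.array([mapping[str(v)] for v in arr])
    except KeyError as exc:
        raise StatsError(f"unknown class label {exc}") from exc


def predict(
    model: LassoModel | ThresholdRule, features: pd.DataFrame
) -> pd.Series:
    """Apply a fitted classifier to a feature table.

    Returns per-sample probabilities of ``can_form`` for a LassoModel, or
    hard class labels for a ThresholdRule.
    """
    if isinstance(model, ThresholdRule):
        if model.feature not in features.columns:
            raise StatsError(f"feature column {model.feature!r} missing")
        values = features[model.feature].to_numpy(dtype=float)
        return pd.Series(
            _apply_threshold(values, model), index=features.index, name="class"
        )
    missing = [n for n in model.feature_names if n not in features.columns]
    if missing:
        raise StatsError(f"feature columns missing: {missing}")
    X = features[model.feature_names].to_numpy(dtype=float)
    eta = X @ model.coefficients + model.intercept
    prob = 1.0 / (1.0 + np.exp(-eta))
    return pd.Series(prob, index=features.index, name="p_can_form")


def load_measurements(path: str | Path, predictor: str | None = None) -> pd.DataFrame:
    """Load a fingerprint/measurement CSV (deposited-table-compatible layout).

    Expected columns: target_id, predictor, label, rmsd_vs_1EMA,
    rmsd_vs_2AWJ, rmsd_vs_1H4U, tight_turn, HD1..HD11. Optionally filters
    to one predictor (AF2 | RF | crystal | synthetic).
    """
    frame = pd.read_csv(path)
    required = {"target_id", "label", "rmsd_vs_1EMA"}
    missing = required - set(frame.columns)
    if missing:
        raise StatsError(f"measurement table {path} lacks columns {sorted(missing)}")
    if predictor is not None:
        frame = frame[frame["predictor"] == predictor].reset_index(drop=True)
        if frame.empty:
            raise StatsError(f"no rows with predictor {predictor!r} in {path}")
    return frame
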