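"""Alignment-based prediction of Molecular Replacement success (AmIgoMR).

From a target-template profile alignment ten candidate predictors are
extracted: global alignment score, number of aligned columns, sequence
identity, fraction of unaligned residues, target length, and five
cumulative counts of alignment columns by per-column score (at least 1.5,
0.5, -0.5, -1.5, and below -1.5).  A logistic regression on the binary
"MR solved" outcome is fitted in backward-elimination mode (drop the least
significant variable while any exceeds alpha), validated by leave-one-out
cross-validation, and calibrated by ROC analysis: AUC via the
Mann-Whitney statistic and an operating threshold at the ROC point
closest to the top-left corner.  Correlated AUCs are compared with the
Hanley-McNeil z-test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

#: The ten candidate features, in canonical order.
FEATURE_NAMES = (
    "global_score", "aligned_columns", "seq_identity", "gap_fraction",
    "target_length", "ge_1_5", "ge_0_5", "ge_m0_5", "ge_m1_5", "below_m1_5",
)

#: Inclusive per-column score thresholds for the cumulative counts.
COLUMN_SCORE_THRESHOLDS = (1.5, 0.5, -0.5, -1.5)

Z_CRIT_005 = stats.norm.ppf(0.975)


class SingleClassError(ValueError):
    """Raised when labels contain only one class."""


@dataclass
class ProfileAlignmentRecord:
    """A target-template profile alignment with per-column scores."""

    target_id: str
    template_id: str
    target_length: int
    seq_identity: float
    gap_fraction: float
    global_score: float
    column_scores: list[float]

    def __post_init__(self) -> None:
        # percent-style identities are normalized to fractions
        if self.seq_identity > 1.0:
            self.seq_identity /= 100.0
        if not 0 <= self.seq_identity <= 1 or not 0 <= self.gap_fraction <= 1:
            raise ValueError("seq_identity and gap_fraction must be fractions")

    @property
    def aligned_columns(self) -> int:
        return len(self.column_scores)


@dataclass
class FeatureVector:
    ge_1_5: int
    ge_0_5: int
    ge_m0_5: int
    ge_m1_5: int
    below_m1_5: int
    seq_identity: float
    gap_fraction: float
    global_score: float
    aligned_columns: int
    target_length: int

    def __post_init__(self) -> None:
        if not self.ge_1_5 <= self.ge_0_5 <= self.ge_m0_5 <= self.ge_m1_5:
            raise ValueError("cumulative column counts must be nondecreasing")
        if self.ge_m1_5 + self.below_m1_5 != self.aligned_columns:
            raise ValueError("ge_m1_5 + below_m1_5 must equal aligned_columns")

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def extract_features(rec: ProfileAlignmentRecord) -> FeatureVector:
    """Cumulative column-score counts plus the copied global descriptors."""
    scores = np.asarray(rec.column_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty column_scores")
    counts = [int(np.sum(scores >= t)) for t in COLUMN_SCORE_THRESHOLDS]
    below = int(np.sum(scores < COLUMN_SCORE_THRESHOLDS[-1]))
    return FeatureVector(*counts, below, rec.seq_identity, rec.gap_fraction,
                         rec.global_score, rec.aligned_columns,
                         rec.target_length)


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame([v.to_dict() for v in vectors], columns=FEATURE_NAMES)


# --------------------------------------------------------------------------
# Logistic regression with backward elimination
# --------------------------------------------------------------------------

@dataclass
class LogisticModel:
    retained_features: list[str]
    coefficients: dict[str, float]
    intercept: float
    alpha: float = 0.05
    separation_warning: bool = False

    def __post_init__(self) -> None:
        missing = [f for f in self.retained_features
                   if f not in self.coefficients]
        if missing:
            raise ValueError(f"no coefficient for features {missing}")

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.intercept, dtype=float)
        for name in self.retained_features:
            eta += self.coefficients[name] * X[name].to_numpy(dtype=float)
        return eta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(X))

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = {
            "retained_features": self.retained_features,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "alpha": self.alpha,
            "separation_warning": self.separation_warning,
        }
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticModel":
        d = json.loads(Path(path).read_text())
        return cls(d["retained_features"], d["coefficients"], d["intercept"],
                   d.get("alpha", 0.05), d.get("separation_warning", False))


def _check_labels(y: np.ndarray) -> None:
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError("labels contain a single class")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")


def _fit_logit(X: np.ndarray, y: np.ndarray) -> tuple:
    """Fit a logit; returns (result, separation_flag).

    Falls back from Newton to L-BFGS when the Hessian is singular (exactly
    collinear designs keep an identified likelihood even though individual
    coefficients are not identified) and flags (quasi-)separated fits.
    """
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError, PerfectSeparationWarning)

    model = sm.Logit(y, X)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                res = model.fit(disp=0)
            separated = any(issubclass(w.category, PerfectSeparationWarning)
                            for w in caught)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            res = model.fit(method="lbfgs", maxiter=1000, disp=0)
            separated = True
    if not np.all(np.isfinite(res.params)):
        res = model.fit(method="lbfgs", maxiter=1000, disp=0)
        separated = True
    return res, separated


def _design(X: pd.DataFrame, features: list[str]) -> np.ndarray:
    return sm.add_constant(X[list(features)].to_numpy(dtype=float),
                           has_constant="add")


def fit_backward(X: pd.DataFrame, y, alpha: float = 0.05,
                 criterion: str = "lrt",
                 features: tuple[str, ...] = FEATURE_NAMES) -> LogisticModel:
    """Backward-elimination logistic regression on the MR-success labels.

    Starting from the saturated model (all candidate features), the least
    significant feature is removed while its p-value exceeds ``alpha``;
    the fit is repeated until every retained feature is significant.
    Significance is judged by a likelihood-ratio test per feature
    (``criterion='lrt'``) or by the Wald z-test (``criterion='wald'``).
    """
    y = np.asarray(y, dtype=float)
    _check_labels(y)
    if len(X) < 20:
        raise ValueError("need at least 20 rows to fit")
    if len(X) != len(y):
        raise ValueError("features and labels differ in length")
    if criterion not in ("lrt", "wald"):
        raise ValueError(f"unknown criterion {criterion!r}")
    kept = [f for f in features if f in X.columns]
    if len(kept) < len(features):
        missing = set(features) - set(kept)
        raise ValueError(f"feature columns missing from table: {sorted(missing)}")

    separated_any = False
    while kept:
        res, sep = _fit_logit(_design(X, kept), y)
        separated_any |= sep
        if criterion == "wald":
            pvals = dict(zip(kept, res.pvalues[1:]))
            pvals = {k: (1.0 if not np.isfinite(p) else float(p))
                     for k, p in pvals.items()}
        else:
            pvals = {}
            for f in kept:
                reduced = [g for g in kept if g != f]
                if reduced:
                    res_r, sep_r = _fit_logit(_design(X, reduced), y)
                    separated_any |= sep_r
                    llf_r = res_r.llf
                else:
                    p0 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
                    llf_r = float(np.sum(y * np.log(p0)
                                         + (1 - y) * np.log(1 - p0)))
                lr = max(0.0, 2.0 * (res.llf - llf_r))
                pvals[f] = float(stats.chi2.sf(lr, df=1))
        worst = max(kept, key=lambda f: (pvals[f], f))
        if pvals[worst] > alpha:
            kept.remove(worst)
        else:
            break

    if kept:
        res, sep = _fit_logit(_design(X, kept), y)
        separated_any |= sep
        intercept = float(res.params[0])
        coeffs = {f: float(c) for f, c in zip(kept, res.params[1:])}
    else:  # intercept-only model: nothing was predictive
        p0 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        intercept = float(np.log(p0 / (1 - p0)))
        coeffs = {}
    return LogisticModel(kept, coeffs, intercept, alpha, separated_any)


def loocv_scores(X: pd.DataFrame, y, alpha: float = 0.05,
                 criterion: str = "lrt",
                 refit_elimination: bool = True,
                 features: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
    """Held-out probabilities from leave-one-out cross-validation.

    For each of the n rows, the full procedure — including backward
    elimination when ``refit_elimination`` is true — is refitted on the
    other n-1 rows and the held-out row is scored.  Deterministic; rows
    whose fold fails (e.g. single-class training labels) come back as NaN
    with a warning.
    """
    y = np.asarray(y, dtype=float)
    _check_labels(y)
    n = len(X)
    base = fit_backward(X, y, alpha, criterion, features) \
        if not refit_elimination else None
    out = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xtr, ytr = X.iloc[mask.nonzero()[0]], y[mask]
        try:
            if refit_elimination:
                model = fit_backward(Xtr, ytr, alpha, criterion, features)
            else:
                res, _ = _fit_logit(_design(Xtr, base.retained_features), ytr)
                model = LogisticModel(
                    base.retained_features,
                    {f: float(c) for f, c in
                     zip(base.retained_features, res.params[1:])},
                    float(res.params[0]), alpha)
            out[i] = float(model.predict_proba(X.iloc[[i]])[0])
        except (SingleClassError, ValueError) as exc:
            warnings.warn(f"LOOCV fold {i} failed: {exc}")
        mask[i] = True
    return out


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------

@dataclass
class RocCurve:
    points: list[tuple[float, float, float]]  # (fpr, tpr, threshold)
    auc: float
    optimal_threshold: float = field(default=float("nan"))
    optimal_point: tuple[float, float] = field(default=(float("nan"),) * 2)


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC (Mann-Whitney with half-credit for ties)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    auc = float(roc_auc_score(y, scores))
    curve = RocCurve([(float(f), float(t), float(h))
                      for f, t, h in zip(fpr, tpr, thr)], auc)
    curve.optimal_threshold = optimal_threshold(curve)
    for f, t, h in curve.points:
        if h == curve.optimal_threshold:
            curve.optimal_point = (f, t)
            break
    return curve


def optimal_threshold(curve: RocCurve) -> float:
    """Score threshold at the ROC point nearest (0, 1).

    Ties prefer the higher (more conservative) threshold.  The synthetic
    point at threshold = +inf is excluded: it corresponds to predicting
    nothing positive.
    """
    finite = [(f, t, h) for f, t, h in curve.points if np.isfinite(h)]
    if not finite:
        raise ValueError("degenerate ROC curve")
    best = min(finite,
               key=lambda p: (np.hypot(p[0], 1.0 - p[1]), -p[2]))
    return float(best[2])


def hanley_mcneil_compare(curve_a: RocCurve, curve_b: RocCurve,
                          paired_scores: tuple | None = None
                          ) -> tuple[float, bool]:
    """Hanley-McNeil z-test for the difference between two AUCs.

    ``paired_scores = (scores_a, scores_b, labels)`` enables the 1983
    correlated-curves variant: the correlation term is estimated as the
    average of the Pearson correlations of the two score vectors within
    the positive and within the negative class.  Passing only the label
    vector treats the curves as independent (r = 0), with a warning.
    """
    if paired_scores is None:
        raise ValueError(
            "need (scores_a, scores_b, labels) or a label vector")
    if isinstance(paired_scores, tuple) and len(paired_scores) == 3:
        sa, sb, labels = paired_scores
        sa = np.asarray(sa, dtype=float)
        sb = np.asarray(sb, dtype=float)
    else:
        warnings.warn("no paired scores given; treating curves as independent")
        sa = sb = None
        labels = paired_scores
    y = np.asarray(labels, dtype=int)
    if sa is not None and not (len(sa) == len(sb) == len(y)):
        raise ValueError("paired scores and labels differ in length")
    _check_labels(y)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))

    def hm_se(auc: float) -> float:
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc**2 / (1.0 + auc)
        var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
               + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
        return float(np.sqrt(max(var, 0.0)))

    se_a, se_b = hm_se(curve_a.auc), hm_se(curve_b.auc)

    def safe_corr(x, z):
        if np.std(x) == 0 or np.std(z) == 0:
            return 0.0
        return float(np.corrcoef(x, z)[0, 1])

    if sa is None:
        r = 0.0
    else:
        r = 0.5 * (safe_corr(sa[y == 1], sb[y == 1])
                   + safe_corr(sa[y == 0], sb[y == 0]))
    var_diff = se_a**2 + se_b**2 - 2.0 * r * se_a * se_b
    if var_diff <= 0:
        return 0.0, False
    z = (curve_a.auc - curve_b.auc) / np.sqrt(var_diff)
    return float(z), bool(abs(z) > Z_CRIT_005)


def classification_metrics(predictions, labels
                           ) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from binary predictions."""
    p = np.asarray(predictions, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    if y.all() or not y.any():
        raise SingleClassError("labels contain a single class")
    tp = int(np.sum(p & y))
    tn = int(np.sum(~p & ~y))
    fp = int(np.sum(p & ~y))
    fn = int(np.sum(~p & y))
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    accuracy = (tp + tn) / len(y)
    return sensitivity, specificity, accuracy


# --------------------------------------------------------------------------
# Tabular I/O
# --------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with precomputed feature columns (extra columns kept)."""
    df = pd.read_csv(path, sep="\t")
    missing = [f for f in FEATURE_NAMES if f not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    if (df["seq_identity"] > 1.0).any():
        df = df.copy()
        df["seq_identity"] = df["seq_identity"] / 100.0
    return df


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "solved" not in df.columns:
        raise ValueError(f"{path}: no 'solved' column")
    return df
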