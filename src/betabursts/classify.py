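"""Sensitivity/specificity analysis and the threshold-robustness sweep.

Each summary measure (four burst features, four PSD quantities) is used
as the single predictor of group membership in a logistic regression;
the area under the ROC curve of the fitted scores and the measure's
optimal cut-off (Youden's J by default) quantify how well the measure
separates patients from controls. Because the logistic link is
monotone, the AUC equals the midrank Mann-Whitney statistic of the raw
feature, which is how it is computed here (exact and tie-robust).

The sweep repeats burst detection, the group/session Poisson model with
its Bayes factors, and the per-session burst-rate ROC at every
threshold multiplier of the grid, to show whether the group inference
depends on the particular threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .bursts import default_k_grid, detect_events, summarize_subject
from .datatypes import Envelope
from .stats import fit_rate_model, summaries_to_frame

__all__ = [
    "RocResult",
    "UnivariateLogisticROC",
    "roc_for_feature",
    "roc_suite",
    "threshold_sweep",
    "ROC_FEATURES",
]

# feature columns in the order they are tabulated
ROC_FEATURES = [
    "relative_beta_power",
    "aperiodic_intercept",
    "aperiodic_exponent",
    "beta_peak_power",
    "rate_per_min",
    "median_duration_ms",
    "median_ibi_ms",
    "median_peak_amp",
]


@dataclass
class RocResult:
    feature: str
    session: int
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    optimal_threshold: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def _midrank_auc(values: np.ndarray, positive: np.ndarray) -> float:
    """AUC as the normalised midrank Mann-Whitney U statistic.

    Probability that a randomly drawn positive-class value outranks a
    randomly drawn negative-class value, ties counted half.
    """
    ranks = rankdata(values)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


class UnivariateLogisticROC(BaseEstimator):
    """Logistic classifier on one feature with ROC/AUC summaries.

    ``fit(x, y)`` fits ``P(positive) = logistic(a + b x)`` and stores
    ``auc_`` (of the fitted scores; equal to the midrank Mann-Whitney
    AUC of x, orientation following the sign of b), the ROC curve
    (``fpr_``, ``tpr_``, ``thresholds_`` on the feature scale) and
    ``optimal_threshold_``.

    Parameters
    ----------
    criterion : {'youden', 'accuracy'}
        Cut-off selection rule; ties resolved toward the lower feature
        value.
    positive_label
        The label treated as the positive class (default 'patient').
    """

    def __init__(self, criterion: str = "youden", positive_label="patient"):
        self.criterion = criterion
        self.positive_label = positive_label

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y)
        pos = y == self.positive_label
        if pos.all() or (~pos).all():
            raise ValueError("both classes must be present")
        if np.unique(y).size > 2:
            raise ValueError("binary labels required")

        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(pos.astype(float), sm.add_constant(x)).fit(disp=0)
                slope = float(res.params[1])
            except Exception:  # perfect separation: direction from means
                slope = float(np.sign(x[pos].mean() - x[~pos].mean()) or 1.0)
        self.coef_ = slope

        score = x if slope >= 0 else -x
        self.auc_ = _midrank_auc(score, pos)

        # ROC curve over feature-valued thresholds: candidate cut-offs are
        # midpoints between consecutive unique values, so the reported
        # optimum falls between the classes rather than on a data point
        uniq = np.unique(x)
        cand = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else uniq
        tpr, fpr = [], []
        n_pos, n_neg = pos.sum(), (~pos).sum()
        for c in cand:
            pred = x >= c if slope >= 0 else x <= c
            tpr.append((pred & pos).sum() / n_pos)
            fpr.append((pred & ~pos).sum() / n_neg)
        tpr, fpr = np.array(tpr), np.array(fpr)
        if self.criterion == "youden":
            j = tpr - fpr
        elif self.criterion == "accuracy":
            j = (tpr * n_pos + (1 - fpr) * n_neg) / (n_pos + n_neg)
        else:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        best = np.flatnonzero(j == j.max())
        self.optimal_threshold_ = float(cand[best].min())
        # sort curve to be monotone in fpr for plotting
        srt = np.lexsort((tpr, fpr))
        self.fpr_ = np.concatenate([[0.0], fpr[srt], [1.0]])
        self.tpr_ = np.concatenate([[0.0], tpr[srt], [1.0]])
        self.thresholds_ = cand
        return self


def roc_for_feature(
    values,
    labels,
    feature: str = "",
    session: int = 1,
    criterion: str = "youden",
) -> RocResult:
    """Univariate logistic ROC for one feature (one value per subject)."""
    clf = UnivariateLogisticROC(criterion=criterion).fit(values, labels)
    return RocResult(
        feature=feature,
        session=session,
        auc=clf.auc_,
        fpr=clf.fpr_,
        tpr=clf.tpr_,
        thresholds=clf.thresholds_,
        optimal_threshold=clf.optimal_threshold_,
    )


def roc_suite(
    feature_table: pd.DataFrame,
    features: list[str] | None = None,
    criterion: str = "youden",
) -> list[RocResult]:
    """One ROC per feature and session.

    ``feature_table`` needs columns subject, group, session plus the
    feature columns; rows with a missing value for a feature are dropped
    from that feature's ROC. Features absent from the table are skipped
    with a warning.
    """
    if features is None:
        features = ROC_FEATURES
    results: list[RocResult] = []
    for feature in features:
        if feature not in feature_table.columns:
            warnings.warn(f"feature column {feature!r} missing; skipped", RuntimeWarning)
            continue
        for session in sorted(feature_table["session"].unique()):
            sub = feature_table[feature_table["session"] == session]
            sub = sub[np.isfinite(sub[feature].astype(float))]
            if sub.empty or sub["group"].nunique() < 2:
                warnings.warn(
                    f"feature {feature!r} session {session}: insufficient data; skipped",
                    RuntimeWarning,
                )
                continue
            results.append(
                roc_for_feature(
                    sub[feature].to_numpy(float),
                    sub["group"].to_numpy(),
                    feature=feature,
                    session=int(session),
                    criterion=criterion,
                )
            )
    return results


def roc_table(results: list[RocResult]) -> pd.DataFrame:
    """Tabular view: feature, session, auc, optimal_threshold."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "session": r.session,
                "auc": r.auc,
                "optimal_threshold": r.optimal_threshold,
            }
            for r in results
        ]
    )


def threshold_sweep(
    envelopes: dict[tuple[str, int], Envelope],
    manifest: pd.DataFrame,
    k_grid: np.ndarray | None = None,
    center: str = "median",
    threshold_mode: str = "scaled",
) -> pd.DataFrame:
    """Group inference and burst-rate ROC across the threshold grid.

    For each multiplier k: re-detect bursts in every record, fit the
    Group + Session mixed Poisson model with its BIC Bayes factors, and
    compute the per-session burst-rate AUC. Returns one row per k.
    """
    if k_grid is None:
        k_grid = default_k_grid()
    rows = []
    for k in np.asarray(k_grid, dtype=float):
        summaries = []
        for _, rec in manifest.iterrows():
            key = (rec["subject"], int(rec["session"]))
            env = envelopes[key]
            events = detect_events(env, k, center=center, threshold_mode=threshold_mode)
            summaries.append(
                summarize_subject(
                    events, env, subject=key[0], group=rec["group"], session=key[1]
                )
            )
        sdf = summaries_to_frame(summaries)
        result = fit_rate_model(sdf)
        row = {
            "k": float(k),
            "bf_group": result.bf_group,
            "bf_session": result.bf_session,
            "bf_interaction": result.bf_interaction,
        }
        for group in sorted(sdf["group"].unique()):
            row[f"rate_mean_{group}"] = sdf.loc[sdf["group"] == group, "rate_per_min"].mean()
        for session in sorted(sdf["session"].unique()):
            sub = sdf[sdf["session"] == session]
            try:
                row[f"auc_session{session}"] = roc_for_feature(
                    sub["rate_per_min"].to_numpy(), sub["group"].to_numpy()
                ).auc
            except ValueError:
                row[f"auc_session{session}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
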