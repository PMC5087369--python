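"""Fisher linear discriminant combination of AQR/VLP features.

The feature table is a pandas DataFrame with a ``label`` column holding
"normal" or "vt" and any number of numeric feature columns (AQR grid
cells, the time-domain late-potential indices, or both). Fisher's linear
discriminant projects each subject onto

    w  proportional to  Sw^{-1} (mu_vt - mu_normal),

where Sw is the pooled within-class covariance. VT is the positive class
throughout: sensitivity counts VT subjects detected, specificity counts
normal subjects cleared. With many correlated AQR features and few
subjects the pooled covariance is singular; a pseudo-inverse (relative
tolerance 1e-10) is used and the collinear columns are named in a warning.

Performance is summarized by specificity, sensitivity, total prediction
accuracy (TPA) at a score cutoff, and by the area under the empirical ROC
curve (AUC), computed as the normalized Mann-Whitney statistic with ties
credited one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "LDAResult",
    "PerformanceReport",
    "fisher_lda",
    "classify_metrics",
    "roc_auc",
    "best_threshold",
    "roc_curve_points",
    "evaluate_features",
]

POSITIVE = "vt"
NEGATIVE = "normal"


def _split_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    known = np.isin(lab, [POSITIVE, NEGATIVE])
    if not known.all():
        raise InvalidInputError(
            f"labels must be '{POSITIVE}' or '{NEGATIVE}'; got {set(lab[~known])}"
        )
    if not (np.any(lab == POSITIVE) and np.any(lab == NEGATIVE)):
        raise InvalidInputError("both classes must be present")
    return lab


def feature_columns(table: pd.DataFrame) -> list:
    """All numeric columns of a feature table except the identifiers."""
    return [
        c
        for c in table.columns
        if c not in ("subject_id", "label")
        and np.issubdtype(table[c].dtype, np.number)
    ]


@dataclass(frozen=True)
class LDAResult:
    """Discriminant direction and the per-subject projection scores."""

    weights: pd.Series  # indexed by feature name
    scores: np.ndarray
    labels: np.ndarray


def fisher_lda(table: pd.DataFrame, feature_cols: list | None = None) -> LDAResult:
    """Fisher's linear discriminant on a labelled feature table.

    Requires at least two subjects per class and finite features. The
    weight vector is pinv(Sw) (mu_vt - mu_normal), oriented so the VT class
    has the higher mean score. Collinear feature columns (those not adding
    rank to the pooled scatter) trigger a warning naming them but do not
    abort: the pseudo-inverse yields the minimum-norm discriminant.
    """
    cols = feature_cols if feature_cols is not None else feature_columns(table)
    if not cols:
        raise InvalidInputError("no feature columns found")
    labels = _split_labels(table["label"].to_numpy())
    X = table[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("features must be finite (drop missing rows first)")
    pos, neg = X[labels == POSITIVE], X[labels == NEGATIVE]
    if len(pos) < 2 or len(neg) < 2:
        raise InvalidInputError("need at least two subjects per class to fit")
    mu_diff = pos.mean(axis=0) - neg.mean(axis=0)
    centered = np.vstack([pos - pos.mean(axis=0), neg - neg.mean(axis=0)])
    sw = centered.T @ centered / (len(X) - 2)
    rank = np.linalg.matrix_rank(sw, tol=None)
    if rank < len(cols):
        # name columns beyond the numerical rank via a pivoted QR on the
        # centered feature matrix
        from scipy.linalg import qr

        _, _, piv = qr(centered, mode="economic", pivoting=True)
        collinear = sorted(np.asarray(cols, dtype=object)[piv[rank:]].tolist())
        warnings.warn(
            f"pooled covariance is singular (rank {rank} < {len(cols)} features); "
            f"using a pseudo-inverse; collinear columns include: {collinear[:10]}",
            stacklevel=2,
        )
    w = np.linalg.pinv(sw, rcond=1e-10) @ mu_diff
    scores = X @ w
    if scores[labels == POSITIVE].mean() < scores[labels == NEGATIVE].mean():
        w, scores = -w, -scores  # enforce VT-high orientation
    return LDAResult(weights=pd.Series(w, index=cols), scores=scores, labels=labels)


@dataclass(frozen=True)
class PerformanceReport:
    """Specificity / sensitivity / TPA (and optionally AUC), in percent."""

    sp: float
    se: float
    tpa: float
    threshold: float
    confusion: tuple  # (TP, FN, TN, FP)
    auc: float | None = None

    def to_dict(self) -> dict:
        tp, fn, tn, fp = self.confusion
        return {
            "sp_pct": self.sp,
            "se_pct": self.se,
            "tpa_pct": self.tpa,
            "auc_pct": self.auc,
            "threshold": self.threshold,
            "confusion": {"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        }


def classify_metrics(scores, labels, threshold: float) -> PerformanceReport:
    """Confusion counts and SP/SE/TPA predicting VT when score >= threshold."""
    lab = _split_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.size != lab.size:
        raise InvalidInputError("scores and labels must be aligned")
    pred_pos = s >= threshold
    pos, neg = lab == POSITIVE, lab == NEGATIVE
    tp = int(np.sum(pred_pos & pos))
    fn = int(np.sum(~pred_pos & pos))
    tn = int(np.sum(~pred_pos & neg))
    fp = int(np.sum(pred_pos & neg))
    return PerformanceReport(
        sp=100.0 * tn / (tn + fp),
        se=100.0 * tp / (tp + fn),
        tpa=100.0 * (tp + tn) / s.size,
        threshold=float(threshold),
        confusion=(tp, fn, tn, fp),
    )


def roc_auc(scores, labels) -> float:
    """Area under the empirical ROC curve, in percent.

    Computed as the normalized Mann-Whitney U statistic (probability that a
    random VT score exceeds a random normal score, ties counted 1/2), which
    equals the trapezoidal area under the empirical ROC curve.
    """
    from scipy.stats import rankdata

    lab = _split_labels(labels)
    s = np.asarray(scores, dtype=float)
    pos = lab == POSITIVE
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return 100.0 * float(u) / (n_pos * n_neg)


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve as (threshold, fpr, tpr) rows, high cutoff first."""
    lab = _split_labels(labels)
    s = np.asarray(scores, dtype=float)
    pos = lab == POSITIVE
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for t in np.unique(s)[::-1]:
        pred = s >= t
        rows.append(
            {
                "threshold": float(t),
                "fpr": float(np.sum(pred & ~pos) / n_neg),
                "tpr": float(np.sum(pred & pos) / n_pos),
            }
        )
    return pd.DataFrame(rows)


def best_threshold(scores, labels) -> float:
    """Score cutoff maximizing TPA; ties resolve toward higher specificity.

    Candidates are the midpoints between adjacent sorted unique scores plus
    one cutoff below every score (predict all VT) and one above (predict
    all normal). Among equal-TPA candidates the higher-specificity one
    wins; among those, the larger cutoff, for determinism.
    """
    lab = _split_labels(labels)
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    cands = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best = None
    for t in cands:
        r = classify_metrics(s, lab, t)
        key = (r.tpa, r.sp, t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


def evaluate_features(
    table: pd.DataFrame, feature_cols: list | None = None
) -> PerformanceReport:
    """LDA combination -> TPA-optimal cutoff -> full performance report."""
    lda = fisher_lda(table, feature_cols)
    t = best_threshold(lda.scores, lda.labels)
    rep = classify_metrics(lda.scores, lda.labels, t)
    return PerformanceReport(
        sp=rep.sp,
        se=rep.se,
        tpa=rep.tpa,
        threshold=rep.threshold,
        confusion=rep.confusion,
        auc=roc_auc(lda.scores, lda.labels),
    )
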