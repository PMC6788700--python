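"""From thresholds to flags, and from flags to classifiers.

Each significant threshold becomes a binary *flag*: an observation raises
the flag when its value lies beyond the cut on the flagged side (strictly
``x < cut`` below the median, ``x > cut`` above). A missing value never
raises a flag — an unobserved measurement cannot evidence an extreme —
which is what makes flag-based prediction usable on incomplete records
without imputation.

Two classifiers are built on the flags:

* **N-UFA** collapses each observation to the pair (number of high-risk
  flags, number of low-risk flags) and separates the classes with a
  linear boundary in that plane — by default a Fisher linear
  discriminant, optionally an exhaustive minimiser of training
  misclassifications.
* **RF-UFA** (or any other downstream model) consumes the full binary
  flag matrix as dummy features; this module only exports the matrix,
  the ensemble itself is an ordinary scikit-learn estimator.

Flags can also be combined conjunctively to stratify the data and report
the relative risk of the outcome inside the stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ThresholdResult, ThresholdSet
from .dataset import Dataset

__all__ = [
    "LinearBoundary",
    "StratumReport",
    "apply_flags",
    "count_flags",
    "fit_nufa",
    "classify_nufa",
    "flag_feature_matrix",
    "stratify_by_flags",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinearBoundary:
    """Linear decision rule over (high-flag count, low-flag count).

    Score of an observation with counts ``(n_high, n_low)`` is
    ``w_high * n_high + w_low * n_low + intercept``; the positive class
    is predicted when the score is >= 0 (ties go to the positive class).
    The rule is invariant under positive rescaling of all three numbers.
    """

    w_high: float
    w_low: float
    intercept: float

    def score(self, n_high, n_low):
        return (
            self.w_high * np.asarray(n_high, dtype=float)
            + self.w_low * np.asarray(n_low, dtype=float)
            + self.intercept
        )


def _raised(t: ThresholdResult, x: np.ndarray) -> np.ndarray:
    """Indicator that each value lies beyond threshold ``t`` (missing -> 0)."""
    with np.errstate(invalid="ignore"):
        if t.side == "below":
            out = x < t.cut
        else:
            out = x > t.cut
    out &= ~np.isnan(x)
    return out.astype(np.int8)


def apply_flags(thresholds: ThresholdSet, dataset: Dataset) -> pd.DataFrame:
    """Per-observation binary flag indicators, one column per threshold.

    Columns are named by :attr:`ThresholdResult.label`
    (``variable|side|cut``). A threshold whose variable is absent from
    the dataset yields an all-zero column with a warning, so a model
    fitted on richer data can still score a narrower table.
    """
    cols = {}
    for t in thresholds:
        if t.variable not in dataset.X.columns:
            logger.warning(
                "variable %r not in dataset; flag %s set to 0", t.variable, t.label
            )
            cols[t.label] = np.zeros(dataset.n_obs, dtype=np.int8)
            continue
        cols[t.label] = _raised(t, dataset.X[t.variable].to_numpy(dtype=float))
    return pd.DataFrame(cols, index=dataset.ids, dtype=np.int8)


def count_flags(flags: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Collapse a flag matrix to per-observation (n_high, n_low) counts."""
    if list(flags.columns) != thresholds.labels:
        raise ValueError("flag matrix columns do not match the threshold set")
    high = [t.label for t in thresholds if t.direction == "high_risk"]
    low = [t.label for t in thresholds if t.direction == "low_risk"]
    return pd.DataFrame(
        {
            "n_high": flags[high].sum(axis=1) if high else 0,
            "n_low": flags[low].sum(axis=1) if low else 0,
        },
        index=flags.index,
        dtype=np.int64,
    )


def flag_feature_matrix(thresholds: ThresholdSet, dataset: Dataset) -> pd.DataFrame:
    """Binary dummy-feature matrix for downstream classifiers.

    Identical to :func:`apply_flags`; exposed under its own name because
    it is the hand-off surface to external models (e.g. a random
    forest), which should not need to know anything about thresholds.
    """
    return apply_flags(thresholds, dataset)


def _fisher_lda(counts: np.ndarray, labels: np.ndarray) -> LinearBoundary:
    """Closed-form two-class LDA on 2-D integer counts.

    Uses the pooled within-class covariance and class priors from the
    training frequencies. Falls back to a midpoint rule on
    ``n_high - n_low`` when the pooled scatter is singular.
    """
    mu1 = counts[labels == 1].mean(axis=0)
    mu0 = counts[labels == 0].mean(axis=0)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    centered1 = counts[labels == 1] - mu1
    centered0 = counts[labels == 0] - mu0
    pooled = (centered1.T @ centered1 + centered0.T @ centered0) / (n0 + n1 - 2)
    try:
        w = np.linalg.solve(pooled, mu1 - mu0)
    except np.linalg.LinAlgError:
        w = None
    if w is None or not np.all(np.isfinite(w)) or np.allclose(w, 0):
        logger.warning(
            "degenerate within-class scatter; falling back to n_high - n_low rule"
        )
        w = np.array([1.0, -1.0])
        mid = (float(mu1 @ w) + float(mu0 @ w)) / 2.0
        return LinearBoundary(w_high=1.0, w_low=-1.0, intercept=-mid)
    prior = np.log(n1 / n0)
    intercept = -0.5 * float(w @ (mu1 + mu0)) + prior
    return LinearBoundary(
        w_high=float(w[0]), w_low=float(w[1]), intercept=float(intercept)
    )


def _exhaustive_boundary(counts: np.ndarray, labels: np.ndarray) -> LinearBoundary:
    """Exact 0-1-loss minimisation over linear boundaries in the count plane.

    The counts live on a small integer grid, so it is feasible to sweep
    every direction defined by a pair of distinct grid points (plus the
    two axes) and, for each, every split of the projected values. Among
    minimisers, the one maximising the margin between the flanking
    projections is returned. Deterministic.
    """
    pts, inv = np.unique(counts, axis=0, return_inverse=True)
    pos = np.bincount(inv, weights=(labels == 1), minlength=len(pts))
    neg = np.bincount(inv, weights=(labels == 0), minlength=len(pts))
    dirs = {(1.0, 0.0), (0.0, 1.0), (1.0, -1.0), (1.0, 1.0)}
    for a, b in combinations(range(len(pts)), 2):
        d = pts[b] - pts[a]
        # normal to the segment joining the two grid points
        nrm = (float(d[1]), float(-d[0]))
        scale = max(abs(nrm[0]), abs(nrm[1]))
        dirs.add((nrm[0] / scale, nrm[1] / scale))
    best = None  # (errors, -margin, boundary)
    total_pos, total_neg = pos.sum(), neg.sum()
    for wh, wl in sorted(dirs):
        proj = pts @ np.array([wh, wl])
        order = np.argsort(proj, kind="stable")
        sp, spos, sneg = proj[order], pos[order], neg[order]
        cum_pos = np.concatenate(([0.0], np.cumsum(spos)))
        cum_neg = np.concatenate(([0.0], np.cumsum(sneg)))
        # split k: points with proj >= cutoff are positive
        for k in range(len(sp) + 1):
            errors = cum_pos[k] + (total_neg - cum_neg[k])
            if k == 0:
                cutoff, margin = sp[0] - 1.0, 1.0
            elif k == len(sp):
                cutoff, margin = sp[-1] + 1.0, 1.0
            else:
                cutoff = (sp[k - 1] + sp[k]) / 2.0
                margin = sp[k] - sp[k - 1]
            for sign in (1.0, -1.0):
                err = errors if sign == 1.0 else (total_pos + total_neg - errors)
                cand = (err, -margin, LinearBoundary(sign * wh, sign * wl, -sign * cutoff))
                if best is None or cand[:2] < best[:2]:
                    best = cand
    assert best is not None
    return best[2]


def fit_nufa(
    train_counts: pd.DataFrame | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    method: str = "lda",
) -> LinearBoundary:
    """Fit the N-UFA linear boundary on training flag counts.

    Parameters
    ----------
    train_counts : DataFrame with columns (n_high, n_low) or (n, 2) array.
    labels : binary class labels, both classes required.
    method : 'lda' (Fisher discriminant, default) or 'exhaustive'
        (exact minimisation of training misclassifications).
    """
    if isinstance(train_counts, pd.DataFrame):
        counts = train_counts[["n_high", "n_low"]].to_numpy(dtype=float)
    else:
        counts = np.asarray(train_counts, dtype=float)
    labels = np.asarray(labels)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("counts must be n x 2: (n_high, n_low)")
    if counts.shape[0] != labels.shape[0]:
        raise ValueError("counts and labels length mismatch")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("training labels must contain both classes 0 and 1")
    if method == "lda":
        return _fisher_lda(counts, labels)
    if method == "exhaustive":
        return _exhaustive_boundary(counts, labels)
    raise ValueError(f"unknown method {method!r}")


def classify_nufa(
    boundary: LinearBoundary, counts: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict classes and return (labels, scores).

    The score is the signed distance proxy ``w . counts + intercept``;
    it ranks observations for AUROC. Score exactly 0 is assigned to the
    positive class.
    """
    if isinstance(counts, pd.DataFrame):
        arr = counts[["n_high", "n_low"]].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(counts, dtype=float))
    scores = boundary.score(arr[:, 0], arr[:, 1])
    return (scores >= 0).astype(np.int8), scores


@dataclass(frozen=True)
class StratumReport:
    """Outcome enrichment of the observations satisfying a flag conjunction."""

    n: int
    outcome_rate: Optional[float]
    overall_rate: float
    relative_risk: Optional[float]


def stratify_by_flags(
    dataset: Dataset, conditions: Iterable[ThresholdResult]
) -> StratumReport:
    """Support, outcome rate and relative risk of a conjunction of flags.

    ``conditions`` lists thresholds that must all be violated (all flags
    raised). An empty conjunction returns the overall rate with relative
    risk 1. An empty stratum has undefined rate and relative risk
    (reported as None).
    """
    y = dataset.y.to_numpy(dtype=float)
    overall = float(y.mean())
    mask = np.ones(dataset.n_obs, dtype=bool)
    for t in conditions:
        x = dataset.X[t.variable].to_numpy(dtype=float)
        mask &= _raised(t, x).astype(bool)
    n = int(mask.sum())
    if n == 0:
        return StratumReport(n=0, outcome_rate=None, overall_rate=overall,
                             relative_risk=None)
    rate = float(y[mask].mean())
    rr = rate / overall if overall > 0 else None
    return StratumReport(n=n, outcome_rate=rate, overall_rate=overall,
                         relative_risk=rr)
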