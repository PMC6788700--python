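"""Univariate threshold detection.

For each continuous variable the algorithm searches, separately below and
above the median, for the cutpoint whose tail outcome rate differs most —
by a two-sample binomial-proportion Z statistic with pooled variance —
from the baseline outcome rate inside the variable's interquartile range
(IQR). A cut is kept only if ``|Z|`` reaches a critical value (default
2.576, a two-sided p-value of 0.01), yielding at most two thresholds per
variable: one below and one above the median.

The Z statistic trades purity against support. For a candidate cut ``c``
on the below side, with tail group ``{x < c}`` of size ``n_out`` and
outcome rate ``p_out``, and IQR baseline of size ``n_iqr`` and rate
``p_iqr``::

    p_wa = (p_iqr * n_iqr + p_out * n_out) / (n_iqr + n_out)
    Z    = (p_out - p_iqr) / sqrt(p_wa * (1 - p_wa) * (1/n_iqr + 1/n_out))

Candidate cuts are the interior breakpoints of ``n_segments`` equal-length
segments between the median and the side's extremum, after trimming the
``min_support_excluded`` most extreme values so that every candidate's
tail retains a minimum level of support.

Missing values of a variable are simply excluded from that variable's
threshold computation; no imputation is ever performed here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .dataset import Dataset, DataError

__all__ = [
    "UfaConfig",
    "BaselineStats",
    "ThresholdResult",
    "ThresholdSet",
    "DegenerateVariableError",
    "compute_baseline",
    "generate_candidates",
    "z_statistic",
    "find_optimal_threshold",
    "detect_thresholds",
]

logger = logging.getLogger(__name__)

Side = Literal["below", "above"]
SIDES: tuple[Side, Side] = ("below", "above")


class DegenerateVariableError(ValueError):
    """A variable cannot support threshold analysis (e.g. all missing)."""


@dataclass(frozen=True)
class UfaConfig:
    """Tuning knobs of the threshold search.

    Parameters
    ----------
    n_segments : int
        Number of equal-length segments between the median and each
        (trimmed) extremum; candidates are the interior breakpoints, so
        there are at most ``n_segments - 1`` per side.
    min_support_excluded : int
        How many of the most extreme values to trim before building the
        grid. Every candidate's tail then contains at least
        ``min_support_excluded + 1`` observations: tails thinner than
        that carry too little support to be of interest.
    critical_value : float
        Two-sided significance cutoff on ``|Z|`` (2.576 <-> p = 0.01).
    sides : tuple of {'below', 'above'}
        Which sides of the median to search.
    bonferroni : bool
        If True, tighten the critical value to hold the same family-wise
        level across every Z evaluation of a detection run. Off by
        default: multiplicity is normally addressed by validating the
        thresholds on unseen data rather than by correction.
    percentile_method : str
        Quantile convention for the median and the IQR bounds; any method
        accepted by :func:`numpy.percentile` (default ``'linear'``,
        i.e. type-7 interpolation).
    """

    n_segments: int = 50
    min_support_excluded: int = 5
    critical_value: float = 2.576
    sides: tuple[Side, ...] = SIDES
    bonferroni: bool = False
    percentile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")
        if self.min_support_excluded < 0:
            raise ValueError("min_support_excluded must be >= 0")
        if not self.critical_value > 0:
            raise ValueError("critical_value must be positive")
        bad = set(self.sides) - set(SIDES)
        if bad or not self.sides:
            raise ValueError(f"sides must be a nonempty subset of {SIDES}")


@dataclass(frozen=True)
class BaselineStats:
    """IQR comparison group for one variable.

    ``p25``/``p75`` bound the interquartile range (membership inclusive);
    ``n_iqr`` observations fall inside it and ``p_iqr`` is their outcome
    rate.
    """

    p25: float
    p75: float
    n_iqr: int
    p_iqr: float


@dataclass(frozen=True)
class ThresholdResult:
    """One detected cutpoint for one variable and side.

    ``direction`` is ``'high_risk'`` when the tail beyond the cut is
    enriched for the outcome (``p_out > p_iqr``, i.e. ``z > 0``) and
    ``'low_risk'`` when depleted. ``significant`` records whether ``|z|``
    reached the configured critical value.
    """

    variable: str
    cut: float
    side: Side
    direction: Literal["high_risk", "low_risk"]
    z: float
    n_out: int
    p_out: float
    baseline: BaselineStats
    significant: bool

    @property
    def label(self) -> str:
        """Stable identifier used as a flag/column name."""
        return f"{self.variable}|{self.side}|{self.cut:.10g}"

    def rule_text(self, outcome: str = "Y") -> str:
        where = "below" if self.side == "below" else "above"
        sense = "higher" if self.direction == "high_risk" else "lower"
        return (
            f"For {self.variable}, a value {where} {self.cut:.4g} is "
            f"associated with a significantly {sense} incidence of "
            f"outcome {outcome}"
        )


@dataclass(frozen=True)
class ThresholdSet:
    """All significant thresholds detected on a dataset (<= 2 per variable)."""

    thresholds: tuple[ThresholdResult, ...]
    config: UfaConfig

    def __post_init__(self) -> None:
        seen = set()
        for t in self.thresholds:
            key = (t.variable, t.side)
            if key in seen:
                raise ValueError(f"duplicate threshold for {key}")
            seen.add(key)
            if not t.significant:
                raise ValueError("ThresholdSet members must be significant")

    def __len__(self) -> int:
        return len(self.thresholds)

    def __iter__(self) -> Iterator[ThresholdResult]:
        return iter(self.thresholds)

    def for_variable(self, name: str) -> list[ThresholdResult]:
        return [t for t in self.thresholds if t.variable == name]

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.thresholds]


def _clean(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop pairs where x is missing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(x)
    return x[keep], y[keep]


def compute_baseline(x: np.ndarray, y: np.ndarray, config: UfaConfig | None = None) -> BaselineStats:
    """Compute the IQR comparison group for one variable.

    Pairs with a missing ``x`` are dropped first. Requires at least four
    non-missing values so that the quartiles are meaningful.
    """
    config = config or UfaConfig()
    xs, ys = _clean(x, y)
    if xs.size == 0:
        raise DegenerateVariableError("all values missing")
    if xs.size < 4:
        raise DegenerateVariableError(
            f"need >= 4 non-missing values, got {xs.size}"
        )
    p25, p75 = np.percentile(xs, [25, 75], method=config.percentile_method)
    inside = (xs >= p25) & (xs <= p75)
    n_iqr = int(inside.sum())
    if n_iqr == 0:
        raise DegenerateVariableError("empty interquartile range")
    p_iqr = float(ys[inside].sum() / n_iqr)
    return BaselineStats(p25=float(p25), p75=float(p75), n_iqr=n_iqr, p_iqr=p_iqr)


def generate_candidates(
    x: np.ndarray, side: Side, config: UfaConfig | None = None
) -> np.ndarray:
    """Candidate cutpoints between the median and one (trimmed) extremum.

    The ``min_support_excluded`` most extreme values on the requested side
    are trimmed, the interval between the remaining extremum and the
    median is divided into ``n_segments`` equal-length segments, and the
    interior breakpoints are returned (strictly between the trimmed
    extremum and the median). An empty array means no admissible cut on
    that side.
    """
    config = config or UfaConfig()
    xs = np.sort(np.asarray(x, dtype=float))
    xs = xs[~np.isnan(xs)]
    k = config.min_support_excluded
    if xs.size <= k:
        return np.empty(0)
    med = np.percentile(xs, 50, method=config.percentile_method)
    if side == "below":
        lo, hi = xs[k], med
    else:
        lo, hi = med, xs[xs.size - 1 - k]
    if not hi > lo:
        return np.empty(0)
    grid = np.linspace(lo, hi, config.n_segments + 1)
    return grid[1:-1]


def z_statistic(p_out: float, n_out: int, p_iqr: float, n_iqr: int) -> float:
    """Two-sample binomial-proportion Z with pooled (weighted-average) variance.

    Returns 0.0 when the pooled rate is 0 or 1: both groups are then
    unanimous and identical, so there is no evidence of separation.
    """
    if n_out < 1 or n_iqr < 1:
        raise ValueError("both group sizes must be >= 1")
    p_wa = (p_iqr * n_iqr + p_out * n_out) / (n_iqr + n_out)
    if p_wa <= 0.0 or p_wa >= 1.0:
        return 0.0
    return (p_out - p_iqr) / math.sqrt(
        p_wa * (1.0 - p_wa) * (1.0 / n_iqr + 1.0 / n_out)
    )


def _scan_side(
    xs: np.ndarray,
    ys: np.ndarray,
    cuts: np.ndarray,
    side: Side,
    baseline: BaselineStats,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised tail counts and Z over all candidates.

    ``xs`` must be sorted ascending with ``ys`` aligned. Tails are strict:
    ``x < cut`` below, ``x > cut`` above, so ties at a cut stay with the
    central mass. Candidates with an empty tail get ``z = NaN``.
    """
    n = xs.size
    cum = np.concatenate(([0.0], np.cumsum(ys)))
    if side == "below":
        idx = np.searchsorted(xs, cuts, side="left")
        n_out = idx
        hits = cum[idx]
    else:
        idx = np.searchsorted(xs, cuts, side="right")
        n_out = n - idx
        hits = cum[n] - cum[idx]
    z = np.full(cuts.shape, np.nan)
    ok = n_out >= 1
    with np.errstate(divide="ignore", invalid="ignore"):
        p_out = np.where(ok, hits / np.maximum(n_out, 1), np.nan)
        p_wa = (baseline.p_iqr * baseline.n_iqr + p_out * n_out) / (
            baseline.n_iqr + n_out
        )
        var = p_wa * (1.0 - p_wa) * (1.0 / baseline.n_iqr + 1.0 / np.maximum(n_out, 1))
        zi = (p_out - baseline.p_iqr) / np.sqrt(var)
    degenerate = ok & ((p_wa <= 0.0) | (p_wa >= 1.0))
    z[ok] = zi[ok]
    z[degenerate] = 0.0
    return n_out, np.where(ok, p_out, np.nan), z


def find_optimal_threshold(
    x: np.ndarray,
    y: np.ndarray,
    side: Side,
    config: UfaConfig | None = None,
    variable: str = "x",
) -> Optional[ThresholdResult]:
    """Best cut on one side of the median, or ``None`` if none exists.

    Evaluates the Z statistic at every candidate cut and returns the one
    maximising ``|Z|``. Ties in ``|Z|`` go to the candidate closest to
    the median, i.e. the one with the largest support. Returns ``None``
    when the candidate grid is empty, no candidate has a nonempty tail,
    or the outcome is constant (Z is then identically zero and can never
    be significant).
    """
    config = config or UfaConfig()
    xs, ys = _clean(x, y)
    baseline = compute_baseline(xs, ys, config)
    if np.all(ys == ys[0]):
        return None
    cuts = generate_candidates(xs, side, config)
    if cuts.size == 0:
        return None
    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], ys[order]
    n_out, p_out, z = _scan_side(xs, ys, cuts, side, baseline)
    valid = ~np.isnan(z)
    if not valid.any():
        return None
    absz = np.where(valid, np.abs(z), -np.inf)
    best = absz.max()
    tied = np.flatnonzero(absz == best)
    # closest to the median: the last candidate below, the first above
    i = tied[-1] if side == "below" else tied[0]
    zi = float(z[i])
    return ThresholdResult(
        variable=variable,
        cut=float(cuts[i]),
        side=side,
        direction="high_risk" if zi > 0 else "low_risk",
        z=zi,
        n_out=int(n_out[i]),
        p_out=float(p_out[i]),
        baseline=baseline,
        significant=abs(zi) >= config.critical_value,
    )


def _count_tests(dataset: Dataset, config: UfaConfig) -> int:
    """Number of Z evaluations a detection run performs (for Bonferroni)."""
    total = 0
    for name in dataset.variables:
        xs = dataset.X[name].to_numpy(dtype=float)
        xs = xs[~np.isnan(xs)]
        if xs.size < 4:
            continue
        for side in config.sides:
            total += generate_candidates(xs, side, config).size
    return total


def detect_thresholds(dataset: Dataset, config: UfaConfig | None = None) -> ThresholdSet:
    """Detect all significant thresholds in a dataset.

    For every variable and configured side, the search runs on the rows
    where that variable is non-missing; an observation missing one
    variable still contributes to every other variable's threshold.
    Variables that cannot be analysed (all missing, or fewer than four
    observed values) are skipped with a warning. The result is
    deterministic for a fixed input.
    """
    config = config or UfaConfig()
    if dataset.continuous_target:
        # group "rates" become group means of y in [0, 1]
        pass
    critical = config.critical_value
    if config.bonferroni:
        m = _count_tests(dataset, config)
        if m > 1:
            alpha = 2.0 * stats.norm.sf(config.critical_value)
            critical = float(stats.norm.isf(alpha / m / 2.0))
    eff = replace(config, critical_value=critical, bonferroni=False)
    found: list[ThresholdResult] = []
    y = dataset.y.to_numpy(dtype=float)
    for name in dataset.variables:
        x = dataset.X[name].to_numpy(dtype=float)
        for side in config.sides:
            try:
                res = find_optimal_threshold(x, y, side, eff, variable=name)
            except DegenerateVariableError as exc:
                logger.warning("skipping variable %r (%s side): %s", name, side, exc)
                break
            if res is not None and res.significant:
                found.append(res)
    return ThresholdSet(thresholds=tuple(found), config=config)
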