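"""Synthetic tabular data with planted univariate thresholds.

The generator emulates the shape of a clinical risk table: continuous
explanatory variables, a binary outcome with a configurable base rate,
and — for chosen variables — a *planted* threshold: beyond a known cut,
on a known side, the outcome probability switches to a known tail rate.
Because the ground truth (cut location, side, direction, effect size) is
recorded, threshold detection, flagging and the classifiers can all be
scored without any external dataset.

Two perturbation operators mirror common robustness protocols:
:func:`inject_missing` blanks a random fraction of variable cells
(missing completely at random, per cell), and :func:`inject_noise`
perturbs a random fraction of cells with zero-mean Gaussian noise whose
variance equals the column's empirical variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset

import logging

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedThresholdSpec",
    "GeneratorConfig",
    "generate",
    "inject_missing",
    "inject_noise",
]

Side = Literal["below", "above"]


@dataclass(frozen=True)
class PlantedThresholdSpec:
    """Ground truth for one planted threshold.

    Exactly one of ``cut_quantile`` (position on the variable's marginal
    distribution, in (0, 1)) or ``cut`` (absolute value) must be given.
    ``tail_rate`` is the outcome probability beyond the cut on ``side``;
    elsewhere the dataset-level base rate applies. A tail rate above the
    base rate plants a high-risk threshold, below it a low-risk one.
    """

    variable: str
    side: Side
    tail_rate: float
    cut_quantile: Optional[float] = None
    cut: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.cut_quantile is None) == (self.cut is None):
            raise ValueError("give exactly one of cut_quantile or cut")
        if self.cut_quantile is not None and not 0 < self.cut_quantile < 1:
            raise ValueError("cut_quantile must be in (0, 1)")
        if not 0 <= self.tail_rate <= 1:
            raise ValueError("tail_rate must be in [0, 1]")
        if self.side not in ("below", "above"):
            raise ValueError("side must be 'below' or 'above'")

    def resolve_cut(self, distribution: str) -> float:
        """Absolute cut value implied by the marginal distribution."""
        if self.cut is not None:
            return float(self.cut)
        if distribution == "uniform":
            return float(self.cut_quantile)
        if distribution == "normal":
            return float(stats.norm.ppf(self.cut_quantile))
        raise ValueError(f"unknown distribution {distribution!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Recipe for one synthetic dataset.

    ``n`` observations are drawn i.i.d.; every variable (planted or pure
    noise) gets the same marginal ``distribution`` (``'uniform'`` on
    [0, 1] or standard ``'normal'``). The outcome of an observation is
    Bernoulli with probability equal to the maximum tail rate over the
    planted tails it occupies, or ``base_rate`` if it occupies none.
    The seed is mandatory: a dataset is reproducible or it is useless
    for testing.
    """

    n: int
    seed: int
    planted: tuple[PlantedThresholdSpec, ...] = ()
    n_noise: int = 0
    base_rate: float = 0.2
    distribution: str = "uniform"
    noise_prefix: str = "noise"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if not 0 <= self.base_rate <= 1:
            raise ValueError("base_rate must be in [0, 1]")
        if self.distribution not in ("uniform", "normal"):
            raise ValueError("distribution must be 'uniform' or 'normal'")
        keys = [(s.variable, s.side) for s in self.planted]
        if len(keys) != len(set(keys)):
            raise ValueError("at most one planted threshold per variable side")


def _draw(rng: np.random.Generator, distribution: str, n: int) -> np.ndarray:
    if distribution == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    return rng.standard_normal(n)


def generate(
    config: GeneratorConfig,
) -> tuple[Dataset, list[PlantedThresholdSpec]]:
    """Draw a dataset and return it with the resolved ground truth.

    The returned specs always carry an absolute ``cut`` (quantiles are
    resolved against the marginal distribution), so recovery can be
    scored directly against them.
    """
    rng = np.random.default_rng(config.seed)
    cols: dict[str, np.ndarray] = {}
    resolved: list[PlantedThresholdSpec] = []
    prob = np.full(config.n, config.base_rate)
    tail_rate = np.full(config.n, -np.inf)  # max over occupied tails
    in_any_tail = np.zeros(config.n, dtype=bool)
    for spec in config.planted:
        # one draw per variable; a variable may carry one tail per side
        if spec.variable in cols:
            x = cols[spec.variable]
        else:
            x = _draw(rng, config.distribution, config.n)
            cols[spec.variable] = x
        cut = spec.resolve_cut(config.distribution)
        lo, hi = x.min(), x.max()
        if not lo < cut < hi:
            raise ValueError(
                f"cut {cut} for {spec.variable!r} outside the sampled support "
                f"[{lo:.4g}, {hi:.4g}]"
            )
        resolved.append(replace(spec, cut_quantile=None, cut=cut))
        tail = x < cut if spec.side == "below" else x > cut
        tail_rate[tail] = np.maximum(tail_rate[tail], spec.tail_rate)
        in_any_tail |= tail
    prob[in_any_tail] = tail_rate[in_any_tail]
    for j in range(config.n_noise):
        cols[f"{config.noise_prefix}{j + 1}"] = _draw(
            rng, config.distribution, config.n
        )
    y = rng.binomial(1, prob)
    X = pd.DataFrame(cols, index=pd.RangeIndex(config.n))
    if X.empty:
        X = pd.DataFrame(index=pd.RangeIndex(config.n))
    return Dataset(X, pd.Series(y, index=X.index)), resolved


def inject_missing(dataset: Dataset, fraction: float, seed: int) -> Dataset:
    """Blank each variable cell independently with probability ``fraction``.

    Missingness is completely at random (MCAR) per cell; the target is
    never masked. Returns a new dataset.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    out = dataset.copy()
    if fraction == 0 or not out.variables:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.X.shape) < fraction
    values = out.X.to_numpy(dtype=float)
    values[mask] = np.nan
    out.X = pd.DataFrame(values, index=out.X.index, columns=out.X.columns)
    return out


def inject_noise(dataset: Dataset, fraction: float, seed: int) -> Dataset:
    """Perturb a random fraction of cells with column-scaled Gaussian noise.

    Each non-missing cell is independently selected with probability
    ``fraction``; selected cells gain a Normal(0, s^2) perturbation where
    s^2 is the column's empirical variance computed on the unperturbed
    data. Constant columns are left untouched. The target is never
    perturbed.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    out = dataset.copy()
    if fraction == 0 or not out.variables:
        return out
    rng = np.random.default_rng(seed)
    values = out.X.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(values, axis=0, ddof=1)
    sd = np.where(np.isfinite(sd), sd, 0.0)
    for name, s in zip(out.X.columns, sd):
        if s == 0.0:
            logger.warning("column %r has zero variance; left unperturbed", name)
    pick = (rng.random(values.shape) < fraction) & ~np.isnan(values)
    noise = rng.standard_normal(values.shape) * sd[np.newaxis, :]
    values = values + np.where(pick, noise, 0.0)
    out.X = pd.DataFrame(values, index=out.X.index, columns=out.X.columns)
    return out
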