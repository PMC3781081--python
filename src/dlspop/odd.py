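"""Nonparametric diagnosis of the order of density dependence (ODD).

How many lagged densities are needed to predict the next census?  For each
candidate order d, a kernel (Nadaraya-Watson) autoregression of the series on
its d most recent lags is scored by leave-one-out cross-validation; the
bandwidth is itself chosen per (series, order) by minimising the same CV
criterion.  Per-plot scores are standardised by setting each plot's minimum
across orders to zero, then averaged across plots: a lower average index
indicates stronger support for that order.

Leave-one-out (rather than block) CV is used because the census series are
only 17-18 points long.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["OddProfile", "odd_cv_score", "odd_profile"]

#: default bandwidth grid (proportional-cover units)
DEFAULT_BANDWIDTHS = np.geomspace(0.02, 1.0, 12)


def _embed(years: np.ndarray, values: np.ndarray, order: int):
    """Lag-embed a (possibly gapped) series on its calendar-year index.

    Returns (X, y): lag matrix rows (p_{t-1}, .., p_{t-order}) and targets
    p_t, using only targets whose full lag window is observed.
    """
    index = {int(yr): i for i, yr in enumerate(years)}
    X, y = [], []
    for yr in years:
        yr = int(yr)
        needed = [yr - l for l in range(1, order + 1)]
        if all(n in index for n in needed):
            X.append([values[index[n]] for n in needed])
            y.append(values[index[yr]])
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def _loo_cv(X: np.ndarray, y: np.ndarray, bandwidth: float) -> float:
    """Leave-one-out squared error of a Gaussian-kernel local-mean smoother."""
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    W = np.exp(-d2 / (2.0 * bandwidth ** 2))
    np.fill_diagonal(W, 0.0)
    denom = W.sum(axis=1)
    fallback = np.array([(y.sum() - yi) / (len(y) - 1) for yi in y])
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = np.where(denom > 1e-300, W @ y / np.where(denom > 0, denom, 1.0), fallback)
    return float(np.mean((y - pred) ** 2))


def odd_cv_score(series, order: int, years=None, bandwidths=None) -> float:
    """Cross-validation error of a kernel autoregression of given order.

    ``series`` is a single plot's proportional-cover values; ``years`` (same
    length) lets gapped series exclude windows spanning a missing census.
    The reported score is the minimum LOO error over the bandwidth grid.
    """
    values = np.asarray(series, dtype=float)
    if years is None:
        years = np.arange(len(values))
    years = np.asarray(years, dtype=int)
    if not 1 <= order <= 5:
        raise ValueError(f"order must be in 1..5, got {order}")
    X, y = _embed(years, values, order)
    if len(y) < 3 or len(values) <= order + 2:
        raise ValueError(
            f"series too short for order {order}: {len(values)} censuses give "
            f"{len(y)} usable targets")
    if bandwidths is None:
        bandwidths = DEFAULT_BANDWIDTHS
    return min(_loo_cv(X, y, h) for h in bandwidths)


@dataclass(frozen=True)
class OddProfile:
    """Cross-validation profile over candidate orders.

    ``raw[p, d-1]`` is plot p's CV error at order d; ``standardized`` sets
    each plot's minimum to zero; ``mean_standardized[d-1]`` averages over
    plots.  The best-supported order minimises the mean standardised score.
    """

    plot_ids: list[str]
    orders: np.ndarray
    raw: np.ndarray
    standardized: np.ndarray
    mean_standardized: np.ndarray

    @property
    def best_order(self) -> int:
        return int(self.orders[np.argmin(self.mean_standardized)])


def odd_profile(plots, max_order: int = 5, bandwidths=None) -> OddProfile:
    """Standardise-then-average CV scores for orders 1..max_order across plots.

    Plots too short for the highest order are skipped with a warning; the
    per-order means are taken over the plots with valid scores.
    """
    orders = np.arange(1, max_order + 1)
    ids, rows = [], []
    for plot in plots:
        try:
            scores = [odd_cv_score(plot.props, d, years=plot.years,
                                   bandwidths=bandwidths) for d in orders]
        except ValueError as exc:
            warnings.warn(f"skipping plot {plot.plot_id}: {exc}", stacklevel=2)
            continue
        ids.append(plot.plot_id)
        rows.append(scores)
    if not rows:
        raise ValueError("no plot is long enough for the requested orders")
    raw = np.asarray(rows)
    standardized = raw - raw.min(axis=1, keepdims=True)
    return OddProfile(plot_ids=ids, orders=orders, raw=raw,
                      standardized=standardized,
                      mean_standardized=standardized.mean(axis=0))
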