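"""Beta-binomial distribution core.

The beta-binomial arises from a binomial whose success probability is itself
beta-distributed.  It is the observation model used throughout this package
for bounded census counts: a plot is scored as ``count`` occupied sample units
out of ``n_trials`` (484 quarter-squares or 100 fixed points), and the beta
mixing density absorbs process variation between censuses.

Two parameterizations are supported:

* shape parameters ``(a, b)`` of the beta component, and
* moments ``(mean, variance)`` of the beta component, linked through the
  overdispersion parameter ``phi = a + b``::

      mu  = a / (a + b)
      var = mu * (1 - mu) / (phi + 1)

All probability mass is computed in log space via log-gamma differences so
that sample sizes of several hundred never overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "BetaBinomialSpec",
    "FeasibilityError",
    "pmf",
    "logpmf",
    "from_moments",
    "from_mean_phi",
    "sample",
    "is_unimodal",
    "is_bimodal",
]

#: relative margin below the beta variance bound mu*(1-mu); variances at or
#: beyond the bound would drive phi -> 0 (a degenerate two-point beta).
FEASIBILITY_MARGIN = 1e-9


class FeasibilityError(ValueError):
    """Requested beta moments lie outside the feasible region."""


@dataclass(frozen=True)
class BetaBinomialSpec:
    """A beta-binomial distribution: beta shapes ``a, b`` and sample size.

    Parameters
    ----------
    a, b
        Positive shape parameters of the mixing beta density.
    n_trials
        Number of binomial trials (sample units scored per census).
    """

    a: float
    b: float
    n_trials: int

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"shape parameters must be positive, got a={self.a}, b={self.b}")
        if not (isinstance(self.n_trials, (int, np.integer)) and self.n_trials >= 1):
            raise ValueError(f"n_trials must be a positive integer, got {self.n_trials!r}")

    @property
    def mean_prop(self) -> float:
        """Mean of the beta component, ``a / (a + b)``, in (0, 1)."""
        return self.a / (self.a + self.b)

    @property
    def phi(self) -> float:
        """Overdispersion parameter ``a + b`` (smaller = more dispersed)."""
        return self.a + self.b

    @property
    def variance(self) -> float:
        """Variance of the beta component, ``mu (1-mu) / (phi + 1)``."""
        mu = self.mean_prop
        return mu * (1.0 - mu) / (self.phi + 1.0)

    @property
    def count_mean(self) -> float:
        """Mean of the count, ``n_trials * mu``."""
        return self.n_trials * self.mean_prop

    @property
    def count_variance(self) -> float:
        """Variance of the count (closed form)."""
        n, mu, phi = self.n_trials, self.mean_prop, self.phi
        return n * mu * (1 - mu) * (phi + n) / (phi + 1)


def _check_counts(count, n_trials):
    k = np.asarray(count)
    if not np.issubdtype(k.dtype, np.integer):
        kk = np.asarray(count, dtype=float)
        if not np.all(kk == np.floor(kk)):
            raise ValueError(f"count must be integer, got {count!r}")
        k = kk.astype(np.int64)
    if np.any(k < 0) or np.any(k > n_trials):
        raise ValueError(f"count out of range [0, {n_trials}]")
    return k


def logpmf(count, spec: BetaBinomialSpec):
    """Log probability mass at ``count`` (scalar or array).

    Computed as ``log C(n, k) + betaln(k+a, n-k+b) - betaln(a, b)`` with the
    binomial coefficient expanded in log-gamma terms.
    """
    k = _check_counts(count, spec.n_trials)
    n, a, b = spec.n_trials, spec.a, spec.b
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    out = log_choose + betaln(k + a, n - k + b) - betaln(a, b)
    return out if np.ndim(count) else float(out)


def pmf(count, spec: BetaBinomialSpec):
    """Probability mass ``P(K = count)``; see :func:`logpmf`."""
    return np.exp(logpmf(count, spec))


def from_moments(mean_prop: float, variance: float, n_trials: int) -> BetaBinomialSpec:
    """Build a spec from beta-component moments.

    Inverts the moment relations: ``phi = mu (1-mu) / var - 1``, ``a = mu phi``,
    ``b = (1-mu) phi``.  The variance must lie strictly below the beta bound
    ``mu (1-mu)`` (with a small margin; at the bound the beta degenerates to a
    two-point distribution).
    """
    if not 0.0 < mean_prop < 1.0:
        raise ValueError(f"mean_prop must be in (0,1), got {mean_prop}")
    if variance <= 0:
        raise FeasibilityError(f"variance must be positive, got {variance}")
    bound = mean_prop * (1.0 - mean_prop)
    if variance > (1.0 - FEASIBILITY_MARGIN) * bound:
        raise FeasibilityError(
            f"variance {variance} infeasible: must be < mu(1-mu) = {bound:.6g} "
            f"for mean {mean_prop}"
        )
    phi = bound / variance - 1.0
    return BetaBinomialSpec(a=mean_prop * phi, b=(1.0 - mean_prop) * phi, n_trials=n_trials)


def from_mean_phi(mean_prop: float, phi: float, n_trials: int) -> BetaBinomialSpec:
    """Build a spec from the beta mean and overdispersion ``phi = a + b``."""
    if not 0.0 < mean_prop < 1.0:
        raise ValueError(f"mean_prop must be in (0,1), got {mean_prop}")
    if phi <= 0:
        raise FeasibilityError(f"phi must be positive, got {phi}")
    return BetaBinomialSpec(a=mean_prop * phi, b=(1.0 - mean_prop) * phi, n_trials=n_trials)


def sample(spec: BetaBinomialSpec, rng: np.random.Generator, size=None):
    """Draw counts by the two-stage scheme: theta ~ Beta(a,b), K ~ Binom(n, theta)."""
    theta = rng.beta(spec.a, spec.b, size=size)
    return rng.binomial(spec.n_trials, theta)


def is_unimodal(spec: BetaBinomialSpec) -> bool:
    """True iff the beta component has a strict interior mode (a > 1 and b > 1).

    Boundary cases (a = 1 or b = 1, including the flat a = b = 1 beta) are
    counted as NOT unimodal: the constraint is used during fitting as a strict
    interior condition.
    """
    return spec.a > 1.0 and spec.b > 1.0


def is_bimodal(spec: BetaBinomialSpec) -> bool:
    """True iff the beta component is U-shaped (a < 1 and b < 1).

    A U-shaped mixing density piles probability at both empty and full cover;
    the disturbance component of the mixture model excludes this region
    (equivalently ``phi >= min(1/mu, 1/(1-mu))``).
    """
    return spec.a < 1.0 and spec.b < 1.0
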