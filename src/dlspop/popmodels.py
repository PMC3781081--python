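"""Population-model skeletons, variance laws, and the disturbance mixture.

A model of annual cover change has four pluggable pieces:

1. **Mean map** — the deterministic skeleton giving expected next-census
   cover ``mu_t`` from lagged proportional covers ``p_{t-1} .. p_{t-L}``.
   Two families are provided, both modified to admit immigration into
   unoccupied space and optional power-law non-linearity:

   * modified Ricker::

       mu_t = I (1 - p_{t-1}) + p_{t-1} exp(r + sum_x [alpha_x p_{t-x} + beta_x p_{t-x}^{c_x}])

   * modified Hassell::

       mu_t = I (1 - p_{t-1}) + p_{t-1} exp(r + sum_x beta_x p_{t-x}^{c_x}) / (1 + sum_x alpha_x p_{t-x})^g

2. **Undisturbed variance law** — all variances are *relative*: fractions of
   the beta feasibility bound ``mu (1 - mu)``, equivalently a predicted
   overdispersion ``phi = 1/sigma^2 - 1``.  The constant law holds
   ``sigma^2`` fixed; the density-linked law lets it vary with density::

       sigma^2(p) = exp(x + y p^z)        (fraction of mu (1 - mu))

   which can be flat (y=0), monotone, or threshold-like (large z localises
   the change near full cover), and keeps the variance inside the
   beta-feasible region automatically — which is what makes estimation under
   the variance constraint efficient.  The constant law is exactly the y=0
   member of this family.

3. **Disturbance mixture** — with probability ``Psi_d(p) = logistic(j + k p)``
   the next census is drawn not from the growth model but from a
   post-disturbance beta-binomial with mean ``mu_d`` and relative variance
   ``sigma2_d``, constrained to a unimodal beta component (a > 1 and b > 1).

4. **Observation model** — the beta-binomial of :mod:`dlspop.betabinom` on
   the count lattice ``0 .. n_trials``.

Parameters are carried as a flat ``{name: value}`` mapping whose universe is
determined by a :class:`ModelSpec`; parameters fixed a priori (e.g.
``beta_x = 0``, ``c_x = 1`` in linear variants) stay in the mapping but are
masked out of the free-parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .betabinom import BetaBinomialSpec, FeasibilityError, from_mean_phi, is_unimodal

__all__ = [
    "ModelSpec",
    "TransitionDistribution",
    "ricker_mean",
    "hassell_mean",
    "undisturbed_variance",
    "disturbance_probability",
    "transition_distribution",
    "transition_components",
    "MEAN_CLIP_EPS",
    "PHI_FLOOR",
]

#: expected proportions are clamped to [EPS, 1-EPS] so the beta mean is interior
MEAN_CLIP_EPS = 1e-9

#: overdispersion floor used when clamping infeasible variances (see methods note)
PHI_FLOOR = 0.05

#: overdispersion ceiling under clamping; beyond ~1e8 the log-gamma
#: differences in the pmf lose all precision to cancellation
PHI_CEIL = 1e8


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one model variant.

    Parameters
    ----------
    mean
        Mean-map family, ``"ricker"`` or ``"hassell"``.
    order
        Maximum lag L in years (1..4).
    linear
        If True, the non-linear terms are fixed a priori (``beta_x = 0``,
        ``c_x = 1``).
    variance
        ``"constant"`` (single sigma^2) or ``"dls"`` (density-linked,
        parameters x, y, z).
    mixture
        Whether the disturbance mixture is included (parameters mu_d,
        sigma2_d, j, k).
    fixed
        Extra parameters fixed a priori, name -> value, beyond those implied
        by ``linear``.
    """

    mean: str = "ricker"
    order: int = 1
    linear: bool = True
    variance: str = "constant"
    mixture: bool = False
    fixed: tuple = field(default_factory=tuple)  # tuple of (name, value) pairs

    def __post_init__(self):
        if self.mean not in ("ricker", "hassell"):
            raise ValueError(f"unknown mean family {self.mean!r}")
        if not 1 <= self.order <= 4:
            raise ValueError(f"order must be in 1..4, got {self.order}")
        if self.variance not in ("constant", "dls"):
            raise ValueError(f"unknown variance mode {self.variance!r}")
        if isinstance(self.fixed, dict):  # tolerate dict input
            object.__setattr__(self, "fixed", tuple(sorted(self.fixed.items())))

    # -- parameter bookkeeping ---------------------------------------------

    def param_names(self) -> list[str]:
        """Full parameter universe for this spec (free and fixed)."""
        names = ["I", "r"]
        for x in range(1, self.order + 1):
            names += [f"alpha{x}", f"beta{x}", f"c{x}"]
        if self.mean == "hassell":
            names.append("g")
        if self.variance == "constant":
            names.append("sigma2")
        else:
            names += ["x", "y", "z"]
        if self.mixture:
            names += ["mu_d", "sigma2_d", "j", "k"]
        return names

    def fixed_values(self) -> dict[str, float]:
        """Parameters fixed a priori, name -> value."""
        out: dict[str, float] = {}
        if self.linear:
            for x in range(1, self.order + 1):
                out[f"beta{x}"] = 0.0
                out[f"c{x}"] = 1.0
        out.update(dict(self.fixed))
        return out

    def free_names(self) -> list[str]:
        fixed = self.fixed_values()
        return [n for n in self.param_names() if n not in fixed]

    @property
    def k_free(self) -> int:
        """Number of estimated (free) parameters."""
        return len(self.free_names())

    def full_params(self, params: dict[str, float]) -> dict[str, float]:
        """Merge supplied values with fixed ones; validate completeness."""
        merged = dict(self.fixed_values())
        merged.update(params)
        missing = [n for n in self.param_names() if n not in merged]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        return {n: float(merged[n]) for n in self.param_names()}

    # -- nesting ------------------------------------------------------------

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True if this spec is a special case of ``other``.

        Linear variants are nested in non-linear ones, constant variance in
        density-linked (y = 0 recovers a constant), non-mixture in mixture
        (j -> -inf), and lower orders in higher orders; mean families do not
        nest in each other.
        """
        if self.mean != other.mean:
            return False
        if self.order > other.order:
            return False
        if other.linear and not self.linear:
            return False
        if self.variance == "dls" and other.variance != "dls":
            return False
        if self.mixture and not other.mixture:
            return False
        return self != other

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "order": self.order,
            "linear": self.linear,
            "variance": self.variance,
            "mixture": self.mixture,
            "fixed": dict(self.fixed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            mean=d.get("mean", "ricker"),
            order=int(d.get("order", 1)),
            linear=bool(d.get("linear", True)),
            variance=d.get("variance", "constant"),
            mixture=bool(d.get("mixture", False)),
            fixed=tuple(sorted(d.get("fixed", {}).items())),
        )

    def label(self) -> str:
        bits = [self.mean, f"order{self.order}", "linear" if self.linear else "nonlinear",
                self.variance, "mixture" if self.mixture else "nomix"]
        return "-".join(bits)


# ---------------------------------------------------------------------------
# mean maps


def _lag_array(lag_props, order: int) -> np.ndarray:
    lags = np.atleast_2d(np.asarray(lag_props, dtype=float))
    if lags.shape[-1] < order:
        raise ValueError(
            f"need {order} lagged proportions (most recent first), got {lags.shape[-1]}"
        )
    lags = lags[..., :order]
    if np.any(lags < 0) or np.any(lags > 1):
        raise ValueError("lagged proportions must lie in [0, 1]")
    return lags


def _clip_mean(mu: np.ndarray) -> np.ndarray:
    return np.clip(mu, MEAN_CLIP_EPS, 1.0 - MEAN_CLIP_EPS)


def ricker_mean(lag_props, params: dict[str, float], order: int = 1):
    """Expected next proportion under the modified Ricker map.

    ``mu_t = I (1 - p_{t-1}) + p_{t-1} exp(r + sum_x alpha_x p_{t-x}
    + beta_x p_{t-x}^{c_x})``: immigration fills a fraction I of unoccupied
    space, while the occupied fraction grows or shrinks by a Ricker factor
    with linear and power-law density dependence at each lag.

    ``lag_props`` holds lagged proportions most recent first; accepts a single
    lag vector or a stack of rows.  Output is clipped to the open unit
    interval so it can serve as a beta mean.
    """
    lags = _lag_array(lag_props, order)
    expo = np.full(lags.shape[:-1], float(params["r"]))
    for x in range(1, order + 1):
        p_x = lags[..., x - 1]
        c = float(params[f"c{x}"])
        if c <= 0:
            raise ValueError(f"c{x} must be positive, got {c}")
        expo = expo + float(params[f"alpha{x}"]) * p_x + float(params[f"beta{x}"]) * p_x ** c
    p1 = lags[..., 0]
    mu = float(params["I"]) * (1.0 - p1) + p1 * np.exp(expo)
    mu = _clip_mean(mu)
    return mu if np.asarray(lag_props).ndim > 1 else float(mu[0])


def hassell_mean(lag_props, params: dict[str, float], order: int = 1):
    """Expected next proportion under the modified Hassell map.

    ``mu_t = I (1 - p_{t-1}) + p_{t-1} exp(r + sum_x beta_x p_{t-x}^{c_x})
    / (1 + sum_x alpha_x p_{t-x})^g``: density dependence acts through the
    Hassell denominator instead of the Ricker exponent, with the same
    immigration and extra non-linearity terms.
    """
    lags = _lag_array(lag_props, order)
    num_expo = np.full(lags.shape[:-1], float(params["r"]))
    denom = np.ones(lags.shape[:-1])
    for x in range(1, order + 1):
        p_x = lags[..., x - 1]
        c = float(params[f"c{x}"])
        if c <= 0:
            raise ValueError(f"c{x} must be positive, got {c}")
        num_expo = num_expo + float(params[f"beta{x}"]) * p_x ** c
        denom = denom + float(params[f"alpha{x}"]) * p_x
    denom = np.maximum(denom, 1e-12)
    g = float(params.get("g", 1.0))
    p1 = lags[..., 0]
    mu = float(params["I"]) * (1.0 - p1) + p1 * np.exp(num_expo) / denom ** g
    mu = _clip_mean(mu)
    return mu if np.asarray(lag_props).ndim > 1 else float(mu[0])


def mean_map(lag_props, spec: ModelSpec, params: dict[str, float]):
    """Dispatch to the spec's mean family."""
    fn = ricker_mean if spec.mean == "ricker" else hassell_mean
    return fn(lag_props, params, order=spec.order)


# ---------------------------------------------------------------------------
# variance and disturbance


def dls_variance_fraction(p, params: dict[str, float]):
    """Density-linked variance fraction ``exp(x + y p^z)`` of the beta bound."""
    p_arr = np.asarray(p, dtype=float)
    z = float(params["z"])
    if z <= 0:
        raise ValueError(f"z must be positive, got {z}")
    return np.exp(float(params["x"]) + float(params["y"]) * p_arr ** z)


def undisturbed_variance(p, params: dict[str, float], mode: str = "dls"):
    """Relative variance of undisturbed cover change at density ``p``.

    Returned on the relative scale: the fraction of the beta feasibility
    bound ``mu (1 - mu)`` occupied by the variance, equivalently
    ``1 / (phi + 1)`` for overdispersion phi.  ``mode="constant"`` returns
    ``sigma2`` regardless of density; ``mode="dls"`` evaluates
    ``sigma^2(p) = exp(x + y p^z)``, which with y < 0 and large z declines
    with abundance, dropping sharply near full cover.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("p must lie in [0, 1]")
    if mode == "constant":
        s2 = float(params["sigma2"])
        if not 0.0 < s2 < 1.0:
            raise FeasibilityError(
                f"constant relative variance must lie in (0, 1), got {s2}")
        out = np.full_like(p_arr, s2, dtype=float)
    elif mode == "dls":
        out = dls_variance_fraction(p_arr, params)
    else:
        raise ValueError(f"unknown variance mode {mode!r}")
    return out if p_arr.ndim else float(out)


def disturbance_probability(p, params: dict[str, float]):
    """Probability ``Psi_d(p) = logistic(j + k p)`` of a disturbance transition.

    Bounded in [0, 1] for any (j, k); strictly increasing in density when
    k > 0, as estimated for wave disturbance of crowded mussel beds.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("p must lie in [0, 1]")
    out = expit(float(params["j"]) + float(params["k"]) * p_arr)
    return out if p_arr.ndim else float(out)


def _phi_from_fraction(frac, clamp: bool, where: str = ""):
    """Overdispersion phi = 1/frac - 1 from a relative variance, floored or checked."""
    frac = np.asarray(frac, dtype=float)
    if clamp:
        frac = np.clip(frac, 1.0 / (1.0 + PHI_CEIL), 1.0 / (1.0 + PHI_FLOOR))
    elif np.any(frac >= 1.0) or np.any(frac <= 0.0):
        raise FeasibilityError(
            f"relative variance {float(np.ravel(frac)[0]):.6g} outside (0, 1)"
            + (f" for {where}" if where else ""))
    return 1.0 / frac - 1.0


def transition_components(lag_props, spec: ModelSpec, params: dict[str, float],
                          clamp: bool = True):
    """Vectorized pieces of the transition distribution for stacked lag rows.

    Returns ``(mu_t, phi_u, psi_d, mu_d, phi_d)`` where the first three are
    arrays over rows and the last two are scalars (or None when the spec has
    no mixture).  ``clamp=True`` floors the overdispersion instead of raising
    when a variance touches the beta feasibility bound.
    """
    full = spec.full_params(params)
    lags = _lag_array(lag_props, spec.order)
    mu_t = np.asarray(mean_map(lags, spec, full))
    p1 = lags[..., 0]
    frac = undisturbed_variance(p1, full, mode=spec.variance)
    phi_u = _phi_from_fraction(frac, clamp=clamp, where="undisturbed state")
    if not spec.mixture:
        return mu_t, phi_u, np.zeros_like(mu_t), None, None
    psi_d = np.asarray(disturbance_probability(p1, full))
    mu_d = float(full["mu_d"])
    phi_d = float(_phi_from_fraction(full["sigma2_d"], clamp=clamp,
                                     where="disturbed state"))
    return mu_t, phi_u, psi_d, mu_d, phi_d


@dataclass(frozen=True)
class TransitionDistribution:
    """Distribution of the next census count given lagged covers.

    A two-component mixture on the count lattice ``0..n_trials``: with
    probability ``1 - psi_d`` a beta-binomial centred on the growth-model mean
    ``mu_t``, and with probability ``psi_d`` the post-disturbance
    beta-binomial (mean ``mu_d``).
    """

    mu_t: float
    sigma2_t: float
    psi_d: float
    undisturbed: BetaBinomialSpec
    disturbed: BetaBinomialSpec | None

    def pmf(self, counts=None) -> np.ndarray:
        """Mixture pmf at ``counts`` (default: the whole lattice)."""
        from .betabinom import pmf as bb_pmf

        if counts is None:
            counts = np.arange(self.undisturbed.n_trials + 1)
        p_u = bb_pmf(counts, self.undisturbed)
        if self.disturbed is None or self.psi_d == 0.0:
            return (1.0 - self.psi_d) * p_u if self.psi_d else p_u
        p_d = bb_pmf(counts, self.disturbed)
        return (1.0 - self.psi_d) * p_u + self.psi_d * p_d

    def sample(self, rng: np.random.Generator, size=None):
        """Draw next-census counts (disturbance indicator, then component)."""
        from .betabinom import sample as bb_sample

        if self.disturbed is None or self.psi_d == 0.0:
            return bb_sample(self.undisturbed, rng, size=size)
        disturbed = rng.random(size=size) < self.psi_d
        out = np.where(
            disturbed,
            bb_sample(self.disturbed, rng, size=size),
            bb_sample(self.undisturbed, rng, size=size),
        )
        return out if size is not None else int(out)


def transition_distribution(lag_props, spec: ModelSpec, params: dict[str, float],
                            n_trials: int, clamp: bool = False,
                            validate_disturbed: bool = True) -> TransitionDistribution:
    """Assemble the full next-census distribution for a single lag vector.

    With ``validate_disturbed`` the post-disturbance beta component is
    required to be unimodal (interior mode, a > 1 and b > 1), the constraint
    imposed on the disturbed state during fitting.
    """
    lags = np.asarray(lag_props, dtype=float).reshape(1, -1)
    mu_t, phi_u, psi_d, mu_d, phi_d = transition_components(lags, spec, params, clamp=clamp)
    mu_t, phi_u, psi_d = float(mu_t[0]), float(phi_u[0]), float(psi_d[0])
    undisturbed = from_mean_phi(mu_t, phi_u, n_trials)
    disturbed = None
    if spec.mixture:
        disturbed = from_mean_phi(mu_d, phi_d, n_trials)
        if validate_disturbed and not is_unimodal(disturbed):
            raise FeasibilityError(
                f"disturbed state (mu_d={mu_d:.4g}, phi_d={phi_d:.4g}) is not "
                f"unimodal: requires phi_d > max(1/mu_d, 1/(1-mu_d)) = "
                f"{max(1 / mu_d, 1 / (1 - mu_d)):.4g}"
            )
    sigma2_t = mu_t * (1 - mu_t) / (phi_u + 1.0)
    return TransitionDistribution(mu_t=mu_t, sigma2_t=sigma2_t, psi_d=psi_d,
                                  undisturbed=undisturbed, disturbed=disturbed)
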