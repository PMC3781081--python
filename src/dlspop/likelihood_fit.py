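"""Dataset construction, mixture likelihood, ML fitting, and AIC comparison.

The observational unit is a plot's annual census series of occupied sample
units.  Fitting pools one-step transitions across plots: each row of a
:class:`LagDataset` pairs an observed next-census count with the lagged
proportional covers that predict it.  The row log-likelihood is the mixture

    LL = log((1 - Psi_d) L + Psi_d L_d)

where L and L_d are beta-binomial likelihoods of the undisturbed growth model
and the post-disturbance state.  Models are ranked by AIC and summarised with
Akaike weights, evidence ratios, and weight-based model averaging.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, expit, gammaln, logit
from scipy.stats import qmc

from .betabinom import FeasibilityError
from .popmodels import ModelSpec, transition_components

__all__ = [
    "PlotTimeSeries",
    "LagDataset",
    "FitResult",
    "ComparisonTable",
    "build_lag_dataset",
    "negative_log_likelihood",
    "fit_ml",
    "aic",
    "compare_models",
    "model_average",
]

#: upper bound for non-linearity exponents c_x (log-scale reparameterization)
C_MAX = 200.0
#: upper bound for the DLS variance exponent z
Z_MAX = 100.0


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class PlotTimeSeries:
    """One plot's annual census series.

    ``years`` are calendar years, strictly increasing with at most
    single-year gaps (a missing census appears as an absent year, not a
    placeholder).  ``counts`` are occupied sample units out of ``n_max``.
    """

    plot_id: str
    years: np.ndarray
    counts: np.ndarray
    n_max: int

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "counts", counts)
        if years.shape != counts.shape or years.ndim != 1 or len(years) == 0:
            raise ValueError(f"plot {self.plot_id}: years/counts must be equal-length 1-D")
        d = np.diff(years)
        if np.any(d < 1):
            raise ValueError(f"plot {self.plot_id}: years must be strictly increasing")
        if np.any(d > 2):
            raise ValueError(f"plot {self.plot_id}: gaps longer than one census year")
        if self.n_max < 1:
            raise ValueError(f"plot {self.plot_id}: n_max must be positive")
        if np.any(counts < 0) or np.any(counts > self.n_max):
            raise ValueError(f"plot {self.plot_id}: counts must lie in [0, n_max]")

    @property
    def props(self) -> np.ndarray:
        """Proportional cover per census."""
        return self.counts / self.n_max

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class LagDataset:
    """Pooled one-step transition rows across plots.

    Row i predicts count ``counts[i]`` (out of ``n_max[i]``) in ``years[i]``
    from the lagged proportions ``lags[i] = (p_{t-1}, ..., p_{t-L})``.  Rows
    never span a missing census.
    """

    plot_ids: np.ndarray
    years: np.ndarray
    counts: np.ndarray
    n_max: np.ndarray
    lags: np.ndarray  # (n_rows, max_lag), most recent first
    max_lag: int

    @property
    def n_rows(self) -> int:
        return len(self.counts)

    def fingerprint(self) -> str:
        """Order-invariant hash identifying the dataset contents."""
        rows = sorted(
            (str(p), int(y), int(c), int(n), tuple(np.round(l, 12)))
            for p, y, c, n, l in zip(self.plot_ids, self.years, self.counts,
                                     self.n_max, self.lags)
        )
        h = hashlib.sha256(repr(rows).encode())
        return h.hexdigest()[:16]


def build_lag_dataset(plots, max_lag: int = 1) -> LagDataset:
    """Pool transition rows from plots, dropping rows that span a gap.

    A target year t contributes a row only if censuses at t, t-1, ..,
    t-max_lag are all present.
    """
    if max_lag not in (1, 2, 3, 4):
        raise ValueError(f"max_lag must be in 1..4, got {max_lag}")
    pid, yrs, cts, nmx, lag_rows = [], [], [], [], []
    for plot in plots:
        year_index = {int(y): i for i, y in enumerate(plot.years)}
        props = plot.props
        for y in plot.years:
            y = int(y)
            needed = [y - l for l in range(1, max_lag + 1)]
            if all(n in year_index for n in needed):
                pid.append(plot.plot_id)
                yrs.append(y)
                cts.append(int(plot.counts[year_index[y]]))
                nmx.append(plot.n_max)
                lag_rows.append([props[year_index[n]] for n in needed])
    if not lag_rows:
        raise ValueError("no usable transitions: every candidate row spans a gap "
                         "or series are shorter than max_lag+1")
    return LagDataset(
        plot_ids=np.array(pid), years=np.array(yrs, dtype=int),
        counts=np.array(cts, dtype=int), n_max=np.array(nmx, dtype=int),
        lags=np.array(lag_rows, dtype=float), max_lag=max_lag,
    )


# ---------------------------------------------------------------------------
# likelihood


def _bb_logpmf_arrays(counts, n_trials, mu, phi):
    """Row-wise beta-binomial log-pmf with per-row n, mean, overdispersion."""
    a = mu * phi
    b = (1.0 - mu) * phi
    k = counts
    n = n_trials
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + betaln(k + a, n - k + b) - betaln(a, b))


def negative_log_likelihood(data: LagDataset, spec: ModelSpec,
                            params: dict[str, float], clamp: bool = False) -> float:
    """Negative log-likelihood of the (possibly mixture) model on the data.

    Per row: ``-log[(1 - Psi_d) BB(N_t; mu_t, phi_u) + Psi_d BB(N_t; mu_d,
    phi_d)]``; non-mixture specs use ``Psi_d = 0``.  Raises
    :class:`~dlspop.betabinom.FeasibilityError` when a parameter set implies
    an infeasible variance at some row's density (``clamp=True`` floors the
    overdispersion instead, the behaviour used inside the optimizer).
    """
    mu_t, phi_u, psi_d, mu_d, phi_d = transition_components(
        data.lags, spec, params, clamp=clamp)
    lp_u = _bb_logpmf_arrays(data.counts, data.n_max, mu_t, phi_u)
    if not spec.mixture:
        return float(-np.sum(lp_u))
    lp_d = _bb_logpmf_arrays(data.counts, data.n_max, mu_d, phi_d)
    with np.errstate(divide="ignore"):
        row_ll = np.logaddexp(np.log1p(-psi_d) + lp_u, np.log(psi_d) + lp_d)
    return float(-np.sum(row_ll))


# ---------------------------------------------------------------------------
# parameter transforms: free vector in R^k <-> constrained named parameters


def _transform_info(spec: ModelSpec):
    """Per-free-parameter (to_free, from_free) scalar transforms.

    c_x and z use scaled-logistic bounds, I and mu_d a logit, sigma2 a scaled
    logistic below the maximal beta variance; sigma2_d is carried as the gap
    of phi_d above the non-bimodality bound (log scale), coupling it to mu_d.
    """
    names = spec.free_names()

    def ident(v):
        return v

    def make_logistic(hi):
        return (lambda v: logit(np.clip(v / hi, 1e-12, 1 - 1e-12)),
                lambda t: hi * float(np.clip(expit(t), 1e-12, 1 - 1e-12)))

    to_f, from_f = {}, {}
    for n in names:
        if n in ("I", "mu_d"):
            to_f[n] = lambda v: logit(np.clip(v, 1e-9, 1 - 1e-9))
            from_f[n] = lambda t: float(np.clip(expit(t), 1e-9, 1.0 - 1e-9))
        elif n.startswith("c") and n[1:].isdigit():
            to_f[n], from_f[n] = make_logistic(C_MAX)
        elif n == "z":
            to_f[n], from_f[n] = make_logistic(Z_MAX)
        elif n == "sigma2":
            to_f[n], from_f[n] = make_logistic(0.25)
        elif n == "g":
            to_f[n] = lambda v: math.log(max(v, 1e-12))
            from_f[n] = math.exp
        else:  # r, alpha_x, beta_x, x, y, j, k, sigma2_d (handled jointly)
            to_f[n] = ident
            from_f[n] = ident
    return names, to_f, from_f


def _phi_d_bound(mu_d: float) -> float:
    """Smallest non-bimodal overdispersion for the disturbed state."""
    return min(1.0 / mu_d, 1.0 / (1.0 - mu_d))


def _params_to_free(spec: ModelSpec, params: dict[str, float]) -> np.ndarray:
    names, to_f, _ = _transform_info(spec)
    full = spec.full_params(params)
    vec = []
    for n in names:
        if n == "sigma2_d":
            mu_d = full["mu_d"]
            phi_d = mu_d * (1 - mu_d) / full["sigma2_d"] - 1.0
            gap = phi_d - _phi_d_bound(mu_d)
            vec.append(math.log(max(gap, 1e-9)))
        else:
            vec.append(float(to_f[n](full[n])))
    return np.array(vec)


def _free_to_params(spec: ModelSpec, vec: np.ndarray) -> dict[str, float]:
    names, _, from_f = _transform_info(spec)
    params = {}
    raw = dict(zip(names, vec))
    for n in names:
        if n == "sigma2_d":
            continue
        params[n] = float(from_f[n](raw[n]))
    if "sigma2_d" in names:
        mu_d = params["mu_d"]
        phi_d = _phi_d_bound(mu_d) + math.exp(min(raw["sigma2_d"], 50.0))
        params["sigma2_d"] = mu_d * (1 - mu_d) / (phi_d + 1.0)
    return params


_DEFAULT_INIT = {
    "I": 0.15, "r": 0.3, "alpha1": -0.3, "alpha2": 0.0, "alpha3": 0.0, "alpha4": 0.0,
    "beta1": 0.01, "beta2": 0.0, "beta3": 0.0, "beta4": 0.0,
    "c1": 10.0, "c2": 1.0, "c3": 1.0, "c4": 1.0, "g": 1.0,
    "sigma2": 0.04, "x": -3.0, "y": -1.0, "z": 10.0,
    "mu_d": 0.4, "sigma2_d": 0.06, "j": -2.5, "k": 1.5,
}


# ---------------------------------------------------------------------------
# fitting and comparison


@dataclass(frozen=True)
class FitResult:
    """ML fit of one model spec on one dataset."""

    spec: ModelSpec
    params: dict[str, float]  # free-parameter estimates
    neg_ll: float
    k: int
    aic: float
    dataset_fingerprint: str
    n_rows: int
    converged: bool = True
    n_starts: int = 1

    def full_params(self) -> dict[str, float]:
        """Estimates merged with a-priori fixed values."""
        return self.spec.full_params(self.params)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params": self.params,
            "neg_ll": self.neg_ll,
            "k": self.k,
            "aic": self.aic,
            "dataset_fingerprint": self.dataset_fingerprint,
            "n_rows": self.n_rows,
            "converged": self.converged,
            "n_starts": self.n_starts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(spec=ModelSpec.from_dict(d["spec"]),
                   params={k: float(v) for k, v in d["params"].items()},
                   neg_ll=float(d["neg_ll"]), k=int(d["k"]), aic=float(d["aic"]),
                   dataset_fingerprint=d["dataset_fingerprint"],
                   n_rows=int(d["n_rows"]), converged=bool(d.get("converged", True)),
                   n_starts=int(d.get("n_starts", 1)))


def aic(neg_ll: float, k: int) -> float:
    """Akaike Information Criterion, ``AIC = 2k + 2(-LL)``."""
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    return 2.0 * k + 2.0 * neg_ll


def fit_ml(data: LagDataset, spec: ModelSpec, n_starts: int = 20, seed: int = 0,
           start: dict[str, float] | None = None, maxiter: int = 500) -> FitResult:
    """Maximum-likelihood fit by multistart bounded quasi-Newton optimization.

    The mixture likelihood surface is multimodal, so optimization runs from a
    heuristic start plus ``n_starts - 1`` seeded low-discrepancy (Sobol)
    scatter points in the transformed parameter space; the best local optimum
    is kept.  Constraints are enforced by reparameterization: logit for
    proportions, scaled logistic for c_x (0, 200] and z, and a log-gap above
    the non-bimodality bound for the disturbed-state variance.  Deterministic
    under a fixed seed.
    """
    if data.max_lag < spec.order:
        raise ValueError(f"dataset has max_lag={data.max_lag} < spec order {spec.order}")
    if data.n_rows < 3 * spec.k_free:
        warnings.warn(
            f"only {data.n_rows} rows for {spec.k_free} free parameters; "
            "estimates may be poorly identified", stacklevel=2)

    def objective(vec):
        params = _free_to_params(spec, vec)
        try:
            # extreme scatter starts can overflow exp(); they score 1e12 below
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                nll = negative_log_likelihood(data, spec, params, clamp=True)
        except (FeasibilityError, ValueError, FloatingPointError, OverflowError):
            return 1e12
        # a discrete-data NLL is mathematically >= 0; negative values signal
        # catastrophic cancellation in extreme-parameter corners
        if not np.isfinite(nll) or nll < -1e-6:
            return 1e12
        return nll

    base = dict(_DEFAULT_INIT)
    if start is not None:
        base.update(start)
    base_vec = _params_to_free(spec, {n: base[n] for n in spec.free_names()})

    starts = [base_vec]
    if n_starts > 1:
        sob = qmc.Sobol(d=len(base_vec), scramble=True, seed=seed)
        scatter = sob.random(n_starts - 1)  # in [0,1)^d
        starts += list(base_vec + 4.0 * (scatter - 0.5))

    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"all {len(starts)} optimization starts failed for {spec.label()}: "
            f"last status {getattr(best, 'message', 'n/a')}")

    params = _free_to_params(spec, best.x)
    neg_ll = negative_log_likelihood(data, spec, params, clamp=True)
    k = spec.k_free
    return FitResult(spec=spec, params=params, neg_ll=neg_ll, k=k,
                     aic=aic(neg_ll, k), dataset_fingerprint=data.fingerprint(),
                     n_rows=data.n_rows, converged=bool(best.success),
                     n_starts=len(starts))


@dataclass(frozen=True)
class ComparisonTable:
    """AIC comparison of fits on a common dataset.

    ``supported`` applies the dual rule: Delta AIC < 6 relative to the best
    model, vetoed when a simpler nested model (declared through
    :meth:`ModelSpec.is_nested_in`) achieves a lower AIC.
    """

    labels: list[str]
    specs: list[ModelSpec]
    neg_ll: np.ndarray
    k: np.ndarray
    aic: np.ndarray
    delta_aic: np.ndarray
    weights: np.ndarray
    evidence_ratios: np.ndarray
    supported: np.ndarray
    best_index: int
    fits: list = field(default_factory=list, repr=False)


def compare_models(fits) -> ComparisonTable:
    """Rank >= 2 fits of different specs on the same dataset.

    ``Delta_i = AIC_i - min AIC``; ``w_i = exp(-Delta_i/2) / sum``;
    ``ER_i = w_best / w_i``.  Ties in the minimum AIC break toward smaller k,
    then lexicographic spec label, so reports are deterministic.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    fps = {f.dataset_fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError(f"fits come from different datasets: fingerprints {sorted(fps)}")
    aics = np.array([f.aic for f in fits])
    labels = [f.spec.label() for f in fits]
    order = sorted(range(len(fits)), key=lambda i: (aics[i], fits[i].k, labels[i]))
    best = order[0]
    delta = aics - aics[best]
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    er = w[best] / w
    supported = delta < 6.0
    for i, fi in enumerate(fits):
        for j, fj in enumerate(fits):
            if i != j and fj.spec.is_nested_in(fi.spec) and aics[j] < aics[i]:
                supported[i] = False
    return ComparisonTable(
        labels=labels, specs=[f.spec for f in fits],
        neg_ll=np.array([f.neg_ll for f in fits]), k=np.array([f.k for f in fits]),
        aic=aics, delta_aic=delta, weights=w, evidence_ratios=er,
        supported=supported, best_index=best, fits=fits,
    )


def model_average(fits, weights=None) -> dict[str, float]:
    """Akaike-weight average of parameter values across fits.

    Fixed-a-priori parameters contribute their fixed values.  A parameter is
    averaged over the models whose universe contains it, with weights
    renormalized within that subset.
    """
    fits = list(fits)
    if weights is None:
        if len(fits) == 1:
            weights = np.array([1.0])
        else:
            weights = compare_models(fits).weights
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(fits):
        raise ValueError("one weight per fit required")
    universe: list[str] = []
    for f in fits:
        for n in f.spec.param_names():
            if n not in universe:
                universe.append(n)
    out = {}
    for n in universe:
        vals, ws = [], []
        for f, w in zip(fits, weights):
            full = f.full_params()
            if n in full:
                vals.append(full[n])
                ws.append(w)
        if vals:
            ws = np.asarray(ws)
            out[n] = float(np.dot(ws, vals) / ws.sum())
    return out
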