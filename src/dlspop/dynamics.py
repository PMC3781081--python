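"""Forward simulation, attractor analysis, prediction envelopes, and spectra.

These diagnostics ask whether a fitted model can reproduce the dynamical
character of the observed series: does the noise-free skeleton converge to a
stable cover, do stochastic trajectories show the build-up/crash pattern, is
low-frequency spectral power as strong as observed, and do one-step outcomes
fall inside the model's 95% prediction region?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popmodels import ModelSpec, mean_map, transition_components

__all__ = [
    "Ensemble",
    "Envelope",
    "Spectrum",
    "iterate_deterministic",
    "find_attractor",
    "simulate",
    "prediction_envelope",
    "hpd_mask",
    "power_spectrum",
    "ensemble_spectrum",
]


# ---------------------------------------------------------------------------
# deterministic skeleton


def iterate_deterministic(spec: ModelSpec, params: dict[str, float],
                          p0: float, T: int) -> np.ndarray:
    """Iterate the noise-free mean map for T steps from cover ``p0``.

    Higher-order specs iterate on the lag vector, with all lags initialised
    at ``p0``.  Returns the trajectory including the initial state
    (length T+1).
    """
    full = spec.full_params(params)
    lag = np.full(spec.order, float(p0))
    traj = np.empty(T + 1)
    traj[0] = p0
    for t in range(1, T + 1):
        mu = mean_map(lag, spec, full)
        traj[t] = mu
        lag = np.roll(lag, 1)
        lag[0] = mu
    return traj


def find_attractor(spec: ModelSpec, params: dict[str, float], p0: float,
                   tol: float = 1e-10, max_iter: int = 10 ** 5,
                   max_period: int = 50):
    """Locate the attractor reached from ``p0``: a fixed point or short cycle.

    Returns ``(kind, values)`` where kind is ``"fixed_point"`` (values: the
    single limit) or ``"cycle"`` (values: one period of the cycle).  Raises
    if no fixed point or cycle of period <= ``max_period`` emerges within
    ``max_iter`` iterations.
    """
    full = spec.full_params(params)
    lag = np.full(spec.order, float(p0))
    block = max(4 * max_period, 200)
    done = 0
    while done < max_iter:
        window = np.empty(block)
        for i in range(block):
            mu = mean_map(lag, spec, full)
            window[i] = mu
            lag = np.roll(lag, 1)
            lag[0] = mu
        done += block
        for period in range(1, max_period + 1):
            tail = window[-(2 * period):]
            if np.all(np.abs(tail[:period] - tail[period:]) < tol):
                if period == 1:
                    return "fixed_point", np.array([tail[-1]])
                # verify it is not a shorter cycle repeated
                cyc = tail[period:]
                if all(not np.all(np.abs(cyc - np.roll(cyc, q)) < tol)
                       for q in range(1, period)):
                    return "cycle", cyc
    raise RuntimeError(
        f"no fixed point or cycle of period <= {max_period} within {max_iter} "
        f"iterations from p0={p0} (last state {window[-1]:.6g})")


# ---------------------------------------------------------------------------
# stochastic simulation


@dataclass(frozen=True)
class Ensemble:
    """Replicate simulated cover trajectories.

    ``props`` has shape (n_replicates, T+1) including initial conditions;
    ``counts`` the corresponding census counts on each replicate's lattice.
    """

    props: np.ndarray
    counts: np.ndarray
    n_trials: np.ndarray
    spec: ModelSpec
    seed: int

    @property
    def n_replicates(self) -> int:
        return self.props.shape[0]

    @property
    def T(self) -> int:
        return self.props.shape[1] - 1


def simulate(spec: ModelSpec, params: dict[str, float], initial_props,
             T: int, n_trials=484, seed: int = 0) -> Ensemble:
    """Simulate one replicate per initial condition for T annual steps.

    Each step draws the next census count from the transition mixture
    (disturbance indicator, then the selected beta-binomial) and converts it
    back to proportional cover on that replicate's count lattice.
    Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    inits = np.atleast_1d(np.asarray(initial_props, dtype=float))
    R = len(inits)
    n_arr = np.broadcast_to(np.asarray(n_trials, dtype=int), (R,)).copy()
    props = np.empty((R, T + 1))
    counts = np.empty((R, T + 1), dtype=int)
    counts[:, 0] = np.round(inits * n_arr).astype(int)
    props[:, 0] = counts[:, 0] / n_arr
    # lag state per replicate, most recent first
    lag = np.tile(props[:, [0]], (1, spec.order))
    for t in range(1, T + 1):
        mu_t, phi_u, psi_d, mu_d, phi_d = transition_components(
            lag, spec, params, clamp=True)
        theta = rng.beta(mu_t * phi_u, (1.0 - mu_t) * phi_u)
        if spec.mixture:
            disturbed = rng.random(R) < psi_d
            theta_d = rng.beta(mu_d * phi_d, (1.0 - mu_d) * phi_d, size=R)
            theta = np.where(disturbed, theta_d, theta)
        counts[:, t] = rng.binomial(n_arr, theta)
        props[:, t] = counts[:, t] / n_arr
        lag = np.roll(lag, 1, axis=1)
        lag[:, 0] = props[:, t]
    return Ensemble(props=props, counts=counts, n_trials=n_arr, spec=spec, seed=seed)


# ---------------------------------------------------------------------------
# prediction envelopes


@dataclass(frozen=True)
class Envelope:
    """Monte-Carlo one-step prediction regions on the count lattice.

    For each starting cover on the grid, ``histogram[i]`` is the outcome
    count distribution and ``in_envelope[i]`` flags the smallest
    highest-probability set of outcome bins whose mass reaches the coverage
    level (a discrete HPD region, valid for multimodal outcomes).
    """

    grid: np.ndarray
    histogram: np.ndarray  # (n_grid, n_trials+1) draw counts
    in_envelope: np.ndarray  # bool, same shape
    retained_mass: np.ndarray  # (n_grid,)
    coverage: float
    n_trials: int
    iters: int
    seed: int

    def contains(self, p_start, count) -> np.ndarray:
        """Whether observed (start cover, outcome count) pairs fall inside."""
        idx = np.clip(np.round(np.asarray(p_start) / (self.grid[1] - self.grid[0])
                               ).astype(int), 0, len(self.grid) - 1)
        return self.in_envelope[idx, np.asarray(count, dtype=int)]


def hpd_mask(hist: np.ndarray, coverage: float):
    """Smallest highest-probability bin sets reaching ``coverage`` mass.

    ``hist`` is (n_rows, n_bins) of draw counts; returns a boolean mask of
    the retained bins and the actually retained mass per row.  Bins are
    accumulated in decreasing probability until the running mass first
    reaches the target, so the retained mass is always >= coverage and the
    set can be disjoint (multimodal outcomes keep separate islands).
    """
    hist = np.atleast_2d(np.asarray(hist))
    totals = hist.sum(axis=1)
    mask = np.zeros_like(hist, dtype=bool)
    retained = np.empty(len(hist))
    for i, row in enumerate(hist):
        order = np.argsort(row)[::-1]
        csum = np.cumsum(row[order])
        n_keep = int(np.searchsorted(csum, coverage * totals[i]) + 1)
        mask[i, order[:n_keep]] = True
        retained[i] = csum[n_keep - 1] / totals[i]
    return mask, retained


def prediction_envelope(spec: ModelSpec, params: dict[str, float], n_trials: int = 484,
                        increment: float = 0.002, iters: int = 10 ** 6,
                        coverage: float = 0.95, seed: int = 0) -> Envelope:
    """Monte-Carlo next-census outcome regions over a grid of starting covers.

    For each starting density on the grid (spacing ``increment`` from 0 to 1)
    the model is iterated one step ``iters`` times; outcome bins are then
    accumulated from highest to lower probability until their summed mass
    first exceeds ``coverage``.  First-order specs only.
    """
    if spec.order != 1:
        raise ValueError("prediction envelopes are defined for first-order specs")
    if iters < 10 / (1 - coverage):
        import warnings
        warnings.warn(f"iters={iters} is small for coverage={coverage}; "
                      "envelope tails will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, 1.0 + increment / 2, increment)
    n_grid = len(grid)
    hist = np.zeros((n_grid, n_trials + 1), dtype=np.int64)
    lag = grid.reshape(-1, 1)
    mu_t, phi_u, psi_d, mu_d, phi_d = transition_components(lag, spec, params, clamp=True)
    for i in range(n_grid):
        theta = rng.beta(mu_t[i] * phi_u[i], (1 - mu_t[i]) * phi_u[i], size=iters)
        if spec.mixture and psi_d[i] > 0:
            disturbed = rng.random(iters) < psi_d[i]
            nd = int(disturbed.sum())
            if nd:
                theta[disturbed] = rng.beta(mu_d * phi_d, (1 - mu_d) * phi_d, size=nd)
        outcomes = rng.binomial(n_trials, theta)
        hist[i] = np.bincount(outcomes, minlength=n_trials + 1)
    in_env, retained = hpd_mask(hist, coverage)
    return Envelope(grid=grid, histogram=hist, in_envelope=in_env,
                    retained_mass=retained, coverage=coverage,
                    n_trials=n_trials, iters=iters, seed=seed)


# ---------------------------------------------------------------------------
# spectral analysis


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum; ``se`` present for ensemble averages."""

    freqs: np.ndarray  # cycles per census interval, up to Nyquist
    power: np.ndarray
    se: np.ndarray | None = None


def power_spectrum(series) -> Spectrum:
    """One-sided periodogram of a mean-removed series, no taper, no padding.

    Normalised so that the powers sum to the series variance (Parseval):
    ``P_k = |X_k|^2 / n^2`` folded one-sided (interior frequencies doubled).
    Frequencies are in cycles per census interval up to Nyquist (0.5).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("series must be 1-D with length >= 8")
    n = len(x)
    x = x - x.mean()
    X = np.fft.rfft(x)
    power = np.abs(X) ** 2 / n ** 2
    # fold: double everything except DC and (for even n) the Nyquist bin
    fold = np.full(len(power), 2.0)
    fold[0] = 1.0
    if n % 2 == 0:
        fold[-1] = 1.0
    power = power * fold
    freqs = np.fft.rfftfreq(n, d=1.0)
    return Spectrum(freqs=freqs, power=power)


def ensemble_spectrum(trajectories) -> Spectrum:
    """Mean spectrum with standard errors across equal-length replicates.

    Accepts an :class:`Ensemble` or a 2-D array (replicates x time).
    """
    if isinstance(trajectories, Ensemble):
        arr = trajectories.props
    else:
        arr = np.asarray(trajectories, dtype=float)
    if arr.ndim != 2:
        raise ValueError("ensemble must be 2-D: replicates x time")
    specs = [power_spectrum(row) for row in arr]
    P = np.vstack([s.power for s in specs])
    R = P.shape[0]
    se = P.std(axis=0, ddof=1) / np.sqrt(R) if R > 1 else np.zeros(P.shape[1])
    return Spectrum(freqs=specs[0].freqs, power=P.mean(axis=0), se=se)
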