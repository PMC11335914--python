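"""Bayesian estimation of the hybrid race model by differential-evolution
MCMC (DE-MCMC).

The posterior is proportional to ``exp(dataset loglik + log prior)`` with
independent truncated-normal priors per parameter (failure probabilities are
estimated on the probit scale with plain normal priors). The sampler runs a
population of chains (by default three per free parameter); crossover
proposals perturb a chain by a scaled difference of two other chains,
``x' = x + gamma (x_a - x_b) + eps``, which automatically adapts to the
posterior correlation structure. During burn-in, a migration step
occasionally circulates states among a random subset of chains to merge
outlying chains; burn-in ends when the multivariate Gelman-Rubin diagnostic
drops below a threshold (1.1 by default) or an iteration cap is reached.

Hierarchical estimation alternates DE-MCMC updates of subject-level
parameters (whose prior is the truncated-normal population distribution at
the chain's current group values) and of the population location/scale
parameters (whose "likelihood" is the product of subject-parameter
densities; locations get the same truncated-normal priors, scales
Exponential(1) priors).

Chains are updated in two alternating half-populations, each using partner
states from the other half, so every likelihood evaluation is vectorized
across chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from .design import ParameterMap, build_map
from .likelihood import CompiledTrials, Trial

__all__ = [
    "TABLE_PRIORS",
    "PriorSpec",
    "HyperPriorSpec",
    "PosteriorSamples",
    "HierarchicalSamples",
    "probit",
    "probit_inverse",
    "log_prior",
    "gelman_rubin",
    "credible_interval",
    "sample_individual",
    "sample_hierarchical",
]

# Default prior setting per parameter type: (location, scale, lower, upper).
# Non-decision time is bounded to [0.1, 1] s; thresholds and rates are
# positive; stop parameters are bounded to [0, 4] s; probit-scale failure
# parameters are unbounded with a location of -2 (failure rates ~2%).
TABLE_PRIORS: dict[str, tuple[float, float, float, float]] = {
    "t0": (0.35, 0.1, 0.1, 1.0),
    "B": (1.0, 5.0, 0.0, math.inf),
    "v": (2.0, 5.0, 0.0, math.inf),
    "mu": (0.5, 1.0, 0.0, 4.0),
    "sigma": (0.1, 1.0, 0.0, 4.0),
    "tau": (0.1, 1.0, 0.0, 4.0),
    "zgf": (-2.0, 2.0, -math.inf, math.inf),
    "ztf": (-2.0, 2.0, -math.inf, math.inf),
}

_LOG_2PI = math.log(2.0 * math.pi)


def probit(p):
    """Probit transform ``ndtri(p)``: probability scale to the real line."""
    return ndtri(p)


def probit_inverse(z):
    """Inverse probit ``ndtr(z)``: real line to probability scale."""
    return ndtr(z)


@dataclass(frozen=True)
class PriorSpec:
    """Independent truncated-normal priors over the flat parameter vector."""

    loc: np.ndarray
    scale: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    log_z: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("loc", "scale", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.scale <= 0):
            raise ValueError("prior scales must be > 0")
        if np.any(self.lower >= self.upper):
            raise ValueError("prior bounds must satisfy lower < upper")
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        mass = np.clip(ndtr(b) - ndtr(a), 1e-300, 1.0)
        object.__setattr__(self, "log_z", np.log(mass))

    @property
    def n_params(self) -> int:
        return self.loc.size

    @classmethod
    def from_map(
        cls,
        pmap: ParameterMap,
        table: dict[str, tuple[float, float, float, float]] | None = None,
    ) -> "PriorSpec":
        """Expand a per-type prior table over the map's flat vector."""
        if table is None:
            table = TABLE_PRIORS
        loc, scale, lower, upper = [], [], [], []
        for label in pmap.labels():
            ptype = label.split(".")[0]
            if ptype not in table:
                raise KeyError(f"no prior setting for parameter type {ptype!r}")
            lo_, sc_, lb_, ub_ = table[ptype]
            loc.append(lo_)
            scale.append(sc_)
            lower.append(lb_)
            upper.append(ub_)
        return cls(np.array(loc), np.array(scale), np.array(lower), np.array(upper))

    def logpdf_many(self, theta: np.ndarray) -> np.ndarray:
        """Summed truncated-normal log density per row; -inf outside bounds."""
        theta = np.atleast_2d(theta)
        z = (theta - self.loc) / self.scale
        terms = -np.log(self.scale) - 0.5 * (_LOG_2PI + z * z) - self.log_z
        out = terms.sum(axis=1)
        inside = np.all((theta >= self.lower) & (theta <= self.upper), axis=1)
        return np.where(inside, out, -np.inf)

    def logpdf(self, flat: np.ndarray) -> float:
        return float(self.logpdf_many(np.asarray(flat, dtype=float)[None, :])[0])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` vectors from the prior."""
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        out = truncnorm.rvs(
            a[None, :], b[None, :], loc=self.loc, scale=self.scale,
            size=(n, self.n_params), random_state=rng,
        )
        return np.atleast_2d(out)


def log_prior(flat: np.ndarray, prior: PriorSpec) -> float:
    """Log prior density of one flat parameter vector."""
    return prior.logpdf(flat)


@dataclass(frozen=True)
class HyperPriorSpec:
    """Priors for the population-level distributions: truncated normals for
    the locations (the per-type prior table) and Exponential(rate) for the
    scales."""

    loc_prior: PriorSpec
    scale_rate: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale_rate > 0:
            raise ValueError("scale rate must be > 0")

    @classmethod
    def from_map(cls, pmap: ParameterMap, table=None, scale_rate: float = 1.0):
        return cls(PriorSpec.from_map(pmap, table), scale_rate)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Gelman-Rubin R-hat per parameter from draws (chains, iters, params).

    The between-chain variance of the chain means is compared with the mean
    within-chain variance; values near 1 indicate convergence.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[..., None]
    K, T, d = draws.shape
    if K < 2:
        raise ValueError("R-hat requires at least two chains")
    if T < 2:
        raise ValueError("R-hat requires at least two iterations per chain")
    chain_means = draws.mean(axis=1)  # (K, d)
    W = draws.var(axis=1, ddof=1).mean(axis=0)  # (d,)
    B = T * chain_means.var(axis=0, ddof=1)  # (d,)
    var_hat = (T - 1) / T * W + B / T
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(W <= 0, np.where(B <= 0, 1.0, np.inf), rhat)
    return rhat


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Central credible interval per parameter (2.5th/97.5th percentiles at
    the default level) over all chains and iterations."""
    draws = np.asarray(draws, dtype=float)
    flat = draws.reshape(-1, draws.shape[-1]) if draws.ndim > 1 else draws[:, None]
    alpha = 100.0 * (1.0 - level) / 2.0
    lo = np.percentile(flat, alpha, axis=0)
    hi = np.percentile(flat, 100.0 - alpha, axis=0)
    return lo, hi


# ---------------------------------------------------------------------------
# samples containers
# ---------------------------------------------------------------------------

def _summary_frame(draws: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    flat = draws.reshape(-1, draws.shape[-1])
    lo, hi = credible_interval(draws)
    return pd.DataFrame(
        {
            "parameter": list(labels),
            "mean": flat.mean(axis=0),
            "median": np.median(flat, axis=0),
            "q2.5": lo,
            "q97.5": hi,
            "rhat": gelman_rubin(draws),
        }
    )


@dataclass
class PosteriorSamples:
    """Retained posterior draws: (chains, iterations, parameters)."""

    draws: np.ndarray
    labels: list[str]
    thin: int
    burn_iterations: int
    converged: bool

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[1]

    def posterior_mean(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1]).mean(axis=0)

    def rhat(self) -> np.ndarray:
        return gelman_rubin(self.draws)

    def credible_interval(self, level: float = 0.95):
        return credible_interval(self.draws, level)

    def summary(self) -> pd.DataFrame:
        return _summary_frame(self.draws, self.labels)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter columns) table."""
        K, T, d = self.draws.shape
        frame = pd.DataFrame(
            self.draws.reshape(K * T, d), columns=list(self.labels)
        )
        frame.insert(0, "iteration", np.tile(np.arange(T), K))
        frame.insert(0, "chain", np.repeat(np.arange(K), T))
        return frame


@dataclass
class HierarchicalSamples:
    """Hierarchical posterior: subject draws (subjects, chains, iterations,
    parameters) plus population location/scale draws."""

    subject_draws: np.ndarray
    loc_draws: np.ndarray
    scale_draws: np.ndarray
    labels: list[str]
    subjects: list
    thin: int
    burn_iterations: int
    converged: bool

    def subject(self, s: int) -> PosteriorSamples:
        return PosteriorSamples(
            self.subject_draws[s], self.labels, self.thin,
            self.burn_iterations, self.converged,
        )

    def group_summary(self) -> pd.DataFrame:
        loc = _summary_frame(self.loc_draws, [f"loc.{l}" for l in self.labels])
        scale = _summary_frame(self.scale_draws, [f"scale.{l}" for l in self.labels])
        return pd.concat([loc, scale], ignore_index=True)


class InitializationError(RuntimeError):
    """All attempted start values had zero posterior density."""


# ---------------------------------------------------------------------------
# DE-MCMC core
# ---------------------------------------------------------------------------

def _crossover_half(
    x: np.ndarray,
    lp: np.ndarray,
    half: np.ndarray,
    other: np.ndarray,
    logpost: Callable[[np.ndarray], np.ndarray],
    gamma: float,
    rng: np.random.Generator,
) -> None:
    """In-place DE crossover update of the chains in ``half`` using partner
    states from ``other``."""
    m, mo = half.size, other.size
    r1 = rng.integers(mo, size=m)
    r2 = rng.integers(mo - 1, size=m)
    r2 = np.where(r2 >= r1, r2 + 1, r2)
    eps = rng.uniform(-1e-3, 1e-3, size=(m, x.shape[1]))
    prop = x[half] + gamma * (x[other][r1] - x[other][r2]) + eps
    lp_prop = logpost(prop)
    accept = np.log(rng.random(m)) < lp_prop - lp[half]
    x[half[accept]] = prop[accept]
    lp[half[accept]] = lp_prop[accept]


def _snooker_half(
    x: np.ndarray,
    lp: np.ndarray,
    half: np.ndarray,
    other: np.ndarray,
    logpost: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
) -> None:
    """In-place snooker update: propose along the line through the chain
    and an anchor state, with the step set by the projection of two other
    states onto that line. Effective for elongated, correlated posteriors
    where plain crossover steps mix slowly."""
    m, mo = half.size, other.size
    d = x.shape[1]
    idx = np.stack([rng.choice(mo, 3, replace=False) for _ in range(m)])
    z = x[other][idx[:, 0]]
    za = x[other][idx[:, 1]]
    zb = x[other][idx[:, 2]]
    e = x[half] - z
    norm2 = np.maximum(np.sum(e * e, axis=1), 1e-300)
    proj = np.sum((za - zb) * e, axis=1) / norm2
    gamma_s = 2.38 / math.sqrt(2.0)
    prop = x[half] + gamma_s * proj[:, None] * e
    lp_prop = logpost(prop)
    norm2_new = np.maximum(np.sum((prop - z) ** 2, axis=1), 1e-300)
    # Jacobian of the line-restricted proposal: |x' - z|^(d-1) / |x - z|^(d-1)
    corr = 0.5 * (d - 1) * (np.log(norm2_new) - np.log(norm2))
    accept = np.log(rng.random(m)) < lp_prop - lp[half] + corr
    x[half[accept]] = prop[accept]
    lp[half[accept]] = lp_prop[accept]


def _migrate(
    x: np.ndarray,
    lp: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Cyclic migration: propose each selected chain's state to the next
    chain in a random cycle, accepting by the Metropolis rule."""
    K = x.shape[0]
    k = int(rng.integers(2, K + 1))
    idx = rng.permutation(K)[:k]
    src_x = x[idx].copy()
    src_lp = lp[idx].copy()
    for i in range(k):
        j = idx[(i + 1) % k]
        if math.log(rng.random()) < src_lp[i] - lp[j]:
            x[j] = src_x[i]
            lp[j] = src_lp[i]


def _run_de_mcmc(
    logpost: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    rng: np.random.Generator,
    n_keep: int,
    thin: int,
    max_iter: int,
    burn_min: int,
    check_every: int,
    rhat_threshold: float,
    migration_prob: float,
    gamma: float | None = None,
    snooker_prob: float = 0.1,
) -> tuple[np.ndarray, int, bool]:
    """Generic DE-MCMC driver; returns (draws (K, n_keep, d), burn-in
    iterations used, converged flag).

    Each iteration updates the two half-populations with crossover moves
    (every 10th at gamma = 1 for mode jumping), replaced by a snooker move
    on a random ``snooker_prob`` of iterations; migration runs only during
    burn-in.
    """
    x = np.array(x0, dtype=float)
    K, d = x.shape
    if K < 4:
        raise ValueError("the half-population crossover scheme needs >= 4 chains")
    lp = logpost(x)
    if not np.any(np.isfinite(lp)):
        raise InitializationError("all start values have zero posterior density")
    if gamma is None:
        gamma = 2.38 / math.sqrt(2.0 * d)
    halves = (np.arange(0, K // 2), np.arange(K // 2, K))

    def sweep(it: int) -> None:
        use_snooker = rng.random() < snooker_prob
        g = 1.0 if it % 10 == 9 else gamma
        for half, other in (halves, halves[::-1]):
            if use_snooker:
                _snooker_half(x, lp, half, other, logpost, rng)
            else:
                _crossover_half(x, lp, half, other, logpost, g, rng)

    history: list[np.ndarray] = []
    hist_thin = 5
    it = 0
    converged = False
    while it < max_iter:
        it += 1
        if migration_prob > 0 and rng.random() < migration_prob:
            _migrate(x, lp, rng)
        else:
            sweep(it)
        if it % hist_thin == 0:
            history.append(x.copy())
        if it >= burn_min and it % check_every == 0 and len(history) >= 4:
            recent = np.stack(history[len(history) // 2 :], axis=1)  # (K, T, d)
            if recent.shape[1] >= 2:
                rhat = gelman_rubin(recent)
                if np.all(rhat < rhat_threshold):
                    converged = True
                    break
    burn_used = it

    draws = np.empty((K, n_keep, d))
    for t in range(n_keep):
        for _ in range(thin):
            it += 1
            sweep(it)
        draws[:, t, :] = x
    return draws, burn_used, converged


def _heuristic_start(
    trials: Sequence[Trial], pmap: ParameterMap, prior: PriorSpec
) -> np.ndarray:
    """Rough data-driven parameter vector from RT summaries.

    Non-decision time from the fastest response, rates from threshold /
    mean decision time (matching accumulators faster than mismatching),
    go-failure rate from the observed go-omission rate, and generic
    stopping values. Used only to anchor the mode search.
    """
    rts = [t.rt for t in trials if t.rt is not None]
    go = [t for t in trials if not t.is_stop]
    omit = sum(1 for t in go if t.response is None) / max(len(go), 1)
    min_rt = min(rts) if rts else 0.4
    mean_rt = float(np.mean(rts)) if rts else 0.7
    t0_h = 0.85 * min_rt
    dt = max(mean_rt - t0_h, 0.15)
    b_h = 1.8
    v_hi = b_h / dt + 0.5
    v_lo = max(v_hi - 1.8, 0.5)
    defaults = {
        "t0": t0_h,
        "B": b_h,
        "mu": 0.2,
        "sigma": 0.05,
        "tau": 0.08,
        "zgf": float(ndtri(min(max(omit, 0.003), 0.3))),
        "ztf": -1.5,
    }
    out = np.empty(pmap.n_params)
    for j, label in enumerate(pmap.labels()):
        parts = label.split(".")
        if parts[0] == "v":
            out[j] = v_lo if "False" in parts[1:] else v_hi
        else:
            out[j] = defaults.get(parts[0], 1.0)
    eps = 1e-9
    return np.clip(out, prior.lower + eps, np.minimum(prior.upper - eps, 1e12))


def _map_start(
    prior: PriorSpec,
    logpost: Callable[[np.ndarray], np.ndarray],
    n_chains: int,
    rng: np.random.Generator,
    anchors: Sequence[np.ndarray] = (),
    n_explore: int = 256,
    maxfev: int = 1500,
    support_floor: np.ndarray | None = None,
) -> np.ndarray:
    """Start values clustered on a posterior-mode estimate.

    The posterior is probed with prior draws; the best draw and any
    supplied anchor vectors are polished with Nelder-Mead and the best
    polished point wins. Chains start from a Laplace (finite-difference
    Hessian) approximation around it, so the population carries the
    posterior's correlation structure from the first iteration. This
    avoids the local mode with non-decision time pinned at its lower
    bound that can trap population samplers started from dispersed prior
    draws.
    """
    from scipy.optimize import minimize

    d = prior.n_params
    draws = prior.sample(n_explore, rng)
    lp = logpost(draws)
    best_draw = draws[int(np.argmax(lp))]
    # the data-driven anchor almost always lands in the right basin; the
    # best prior draw is the fallback when no anchor is supplied or the
    # anchor search fails
    starts = list(anchors) if anchors else [best_draw]

    def neg(x: np.ndarray) -> float:
        val = logpost(x[None])[0]
        return 1e12 if not np.isfinite(val) else -val

    def neg_and_grad(x: np.ndarray):
        # batched central-difference gradient through the vectorized
        # posterior: one (2d+1)-row evaluation per gradient
        h = np.maximum(1e-5 * np.abs(x), 1e-6)
        pts = np.vstack([x, x + np.diag(h), x - np.diag(h)])
        vals = logpost(pts)
        if not np.isfinite(vals[0]):
            return 1e12, np.zeros(d)
        with np.errstate(invalid="ignore"):
            g = (vals[1 : 1 + d] - vals[1 + d :]) / (2.0 * h)
        return -vals[0], -np.where(np.isfinite(g), g, 0.0)

    eps = 1e-6
    lb = np.where(np.isfinite(prior.lower), prior.lower + eps, -1e6)
    if support_floor is not None:
        lb = np.maximum(lb, support_floor)
    ub = np.where(np.isfinite(prior.upper), prior.upper - eps, 1e6)

    # Nelder-Mead locates the basin (gradient steps can jump from a rough
    # start into the local mode with t0 at its bound); a bounded
    # quasi-Newton polish then sharpens the mode estimate cheaply.
    best_x, best_val = None, np.inf
    for x_start in starts:
        res = minimize(
            neg, x_start, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-3, "adaptive": True},
        )
        if res.fun < best_val:
            best_x, best_val = res.x, res.fun
    if best_val >= 1e11 and anchors:  # anchor search failed outright
        res = minimize(
            neg, best_draw, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-3, "adaptive": True},
        )
        best_x, best_val = res.x, res.fun
    polish = minimize(
        neg_and_grad, np.clip(best_x, lb, ub), jac=True, method="L-BFGS-B",
        bounds=list(zip(lb, ub)), options={"maxiter": 35},
    )
    x_map = polish.x if polish.fun < best_val else best_x
    cov = _laplace_cov(logpost, x_map, prior)
    chol = np.linalg.cholesky(cov)
    eps = 1e-9
    hi_clip = np.minimum(prior.upper - eps, 1e12)

    def draw(n: int, scale: float) -> np.ndarray:
        z = rng.standard_normal((n, x_map.size))
        return np.clip(x_map + scale * z @ chol.T, prior.lower + eps, hi_clip)

    x0 = draw(n_chains, 1.0)
    lp0 = logpost(x0)
    for _ in range(100):
        bad = ~np.isfinite(lp0)
        if not bad.any():
            return x0
        n_bad = int(bad.sum())
        x0[bad] = draw(n_bad, 0.3)
        lp0[bad] = logpost(x0[bad])
    raise InitializationError("could not jitter mode-centered start values")


def _laplace_cov(
    logpost: Callable[[np.ndarray], np.ndarray],
    x_map: np.ndarray,
    prior: PriorSpec,
) -> np.ndarray:
    """Covariance of the Laplace (normal) approximation at a mode estimate.

    Central finite differences of the log posterior give the negative
    Hessian; all evaluation points are batched through the vectorized
    posterior. Non-positive curvature directions (e.g. a mode estimate
    near a prior bound) are clipped to keep the covariance positive
    definite, with the per-parameter prior scale as a fallback ceiling.
    """
    d = x_map.size
    h = np.maximum(1e-3 * np.abs(x_map), 1e-4)
    # keep symmetric stencils inside the prior support
    room = np.minimum(x_map - prior.lower, prior.upper - x_map) / 2.1
    h = np.where(np.isfinite(room) & (room > 0), np.minimum(h, room), h)
    points = [x_map]
    for i in range(d):
        for sgn in (+1, -1):
            x = x_map.copy()
            x[i] += sgn * h[i]
            points.append(x)
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    for i, j in pairs:
        for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            x = x_map.copy()
            x[i] += si * h[i]
            x[j] += sj * h[j]
            points.append(x)
    values = logpost(np.asarray(points))
    f0 = values[0]
    fplus = values[1 : 2 * d + 1 : 2]
    fminus = values[2 : 2 * d + 1 : 2]
    H = np.zeros((d, d))
    H[np.diag_indices(d)] = (fplus - 2 * f0 + fminus) / h**2
    off = values[2 * d + 1 :].reshape(-1, 4)
    for (i, j), (fpp, fpm, fmp, fmm) in zip(pairs, off):
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    H = np.where(np.isfinite(H), H, 0.0)
    neg_h = -0.5 * (H + H.T)
    w, v = np.linalg.eigh(neg_h)
    w_floor = max(w.max(), 1.0) * 1e-8
    w = np.maximum(w, w_floor)
    cov = (v / w) @ v.T
    # Cap marginal start scales tightly: DE proposals scale with the
    # population spread, so a population much wider than the posterior
    # rejects everything and cannot shrink, while a narrow one grows
    # geometrically. Flat curvature directions therefore fall back to a
    # modest scale rather than the prior's.
    cap = np.maximum(0.05 * np.abs(x_map), 0.02) ** 2
    diag = np.diag(cov)
    shrink = np.sqrt(np.minimum(1.0, cap / np.maximum(diag, 1e-300)))
    return cov * np.outer(shrink, shrink)


def _init_from_prior(
    prior: PriorSpec,
    loglik: Callable[[np.ndarray], np.ndarray],
    n_chains: int,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> np.ndarray:
    x = prior.sample(n_chains, rng)
    ll = loglik(x)
    for _ in range(max_tries):
        bad = ~np.isfinite(ll)
        if not bad.any():
            return x
        x[bad] = prior.sample(int(bad.sum()), rng)
        ll[bad] = loglik(x[bad])
    raise InitializationError(
        "could not find start values with finite likelihood for all chains"
    )


# ---------------------------------------------------------------------------
# public samplers
# ---------------------------------------------------------------------------

def _as_trials(trials) -> list[Trial]:
    if isinstance(trials, pd.DataFrame):
        from .simulate import trials_from_table

        return trials_from_table(trials)
    return list(trials)


def sample_individual(
    trials,
    pmap: ParameterMap | None = None,
    prior: PriorSpec | None = None,
    n_chains: int | None = None,
    thin: int = 5,
    n_keep: int = 250,
    max_iter: int = 5000,
    burn_min: int = 200,
    check_every: int = 50,
    rhat_threshold: float = 1.1,
    migration_prob: float = 0.05,
    gl_nodes: int = 16,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    init: np.ndarray | str = "map",
) -> PosteriorSamples:
    """Fit one participant's data by DE-MCMC.

    ``n_chains`` defaults to three times the number of free parameters;
    draws are thinned (every 5th kept by default) and ``n_keep`` draws per
    chain are retained after burn-in. ``init`` selects start values:
    ``"map"`` (default) clusters chains on a Nelder-Mead posterior-mode
    estimate, ``"prior"`` draws each chain from the prior, or pass an
    explicit (n_chains, n_params) array. Deterministic given the seed.
    """
    if pmap is None:
        pmap = build_map()
    if prior is None:
        prior = PriorSpec.from_map(pmap)
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_chains is None:
        n_chains = 3 * pmap.n_params
    if n_chains < pmap.n_params + 2:
        raise ValueError("n_chains must be at least n_params + 2 for crossover")

    compiled = CompiledTrials(_as_trials(trials), pmap, gl_nodes=gl_nodes)

    def logpost(theta: np.ndarray) -> np.ndarray:
        lp = prior.logpdf_many(theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if ok.any():
            out[ok] = lp[ok] + compiled.loglik_many(theta[ok])
        return out

    if isinstance(init, str):
        if init == "map":
            anchor = _heuristic_start(_as_trials(trials), pmap, prior)
            floor = np.full(pmap.n_params, -np.inf)
            for ptype, sl in pmap.type_slices().items():
                if ptype in ("sigma", "tau"):
                    floor[sl] = 10.0 * compiled.scale_floor
            x0 = _map_start(
                prior, logpost, n_chains, rng, anchors=[anchor],
                support_floor=floor,
            )
        elif init == "prior":
            x0 = _init_from_prior(prior, lambda t: logpost(t), n_chains, rng)
        else:
            raise ValueError(f"unknown init mode {init!r}")
    else:
        x0 = np.array(init, dtype=float)
        if x0.shape != (n_chains, pmap.n_params):
            raise ValueError("init must have shape (n_chains, n_params)")

    draws, burn_used, converged = _run_de_mcmc(
        logpost, x0, rng, n_keep=n_keep, thin=thin, max_iter=max_iter,
        burn_min=burn_min, check_every=check_every,
        rhat_threshold=rhat_threshold, migration_prob=migration_prob,
    )
    return PosteriorSamples(draws, pmap.labels(), thin, burn_used, converged)


def _tn_logpdf_sum(x, loc, scale, lower, upper):
    """Summed truncated-normal log density of subject parameters ``x``
    (..., d) under population values ``loc``/``scale`` (..., d)."""
    z = (x - loc) / scale
    a = (lower - loc) / scale
    b = (upper - loc) / scale
    mass = np.clip(ndtr(b) - ndtr(a), 1e-300, None)
    terms = -np.log(scale) - 0.5 * (_LOG_2PI + z * z) - np.log(mass)
    terms = np.where((x >= lower) & (x <= upper), terms, -np.inf)
    return terms.sum(axis=-1)


def sample_hierarchical(
    trials_by_subject,
    pmap: ParameterMap | None = None,
    hyper: HyperPriorSpec | None = None,
    n_chains: int | None = None,
    thin: int = 5,
    n_keep: int = 250,
    max_iter: int = 3000,
    burn_min: int = 200,
    check_every: int = 50,
    rhat_threshold: float = 1.1,
    migration_prob: float = 0.05,
    gl_nodes: int = 16,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    init_subjects: np.ndarray | str = "map",
) -> HierarchicalSamples:
    """Hierarchical DE-MCMC over several participants.

    Each iteration alternates crossover updates of every subject's parameter
    block (prior: truncated normal at the chain's current population values)
    with an update of the population location/scale block (likelihood:
    product of subject-parameter densities; priors per
    :class:`HyperPriorSpec`). Subject start values may be supplied (e.g.
    posterior draws from individual fits) as an array (subjects, chains,
    params); population starts derive from their across-subject mean/SD.
    """
    if isinstance(trials_by_subject, dict):
        subjects = list(trials_by_subject)
        trial_lists = [trials_by_subject[s] for s in subjects]
    else:
        trial_lists = list(trials_by_subject)
        subjects = list(range(len(trial_lists)))
    S = len(trial_lists)
    if S < 1:
        raise ValueError("at least one subject is required")
    if pmap is None:
        pmap = build_map()
    if hyper is None:
        hyper = HyperPriorSpec.from_map(pmap)
    if rng is None:
        rng = np.random.default_rng(seed)
    d = pmap.n_params
    if n_chains is None:
        n_chains = 3 * d
    K = n_chains
    lower, upper = hyper.loc_prior.lower, hyper.loc_prior.upper

    compiled = [CompiledTrials(_as_trials(t), pmap, gl_nodes=gl_nodes) for t in trial_lists]

    # --- initialization ---------------------------------------------------
    if isinstance(init_subjects, str):
        xs = np.empty((S, K, d))
        trial_cache = [_as_trials(t) for t in trial_lists]
        for s in range(S):
            if init_subjects == "map":
                prior_s = hyper.loc_prior

                def logpost_s(th, _c=compiled[s]):
                    lp = prior_s.logpdf_many(th)
                    out = np.full(th.shape[0], -np.inf)
                    ok = np.isfinite(lp)
                    if ok.any():
                        out[ok] = lp[ok] + _c.loglik_many(th[ok])
                    return out

                anchor = _heuristic_start(trial_cache[s], pmap, prior_s)
                floor = np.full(d, -np.inf)
                for ptype, sl in pmap.type_slices().items():
                    if ptype in ("sigma", "tau"):
                        floor[sl] = 10.0 * compiled[s].scale_floor
                xs[s] = _map_start(
                    prior_s, logpost_s, K, rng, anchors=[anchor],
                    maxfev=800, support_floor=floor,
                )
            elif init_subjects == "prior":
                xs[s] = _init_from_prior(
                    hyper.loc_prior, compiled[s].loglik_many, K, rng
                )
            else:
                raise ValueError(f"unknown init mode {init_subjects!r}")
    else:
        xs = np.array(init_subjects, dtype=float)
        if xs.shape != (S, K, d):
            raise ValueError("init_subjects must have shape (subjects, chains, params)")
    loc = xs.mean(axis=0) + 0.01 * rng.standard_normal((K, d))
    loc = np.clip(loc, lower + 1e-6, np.minimum(upper - 1e-6, 1e6))
    scale = np.maximum(xs.std(axis=0), 0.01) * rng.uniform(0.8, 1.2, size=(K, d))

    # ll_subj caches the data likelihood (independent of the group state);
    # lp_subj = ll_subj + population-prior term
    ll_subj = np.stack([compiled[s].loglik_many(xs[s]) for s in range(S)])  # (S, K)
    lp_subj = ll_subj + np.stack(
        [_tn_logpdf_sum(xs[s], loc, scale, lower, upper) for s in range(S)]
    )

    def group_logpost(loc_, scale_, xs_):
        """Log posterior of the group block given subject params (..., K')."""
        out = hyper.loc_prior.logpdf_many(loc_)
        bad = np.any(scale_ <= 0, axis=-1)
        lp = np.where(bad, -np.inf, out)
        ok = ~bad & np.isfinite(lp)
        if ok.any():
            prior_scale = -hyper.scale_rate * scale_[ok].sum(axis=-1)
            tn = sum(
                _tn_logpdf_sum(xs_[s][ok], loc_[ok], scale_[ok], lower, upper)
                for s in range(S)
            )
            lp[ok] = lp[ok] + prior_scale + tn
        return lp

    lp_group = group_logpost(loc, scale, xs)
    gamma_s = 2.38 / math.sqrt(2.0 * d)
    gamma_g = 2.38 / math.sqrt(2.0 * 2 * d)
    halves = (np.arange(0, K // 2), np.arange(K // 2, K))

    def subject_step(s: int) -> None:
        for half, other in (halves, halves[::-1]):
            m, mo = half.size, other.size
            r1 = rng.integers(mo, size=m)
            r2 = rng.integers(mo - 1, size=m)
            r2 = np.where(r2 >= r1, r2 + 1, r2)
            prop = (
                xs[s][half]
                + gamma_s * (xs[s][other][r1] - xs[s][other][r2])
                + rng.uniform(-1e-3, 1e-3, size=(m, d))
            )
            lp_prior = _tn_logpdf_sum(prop, loc[half], scale[half], lower, upper)
            ll_prop = np.full(m, -np.inf)
            ok = np.isfinite(lp_prior)
            if ok.any():
                ll_prop[ok] = compiled[s].loglik_many(prop[ok])
            lp_prop = lp_prior + ll_prop
            accept = np.log(rng.random(m)) < lp_prop - lp_subj[s][half]
            idx = half[accept]
            xs[s][idx] = prop[accept]
            lp_subj[s][idx] = lp_prop[accept]
            ll_subj[s][idx] = ll_prop[accept]

    def group_step() -> None:
        nonlocal lp_group
        joint = np.concatenate([loc, scale], axis=1)  # (K, 2d)
        for half, other in (halves, halves[::-1]):
            m, mo = half.size, other.size
            r1 = rng.integers(mo, size=m)
            r2 = rng.integers(mo - 1, size=m)
            r2 = np.where(r2 >= r1, r2 + 1, r2)
            prop = (
                joint[half]
                + gamma_g * (joint[other][r1] - joint[other][r2])
                + rng.uniform(-1e-3, 1e-3, size=(m, 2 * d))
            )
            loc_p, scale_p = prop[:, :d], prop[:, d:]
            xs_half = xs[:, half, :]
            lp_prop = group_logpost(loc_p, scale_p, xs_half)
            accept = np.log(rng.random(m)) < lp_prop - lp_group[half]
            idx = half[accept]
            loc[idx] = loc_p[accept]
            scale[idx] = scale_p[accept]
            lp_group[idx] = lp_prop[accept]
            joint[half[accept]] = prop[accept]
        # the subject-block posteriors change with the group state; the
        # cached data likelihoods do not
        for s in range(S):
            lp_subj[s] = ll_subj[s] + _tn_logpdf_sum(xs[s], loc, scale, lower, upper)

    def migrate_super() -> None:
        k = int(rng.integers(2, K + 1))
        idx = rng.permutation(K)[:k]
        total = lp_group[idx] + lp_subj[:, idx].sum(axis=0)
        src_xs = xs[:, idx, :].copy()
        src_loc = loc[idx].copy()
        src_scale = scale[idx].copy()
        src_total = total.copy()
        src_lp_subj = lp_subj[:, idx].copy()
        src_ll_subj = ll_subj[:, idx].copy()
        src_lp_group = lp_group[idx].copy()
        for i in range(k):
            j = idx[(i + 1) % k]
            cur_total = lp_group[j] + lp_subj[:, j].sum(axis=0)
            if math.log(rng.random()) < src_total[i] - cur_total:
                xs[:, j, :] = src_xs[:, i, :]
                loc[j] = src_loc[i]
                scale[j] = src_scale[i]
                lp_subj[:, j] = src_lp_subj[:, i]
                ll_subj[:, j] = src_ll_subj[:, i]
                lp_group[j] = src_lp_group[i]

    history: list[np.ndarray] = []
    hist_thin = 5
    it = 0
    converged = False
    while it < max_iter:
        it += 1
        if rng.random() < migration_prob:
            migrate_super()
        else:
            for s in range(S):
                subject_step(s)
            group_step()
        if it % hist_thin == 0:
            history.append(np.concatenate([loc, scale], axis=1).copy())
        if it >= burn_min and it % check_every == 0 and len(history) >= 4:
            recent = np.stack(history[len(history) // 2 :], axis=1)
            if recent.shape[1] >= 2 and np.all(gelman_rubin(recent) < rhat_threshold):
                converged = True
                break
    burn_used = it

    subj_draws = np.empty((S, K, n_keep, d))
    loc_draws = np.empty((K, n_keep, d))
    scale_draws = np.empty((K, n_keep, d))
    for t in range(n_keep):
        for _ in range(thin):
            for s in range(S):
                subject_step(s)
            group_step()
        subj_draws[:, :, t, :] = xs
        loc_draws[:, t, :] = loc
        scale_draws[:, t, :] = scale
    return HierarchicalSamples(
        subj_draws, loc_draws, scale_draws, pmap.labels(), subjects,
        thin, burn_used, converged,
    )
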