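"""Goodness-of-fit machinery and the parameter-recovery harness.

Posterior predictive checks simulate replicate datasets from parameter
vectors drawn jointly from the posterior, holding the observed SSDs and the
observed number of go and stop trials per design cell fixed, and compare
observed and predicted summaries: defective-CDF percentiles per response
(the CDF asymptote is the response probability), the inhibition function
(probability of responding on stop trials by SSD), and median
signal-respond RT by SSD, with SSDs grouped into equal-count bins.

The recovery harness simulates datasets from known parameter vectors, fits
each individually, and summarizes recovery by the correlation between true
and (replicate-averaged) estimated values, the coverage of the 95% credible
intervals, and bias, alongside bimodality diagnostics of the sampling
distribution of the posterior means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .design import ParameterMap, build_map
from .inference import PosteriorSamples, credible_interval, sample_individual
from .simulate import make_schedule, simulate_dataset

__all__ = [
    "posterior_predict",
    "defective_cdf_percentiles",
    "inhibition_function",
    "srrt_by_ssd",
    "BimodalityFlag",
    "bimodality_flag",
    "RecoveryReport",
    "recovery_run",
]

PERCENTILES = (10, 30, 50, 70, 90)

# Reduced-MCMC settings for desk-scale recovery studies: minimum viable
# chain count (free parameters + 2), a mode-initialized population, a
# capped burn-in and a long thinned collection window. Full-scale studies
# should raise max_iter and n_keep.
SCALED_RECOVERY_SETTINGS: dict = {
    "n_chains": 24,
    "thin": 6,
    "n_keep": 100,
    "burn_min": 300,
    "max_iter": 350,
    "check_every": 50,
    "rhat_threshold": 1.1,
    "gl_nodes": 12,
}

# linear interpolation of the empirical CDF at p = k/n (R type 4), so the
# 10th percentile of {0.01..1.00} is exactly 0.10
_PCTL_METHOD = "interpolated_inverted_cdf"


def posterior_predict(
    table: pd.DataFrame,
    samples: PosteriorSamples,
    pmap: ParameterMap | None = None,
    n_draws: int = 100,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    deadline: float = 2.0,
) -> list[pd.DataFrame]:
    """Simulate ``n_draws`` posterior predictive replicates of an observed
    trial table.

    Parameter vectors are drawn jointly (whole rows of the retained chains,
    not independent marginals). Each replicate reuses the observed SSDs
    (the staircase is disabled) and the observed per-cell trial counts.
    """
    if pmap is None:
        pmap = build_map()
    if rng is None:
        rng = np.random.default_rng(seed)
    K, T, d = samples.draws.shape
    if K * T < n_draws:
        raise ValueError(
            f"only {K * T} retained draws available for {n_draws} predictive draws"
        )
    chain = rng.integers(K, size=n_draws)
    it = rng.integers(T, size=n_draws)
    vectors = samples.draws[chain, it, :]

    schedule = table[
        ["session", "block", "trial", "block_type", "bias", "difficulty", "stimulus"]
    ].copy()
    schedule["is_stop"] = (table["trial_type"] == "stop").to_numpy()
    observed_ssd = table.loc[table["trial_type"] == "stop", "ssd"].to_numpy(float)

    reps = []
    for v in vectors:
        reps.append(
            simulate_dataset(
                schedule, v, pmap, deadline=deadline, rng=rng, fixed_ssd=observed_ssd
            )
        )
    return reps


def defective_cdf_percentiles(
    rts: np.ndarray,
    responses: np.ndarray,
    probs: tuple[int, ...] = PERCENTILES,
) -> pd.DataFrame:
    """Percentiles of each response's RT distribution together with the
    response proportion (the defective-CDF asymptote).

    Proportions are taken over all trials including omissions, so they sum
    to at most 1; responses with no observations are absent from the table.
    """
    responses = np.asarray(responses, dtype=object)
    rts = np.asarray(rts, dtype=float)
    n = len(responses)
    if n == 0:
        raise ValueError("empty trial set")
    rows = []
    for resp in pd.unique(responses):
        if resp in ("none", None) or (isinstance(resp, float) and math.isnan(resp)):
            continue
        sel = rts[(responses == resp) & np.isfinite(rts)]
        if sel.size == 0:
            continue
        row = {"response": resp, "proportion": sel.size / n}
        for p in probs:
            row[f"p{p}"] = float(np.percentile(sel, p, method=_PCTL_METHOD))
        rows.append(row)
    return pd.DataFrame(rows)


def _equal_count_bins(ssd: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    """Assign SSDs to ``n_bins`` equal-count bins (counts differ by at most
    one when ties permit); reduces the bin count with a warning when there
    are fewer observations than bins."""
    n = ssd.size
    if n == 0:
        raise ValueError("no stop trials to bin")
    if n < n_bins:
        warnings.warn(
            f"only {n} stop trials for {n_bins} SSD bins; reducing to {n}",
            stacklevel=3,
        )
        n_bins = n
    order = np.argsort(ssd, kind="stable")
    assignment = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        assignment[chunk] = b
    return assignment, n_bins


def inhibition_function(
    ssd: np.ndarray, responded: np.ndarray, n_bins: int = 5
) -> pd.DataFrame:
    """Probability of responding on stop trials per equal-count SSD bin.

    SSD bins are unevenly spaced so that approximately the same number of
    stop trials contributes to each bin.
    """
    ssd = np.asarray(ssd, dtype=float)
    responded = np.asarray(responded, dtype=bool)
    assignment, n_bins = _equal_count_bins(ssd, n_bins)
    rows = []
    for b in range(n_bins):
        sel = assignment == b
        rows.append(
            {
                "bin": b,
                "mean_ssd": float(ssd[sel].mean()),
                "n": int(sel.sum()),
                "p_respond": float(responded[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


def srrt_by_ssd(
    ssd: np.ndarray, rt: np.ndarray, n_bins: int = 5
) -> pd.DataFrame:
    """Median signal-respond RT per equal-count SSD bin (same binning as
    :func:`inhibition_function`, over all supplied stop trials). Bins with
    no responded trials are absent from the output."""
    ssd = np.asarray(ssd, dtype=float)
    rt = np.asarray(rt, dtype=float)
    assignment, n_bins = _equal_count_bins(ssd, n_bins)
    rows = []
    for b in range(n_bins):
        sel = (assignment == b) & np.isfinite(rt)
        if not sel.any():
            continue
        rows.append(
            {
                "bin": b,
                "mean_ssd": float(ssd[assignment == b].mean()),
                "n_respond": int(sel.sum()),
                "median_srrt": float(np.median(rt[sel])),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bimodality diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BimodalityFlag:
    """Result of the mode diagnostic for one parameter's draws."""

    bimodal: bool
    n_modes: int
    mode_locations: tuple[float, ...]
    boundary_pileup: bool
    bandwidth: float


def bimodality_flag(
    draws: np.ndarray,
    min_mass: float = 0.10,
    min_prominence: float = 0.2,
    bounds: tuple[float, float] | None = None,
    grid_size: int = 512,
) -> BimodalityFlag:
    """Kernel-density mode count with mass and prominence thresholds.

    A Gaussian KDE with Silverman bandwidth is evaluated on a grid; local
    maxima delimit basins. Adjacent maxima whose separating density dip is
    shallow (above ``1 - min_prominence`` of the smaller peak) are merged —
    they reflect sampling roughness, not separated modes — and a mode must
    carry at least ``min_mass`` of the sample to count. Additionally flags
    mass piling against a supplied prior bound (either at least ``min_mass``
    within one bandwidth of it, or a density mode within two bandwidths).
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 5:
        raise ValueError("too few draws for a mode diagnostic")
    sd = draws.std(ddof=1)
    if not np.isfinite(sd) or sd <= 1e-12 * (1.0 + abs(float(draws.mean()))):
        return BimodalityFlag(False, 1, (float(draws[0]),), False, 0.0)
    kde = gaussian_kde(draws, bw_method="silverman")
    bw = sd * kde.factor
    lo, hi = draws.min() - bw, draws.max() + bw
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    # local maxima of the density on the grid
    rising = dens[1:] > dens[:-1]
    maxima = list(np.where(~rising[1:] & rising[:-1])[0] + 1)
    if dens[0] > dens[1]:
        maxima = [0] + maxima
    if dens[-1] > dens[-2]:
        maxima = maxima + [grid_size - 1]
    if not maxima:
        maxima = [int(np.argmax(dens))]
    # merge adjacent maxima separated by shallow dips
    while len(maxima) > 1:
        ratios = []
        for i in range(len(maxima) - 1):
            seg = dens[maxima[i] : maxima[i + 1] + 1]
            dip = seg.min()
            ratios.append(dip / max(min(dens[maxima[i]], dens[maxima[i + 1]]), 1e-300))
        worst = int(np.argmax(ratios))
        if ratios[worst] <= 1.0 - min_prominence:
            break
        drop = worst if dens[maxima[worst]] < dens[maxima[worst + 1]] else worst + 1
        del maxima[drop]
    if len(maxima) <= 1:
        modes = [float(grid[maxima[0]])]
        n_modes = 1
    else:
        boundaries = [
            grid[m + int(np.argmin(dens[m : maxima[i + 1] + 1]))]
            for i, m in enumerate(maxima[:-1])
        ]
        edges = np.concatenate([[lo], boundaries, [hi]])
        masses = np.histogram(draws, bins=edges)[0] / draws.size
        keep = masses >= min_mass
        modes = [float(grid[m]) for m, k in zip(maxima, keep) if k]
        n_modes = int(keep.sum())
        if n_modes == 0:  # pathological flat density
            modes, n_modes = [float(grid[np.argmax(dens)])], 1
    pileup = False
    if bounds is not None:
        for bound in bounds:
            if not np.isfinite(bound):
                continue
            # mass stacked against the bound, or a density mode within two
            # bandwidths of it
            frac = np.mean(np.abs(draws - bound) <= bw)
            near_mode = any(abs(m - bound) <= 2 * bw for m in modes)
            if frac >= min_mass or near_mode:
                pileup = True
    return BimodalityFlag(n_modes >= 2, n_modes, tuple(modes), pileup, float(bw))


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Recovery-study results.

    ``means``, ``ci_low``, ``ci_high`` have shape (truth sets, replicates,
    parameters); failed fits are recorded in ``failures`` and hold NaN.
    """

    truths: np.ndarray
    means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    labels: list[str]
    failures: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def averaged_means(self) -> np.ndarray:
        """Posterior means averaged over replicates: (truth sets, params)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.means, axis=1)

    def _types(self) -> dict[str, np.ndarray]:
        types: dict[str, list[int]] = {}
        for j, label in enumerate(self.labels):
            types.setdefault(label.split(".")[0], []).append(j)
        return {t: np.array(idx) for t, idx in types.items()}

    def correlation_by_type(self) -> dict[str, float]:
        """Pearson correlation between true values and replicate-averaged
        posterior means, pooling a type's parameters across truth sets (as
        in combining all thresholds into one panel)."""
        avg = self.averaged_means
        out = {}
        for t, idx in self._types().items():
            x = self.truths[:, idx].ravel()
            y = avg[:, idx].ravel()
            ok = np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0:
                out[t] = float("nan")
            else:
                out[t] = float(np.corrcoef(x[ok], y[ok])[0, 1])
        return out

    def coverage(self) -> np.ndarray:
        """Fraction of replicates whose 95% credible interval contains the
        truth, per (truth set, parameter)."""
        inside = (self.ci_low <= self.truths[:, None, :]) & (
            self.truths[:, None, :] <= self.ci_high
        )
        valid = np.isfinite(self.means)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.where(valid, inside, np.nan).astype(float).mean(
                axis=1, where=valid
            )

    def coverage_by_type(self) -> dict[str, float]:
        cov = self.coverage()
        return {
            t: float(np.nanmean(cov[:, idx])) for t, idx in self._types().items()
        }

    def bias(self) -> np.ndarray:
        """Averaged posterior mean minus truth, per (truth set, parameter)."""
        return self.averaged_means - self.truths

    def bimodality_flags(self, min_mass: float = 0.10):
        """Mode diagnostic of the sampling distribution of the posterior
        mean (across replicates) per (truth set, parameter)."""
        n_sets, _, d = self.means.shape
        flags = np.empty((n_sets, d), dtype=object)
        for s in range(n_sets):
            for j in range(d):
                draws = self.means[s, :, j]
                draws = draws[np.isfinite(draws)]
                flags[s, j] = (
                    bimodality_flag(draws, min_mass=min_mass)
                    if draws.size >= 5
                    else None
                )
        return flags

    def summary(self) -> pd.DataFrame:
        corr = self.correlation_by_type()
        cov = self.coverage_by_type()
        return pd.DataFrame(
            {
                "type": list(corr),
                "correlation": [corr[t] for t in corr],
                "coverage": [cov[t] for t in corr],
            }
        )


def recovery_run(
    truths: np.ndarray,
    pmap: ParameterMap | None = None,
    n_replicates: int = 200,
    schedule_kwargs: dict | None = None,
    fit_kwargs: dict | None = None,
    seed: int | None = None,
    deadline: float = 2.0,
) -> RecoveryReport:
    """Simulate ``n_replicates`` staircase datasets per truth vector, fit
    each individually with prior-drawn start values, and collect posterior
    means and 95% credible intervals. Fully seeded; fit failures are
    recorded per replicate rather than fatal."""
    if pmap is None:
        pmap = build_map()
    truths = np.atleast_2d(np.asarray(truths, dtype=float))
    n_sets, d = truths.shape
    if d != pmap.n_params:
        raise ValueError("truth vectors do not match the parameter map")
    schedule_kwargs = dict(schedule_kwargs or {})
    fit_kwargs = dict(fit_kwargs or {})
    root = np.random.SeedSequence(seed)
    means = np.full((n_sets, n_replicates, d), np.nan)
    ci_low = np.full((n_sets, n_replicates, d), np.nan)
    ci_high = np.full((n_sets, n_replicates, d), np.nan)
    failures: list[tuple[int, int, str]] = []
    for s in range(n_sets):
        for r in range(n_replicates):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            schedule = make_schedule(rng=rng, **schedule_kwargs)
            data = simulate_dataset(schedule, truths[s], pmap, deadline=deadline, rng=rng)
            try:
                fit = sample_individual(data, pmap, rng=rng, **fit_kwargs)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                failures.append((s, r, repr(exc)))
                continue
            means[s, r] = fit.posterior_mean()
            lo, hi = fit.credible_interval()
            ci_low[s, r] = lo
            ci_high[s, r] = hi
    return RecoveryReport(truths, means, ci_low, ci_high, pmap.labels(), failures)
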