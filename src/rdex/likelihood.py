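"""Trial-level likelihoods of the hybrid race model with attention failures.

The model is an independent race. On go trials two Wald accumulators race;
the observed response is the winner and its RT the winning time plus
non-decision time. With probability ``pgf`` (go failure) the go runners are
never launched and the trial is an omission. On stop trials a truncated
ex-Gaussian stop runner joins the race at the stop-signal delay (SSD); with
probability ``ptf`` (trigger failure) it is never launched. A response on a
stop trial (signal-respond) occurs when the winning go runner beats the stop
runner; a successful inhibition when the stop runner wins or the go runners
were never launched.

Clock convention: RT and SSD are measured from go-stimulus onset; the stop
runner's finishing time is measured from stop-signal onset, so its survival
on the go clock is evaluated at ``t - SSD`` and the inhibition integral runs
over the stop clock.

Two evaluation paths are provided: scalar reference operations built on
:mod:`rdex.distributions` (adaptive quadrature for the inhibition integral),
and :class:`CompiledTrials`, which pre-indexes a dataset against a
:class:`~rdex.design.ParameterMap` and evaluates the joint log-likelihood
for many parameter vectors at once (fixed-order Gauss-Legendre quadrature),
the workhorse of the MCMC sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.special import log_ndtr, ndtr

from ._kernels import HAVE_NUMBA as _HAVE_NUMBA
from .design import AccumulatorRole, DesignCell, ParameterMap
from .distributions import (
    DEFAULT_STOP_LOWER,
    GoRunnerParams,
    StopRunnerParams,
    trunc_exg_density,
    trunc_exg_survival,
    wald_density,
    wald_survival,
)

__all__ = [
    "Trial",
    "NumericFailureError",
    "go_response_density",
    "go_omission_probability",
    "signal_respond_density",
    "inhibition_probability",
    "respond_probability",
    "dataset_loglik",
    "CompiledTrials",
    "stop_upper_effective",
]

RESPONSES = ("blue", "orange")


class NumericFailureError(ArithmeticError):
    """Raised when a likelihood evaluation fails numerically."""


@dataclass(frozen=True)
class Trial:
    """One stop-signal trial: design cell, trial type, SSD, response, RT."""

    cell: DesignCell
    is_stop: bool = False
    ssd: float | None = None
    response: str | None = None
    rt: float | None = None

    def __post_init__(self) -> None:
        if not self.is_stop and self.ssd is not None:
            raise ValueError("go trials carry no SSD")
        if self.is_stop and self.ssd is None:
            raise ValueError("stop trials require an SSD")
        if self.response is None and self.rt is not None:
            raise ValueError("a trial without a response carries no RT")
        if self.response is not None:
            if self.response not in RESPONSES:
                raise ValueError(f"invalid response {self.response!r}")
            if self.rt is None or not self.rt > 0:
                raise ValueError("a responded trial requires rt > 0")


def stop_upper_effective(stop: StopRunnerParams) -> float:
    """Practical upper integration limit when the truncation upper bound is
    infinite: ``mu + 10 sigma + 20 tau`` covers the ex-Gaussian tail to well
    below quadrature tolerance."""
    if math.isfinite(stop.upper):
        return stop.upper
    return stop.mu + 10.0 * stop.sigma + 20.0 * stop.tau


def go_response_density(
    rt: float, winner: GoRunnerParams, loser: GoRunnerParams, pgf: float
) -> float:
    """Defective density of the observed response at time ``rt`` on a go
    trial: ``(1 - pgf) f_winner(rt - t0_w) S_loser(rt - t0_l)``.

    Zero when ``rt <= t0_winner``; the loser's survival is 1 before its own
    non-decision time. The go-failure mass ``pgf`` is carried by the
    omission outcome, so outcome probabilities sum to one.
    """
    if not rt > 0:
        raise ValueError("rt must be > 0")
    td_w = rt - winner.t0
    if td_w <= 0:
        return 0.0
    f_w = wald_density(td_w, winner.v, winner.b)
    s_l = wald_survival(rt - loser.t0, loser.v, loser.b)
    return (1.0 - pgf) * f_w * s_l


def go_omission_probability(pgf: float) -> float:
    """Probability of a go omission: the go-failure probability."""
    return pgf


def signal_respond_density(
    rt: float,
    ssd: float,
    winner: GoRunnerParams,
    loser: GoRunnerParams,
    stop: StopRunnerParams,
    pgf: float,
    ptf: float,
) -> float:
    """Defective density of a response at ``rt`` on a failed stop trial:
    the trigger-failure mixture of the plain go race and the go race that
    additionally beats the stop runner (evaluated on the stop clock at
    ``rt - ssd``)."""
    if not rt > 0:
        raise ValueError("rt must be > 0")
    if ssd < 0:
        raise ValueError("ssd must be >= 0")
    td_w = rt - winner.t0
    if td_w <= 0:
        return 0.0
    f_w = wald_density(td_w, winner.v, winner.b)
    s_l = wald_survival(rt - loser.t0, loser.v, loser.b)
    s_stop = trunc_exg_survival(rt - ssd, stop)
    return (1.0 - pgf) * f_w * s_l * (ptf + (1.0 - ptf) * s_stop)


def inhibition_probability(
    ssd: float,
    go_i: GoRunnerParams,
    go_j: GoRunnerParams,
    stop: StopRunnerParams,
    pgf: float,
    ptf: float,
) -> float:
    """Probability of a successful inhibition at the given SSD:
    ``pgf + (1 - pgf)(1 - ptf) * Int f_stop(s) S_i(s + ssd - t0_i)
    S_j(s + ssd - t0_j) ds`` over the stop runner's support, with ``s`` on
    the stop clock. Adaptive quadrature to relative tolerance 1e-6."""
    if ssd < 0:
        raise ValueError("ssd must be >= 0")
    lo = stop.lower if math.isfinite(stop.lower) else stop.mu - 40 * stop.sigma
    hi = stop_upper_effective(stop)

    def integrand(s: float) -> float:
        val = trunc_exg_density(s, stop)
        if val == 0.0:
            return 0.0
        val *= wald_survival(s + ssd - go_i.t0, go_i.v, go_i.b)
        val *= wald_survival(s + ssd - go_j.t0, go_j.v, go_j.b)
        return val

    integral, err = quad(integrand, lo, hi, epsrel=1e-6, epsabs=1e-12, limit=200)
    if not np.isfinite(integral) or (integral > 1e-8 and err > 1e-3 * integral):
        raise NumericFailureError(
            f"inhibition integral did not converge: value={integral}, "
            f"error={err}, ssd={ssd}, stop={stop}"
        )
    return pgf + (1.0 - pgf) * (1.0 - ptf) * min(max(integral, 0.0), 1.0)


def respond_probability(
    ssd: float,
    go_i: GoRunnerParams,
    go_j: GoRunnerParams,
    stop: StopRunnerParams,
    pgf: float,
    ptf: float,
) -> float:
    """Probability of responding on a stop trial (inhibition-function
    value): the complement of :func:`inhibition_probability`."""
    return 1.0 - inhibition_probability(ssd, go_i, go_j, stop, pgf, ptf)


def _other_response(response: str) -> str:
    return RESPONSES[1 - RESPONSES.index(response)]


def dataset_loglik(
    trials: Iterable[Trial],
    flat: np.ndarray,
    pmap: ParameterMap,
    stop_lower: float = DEFAULT_STOP_LOWER,
    stop_upper: float = math.inf,
) -> float:
    """Joint log-likelihood (nats) of a trial collection, summing log
    defective densities for responses, log omission probabilities for go
    omissions, and log inhibition probabilities for successful stops.

    Reference per-trial loop; use :class:`CompiledTrials` for repeated
    evaluation. Returns ``-inf`` only when some trial has likelihood zero;
    raises :class:`NumericFailureError` identifying the trial on NaN.
    """
    total = 0.0
    for k, trial in enumerate(trials):
        cell = trial.cell
        mix = pmap.mixture_params(flat, cell)
        if trial.response is not None:
            w_role = AccumulatorRole(trial.response)
            l_role = AccumulatorRole(_other_response(trial.response))
            winner = pmap.go_params(flat, cell, w_role)
            loser = pmap.go_params(flat, cell, l_role)
            if trial.is_stop:
                stop = pmap.stop_params(flat, cell, lower=stop_lower, upper=stop_upper)
                lik = signal_respond_density(
                    trial.rt, trial.ssd, winner, loser, stop, mix.pgf, mix.ptf
                )
            else:
                lik = go_response_density(trial.rt, winner, loser, mix.pgf)
        elif trial.is_stop:
            stop = pmap.stop_params(flat, cell, lower=stop_lower, upper=stop_upper)
            go_i = pmap.go_params(flat, cell, AccumulatorRole("blue"))
            go_j = pmap.go_params(flat, cell, AccumulatorRole("orange"))
            lik = inhibition_probability(trial.ssd, go_i, go_j, stop, mix.pgf, mix.ptf)
        else:
            lik = go_omission_probability(mix.pgf)
        if math.isnan(lik):
            raise NumericFailureError(f"NaN likelihood at trial {k}: {trial}")
        with np.errstate(divide="ignore"):
            total += float(np.log(lik))
    return total


# ---------------------------------------------------------------------------
# compiled, vectorized path
# ---------------------------------------------------------------------------

def _wald_logpdf_raw(t, v, b):
    """Wald log density; assumes v, b > 0; -inf where t <= 0."""
    tp = np.where(t > 0, t, 1.0)
    out = np.log(b) - 0.5 * (math.log(2 * math.pi) + 3 * np.log(tp)) - (v * tp - b) ** 2 / (2 * tp)
    return np.where(t > 0, out, -np.inf)


def _wald_sf_raw(t, v, b):
    """Wald survival; assumes v, b > 0; 1 where t <= 0.

    The second CDF term carries an exp(2bv) factor; for 2bv < 500 the
    direct product is exact and cheap (where ndtr underflows, the term is
    provably negligible against the first), otherwise the term is assembled
    in log space.
    """
    tp = np.where(t > 0, t, 1.0)
    rt_ = np.sqrt(tp)
    z1 = (v * tp - b) / rt_
    z2 = (v * tp + b) / rt_
    bv2 = 2.0 * b * v
    term1 = ndtr(-z1)
    if np.any(bv2 >= 500.0):
        term2 = np.exp(np.broadcast_to(bv2, z2.shape) + log_ndtr(-z2))
    else:
        term2 = np.exp(bv2) * ndtr(-z2)
    out = np.clip(term1 - term2, 0.0, 1.0)
    return np.where(t > 0, out, 1.0)


def _exg_logpdf_raw(t, mu, sigma, tau):
    z = (t - mu) / sigma
    return -np.log(tau) + (mu - t) / tau + sigma**2 / (2 * tau**2) + log_ndtr(z - sigma / tau)


def _exg_cdf_raw(t, mu, sigma, tau):
    z = (t - mu) / sigma
    log_term = sigma**2 / (2 * tau**2) - (t - mu) / tau + log_ndtr(z - sigma / tau)
    return np.clip(ndtr(z) - np.exp(log_term), 0.0, 1.0)


_GO_IDX_FIELDS = ("v_w", "B_w", "t0_w", "v_l", "B_l", "t0_l")


class CompiledTrials:
    """A dataset pre-indexed against a :class:`ParameterMap` for fast joint
    log-likelihood evaluation across many parameter vectors.

    Trials are split into four outcome groups (go responses, go omissions,
    signal-respond, successful inhibitions); each group stores flat-vector
    index arrays. Successful inhibitions are deduplicated to unique
    (parameter-indices, SSD) rows with counts, and their integrals are
    computed with ``gl_nodes``-point Gauss-Legendre quadrature on
    ``[lower, mu + 10 sigma + 20 tau]`` per parameter vector.
    """

    def __init__(
        self,
        trials: Sequence[Trial],
        pmap: ParameterMap,
        stop_lower: float = DEFAULT_STOP_LOWER,
        stop_upper: float = math.inf,
        gl_nodes: int = 16,
        use_numba: bool = True,
    ) -> None:
        self.pmap = pmap
        self.n_params = pmap.n_params
        self.stop_lower = float(stop_lower)
        self.stop_upper = float(stop_upper)
        self.n_trials = len(trials)
        # quadrature panels (Gaussian bump + segmented exponential tail);
        # see _stop_nodes
        self._gl_a = np.polynomial.legendre.leggauss(max(6, gl_nodes))
        self._gl_b = np.polynomial.legendre.leggauss(max(4, gl_nodes // 2))

        resp_rows: list[list[float]] = []  # go responses
        sr_rows: list[list[float]] = []  # signal-respond
        omit_idx: list[int] = []  # go omissions -> zgf index
        inhib_rows: list[list[float]] = []

        def go_indices(cell: DesignCell, resp: str) -> list[int]:
            w = AccumulatorRole(resp)
            l = AccumulatorRole(_other_response(resp))
            return [
                pmap.index("v", cell, w),
                pmap.index("B", cell, w),
                pmap.index("t0", cell, w),
                pmap.index("v", cell, l),
                pmap.index("B", cell, l),
                pmap.index("t0", cell, l),
            ]

        def stop_indices(cell: DesignCell) -> list[int]:
            return [
                pmap.index("mu", cell),
                pmap.index("sigma", cell),
                pmap.index("tau", cell),
            ]

        for trial in trials:
            cell = trial.cell
            izgf = pmap.index("zgf", cell)
            if trial.response is not None:
                gi = go_indices(cell, trial.response)
                if trial.is_stop:
                    iztf = pmap.index("ztf", cell)
                    sr_rows.append(
                        gi + stop_indices(cell) + [izgf, iztf, trial.ssd, trial.rt]
                    )
                else:
                    resp_rows.append(gi + [izgf, trial.rt])
            elif trial.is_stop:
                gi = go_indices(cell, "blue")  # both runners, order immaterial
                iztf = pmap.index("ztf", cell)
                inhib_rows.append(gi + stop_indices(cell) + [izgf, iztf, trial.ssd])
            else:
                omit_idx.append(izgf)

        # numerical validity floor: the ex-Gaussian evaluations are stable
        # for sigma, tau >= 1e-4; vectors below it get zero likelihood
        # (posterior mass there is negligible for any realistic dataset,
        # and a tau -> 0 stop runner is a degenerate model)
        self.scale_floor = 1e-4
        scale_idx: list[int] = []
        for ptype, sl in pmap.type_slices().items():
            if ptype in ("sigma", "tau"):
                scale_idx.extend(range(sl.start, sl.stop))
        self._scale_idx = np.asarray(sorted(set(scale_idx)), dtype=int)

        self._resp = np.asarray(resp_rows, dtype=float).reshape(-1, 8)
        self._sr = np.asarray(sr_rows, dtype=float).reshape(-1, 13)
        self._omit_idx, self._omit_counts = (
            np.unique(np.asarray(omit_idx, dtype=int), return_counts=True)
            if omit_idx
            else (np.empty(0, dtype=int), np.empty(0, dtype=int))
        )
        inhib = np.asarray(inhib_rows, dtype=float).reshape(-1, 12)
        if inhib.size:
            # deduplicate identical (indices, ssd) rows; SSDs live on a
            # 0.05 s staircase grid so exact ties are common
            uniq, counts = np.unique(np.round(inhib, 9), axis=0, return_counts=True)
            self._inhib = uniq
            self._inhib_counts = counts.astype(float)
            self._stop_groups, g_of_r = np.unique(
                uniq[:, 6:9].astype(np.int64), axis=0, return_inverse=True
            )
            self._g_of_r = np.asarray(g_of_r, dtype=np.int64).ravel()
        else:
            self._inhib = inhib
            self._inhib_counts = np.empty(0)
            self._stop_groups = np.zeros((0, 3), dtype=np.int64)
            self._g_of_r = np.zeros(0, dtype=np.int64)
        self._use_numba = bool(use_numba and _HAVE_NUMBA)

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _gather(theta: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return theta[:, idx.astype(int)]

    def _go_race_loglik(self, theta: np.ndarray, rows: np.ndarray, rt: np.ndarray):
        """log f_winner + log S_loser for each (vector, trial)."""
        v_w = self._gather(theta, rows[:, 0])
        b_w = self._gather(theta, rows[:, 1])
        t0_w = self._gather(theta, rows[:, 2])
        v_l = self._gather(theta, rows[:, 3])
        b_l = self._gather(theta, rows[:, 4])
        t0_l = self._gather(theta, rows[:, 5])
        logf = _wald_logpdf_raw(rt[None, :] - t0_w, v_w, b_w)
        s_l = _wald_sf_raw(rt[None, :] - t0_l, v_l, b_l)
        with np.errstate(divide="ignore"):
            return logf + np.log(s_l)

    def loglik_many(self, theta: np.ndarray) -> np.ndarray:
        """Joint log-likelihood for each row of ``theta`` (shape (K, d)).

        Assumes every row satisfies the parameter-support constraints
        (positive rates, thresholds, scales); the sampler guarantees this by
        rejecting out-of-support proposals through the prior.
        """
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if theta.shape[1] != self.n_params:
            raise ValueError("theta width does not match the parameter map")
        if self._use_numba:
            return self._loglik_many_numba(theta)
        K = theta.shape[0]
        if self._scale_idx.size:
            bad = np.any(theta[:, self._scale_idx] < self.scale_floor, axis=1)
            if bad.any():
                out = np.full(K, -np.inf)
                ok = ~bad
                if ok.any():
                    out[ok] = self.loglik_many(theta[ok])
                return out
        total = np.zeros(K)

        with np.errstate(divide="ignore", invalid="ignore"):
            # go responses
            if self._resp.size:
                rows = self._resp
                rt = rows[:, 7]
                ll = self._go_race_loglik(theta, rows[:, :6], rt)
                pgf = ndtr(self._gather(theta, rows[:, 6]))
                total += np.sum(ll + np.log1p(-pgf), axis=1)
            # go omissions
            if self._omit_idx.size:
                pgf = ndtr(theta[:, self._omit_idx])
                total += np.log(pgf) @ self._omit_counts
            # signal-respond
            if self._sr.size:
                rows = self._sr
                ssd, rt = rows[:, 11], rows[:, 12]
                ll = self._go_race_loglik(theta, rows[:, :6], rt)
                mu = self._gather(theta, rows[:, 6])
                sig = self._gather(theta, rows[:, 7])
                tau = self._gather(theta, rows[:, 8])
                pgf = ndtr(self._gather(theta, rows[:, 9]))
                ptf = ndtr(self._gather(theta, rows[:, 10]))
                s_stop = self._trunc_sf(rt[None, :] - ssd[None, :], mu, sig, tau)
                total += np.sum(
                    ll + np.log1p(-pgf) + np.log(ptf + (1.0 - ptf) * s_stop), axis=1
                )
            # successful inhibitions
            if self._inhib.size:
                rows = self._inhib
                p_inhib = self._inhibition_many(theta, rows)
                total += np.log(p_inhib) @ self._inhib_counts

        return np.where(np.isnan(total), -np.inf, total)

    def _trunc_mass(self, mu, sig, tau):
        fl = _exg_cdf_raw(self.stop_lower, mu, sig, tau)
        if math.isfinite(self.stop_upper):
            fu = _exg_cdf_raw(self.stop_upper, mu, sig, tau)
        else:
            fu = 1.0
        return fl, fu

    def _trunc_sf(self, t, mu, sig, tau):
        """Truncated ex-Gaussian survival, vectorized; 1 below the lower
        bound."""
        fl, fu = self._trunc_mass(mu, sig, tau)
        mass = np.maximum(fu - fl, 1e-300)
        ft = _exg_cdf_raw(np.maximum(t, self.stop_lower), mu, sig, tau)
        out = np.clip((fu - ft) / mass, 0.0, 1.0)
        return np.where(t <= self.stop_lower, 1.0, out)

    def _stop_nodes(self, mu, sig, tau):
        """Quadrature nodes and weights over the stop runner's support.

        The ex-Gaussian density has a Gaussian bump near ``mu`` and an
        exponential tail of scale ``tau``; a single Gauss-Legendre rule over
        the whole support under-resolves whichever feature is narrow. A
        Gauss-Legendre panel covers the bump on ``[mu - 6 sigma, mu + 6
        sigma]`` (clipped to the truncation interval; the mass below is
        < 1e-9), and the tail is segmented at ``c + {1, 3, 7} tau`` with
        each segment integrated in ``u = 1 - exp(-(s - s0)/tau)``, an
        exactly exponential change of variables that also keeps the go
        runners' survival drop-off resolved. The overall truncation point
        ``mu + 10 sigma + 20 tau`` leaves ~e^-20 of the tail mass.
        """
        lo = self.stop_lower
        if math.isfinite(self.stop_upper):
            hi = np.full_like(mu, self.stop_upper)
        else:
            hi = mu + 10.0 * sig + 20.0 * tau
        c = np.clip(mu + 6.0 * sig, lo, hi)
        a0 = np.clip(mu - 6.0 * sig, lo, hi)
        x_a, w_a = self._gl_a
        x_b, w_b = self._gl_b
        half_a = 0.5 * (c - a0)
        nodes = [a0[..., None] + half_a[..., None] * (x_a + 1.0)]
        weights = [half_a[..., None] * w_a]
        edges = [c, np.minimum(c + tau, hi), np.minimum(c + 3 * tau, hi),
                 np.minimum(c + 7 * tau, hi), hi]
        for s0, s1 in zip(edges[:-1], edges[1:]):
            u_max = -np.expm1(-(s1 - s0) / tau)
            half_b = 0.5 * u_max
            u = np.clip(half_b[..., None] * (x_b + 1.0), 0.0, 1.0 - 1e-12)
            nodes.append(s0[..., None] - tau[..., None] * np.log1p(-u))
            weights.append(half_b[..., None] * w_b * tau[..., None] / (1.0 - u))
        return np.concatenate(nodes, axis=-1), np.concatenate(weights, axis=-1)

    def _inhibition_many(self, theta: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """P(successful inhibition) for each (vector, unique stop row).

        Quadrature nodes and the stop density at them depend only on the
        stop-parameter indices, which are shared across rows (one group in
        the default parametrization), so they are computed per group and
        gathered per row; only the go survivals are evaluated per row.
        """
        pgf = ndtr(self._gather(theta, rows[:, 9]))
        ptf = ndtr(self._gather(theta, rows[:, 10]))
        ssd = rows[:, 11][None, :]

        stop_groups, g_of_r = self._stop_groups, self._g_of_r
        mu = theta[:, stop_groups[:, 0]]  # (K, G)
        sig = theta[:, stop_groups[:, 1]]
        tau = theta[:, stop_groups[:, 2]]
        s, w = self._stop_nodes(mu, sig, tau)  # (K, G, M)

        fl, fu = self._trunc_mass(mu, sig, tau)
        mass = np.maximum(fu - fl, 1e-300)
        mu_, sig_, tau_ = mu[..., None], sig[..., None], tau[..., None]
        expo = (mu_ - s) / tau_ + sig_**2 / (2.0 * tau_**2)
        arg = (s - mu_) / sig_ - sig_ / tau_
        if np.any(expo >= 600.0) or np.any(arg <= -30.0):
            f_stop = np.exp(expo + log_ndtr(arg)) / tau_
        else:
            f_stop = np.exp(expo) * ndtr(arg) / tau_
        wf = w * f_stop / mass[..., None]  # (K, G, M)

        # per-row go-clock times of the stop-runner finish
        t_go = s[:, g_of_r, :] + ssd[..., None]  # (K, R, M)
        s_i = _wald_sf_raw(
            t_go - self._gather(theta, rows[:, 2])[..., None],
            self._gather(theta, rows[:, 0])[..., None],
            self._gather(theta, rows[:, 1])[..., None],
        )
        s_j = _wald_sf_raw(
            t_go - self._gather(theta, rows[:, 5])[..., None],
            self._gather(theta, rows[:, 3])[..., None],
            self._gather(theta, rows[:, 4])[..., None],
        )
        integral = np.clip(
            np.sum(wf[:, g_of_r, :] * s_i * s_j, axis=-1), 0.0, 1.0
        )
        return pgf + (1.0 - pgf) * (1.0 - ptf) * integral

    def _numba_args(self) -> tuple:
        try:
            return self._nb_args
        except AttributeError:
            pass
        empty_i = np.zeros(0, dtype=np.int64)
        empty_f = np.zeros(0)
        resp = self._resp
        sr = self._sr
        inhib = self._inhib
        self._nb_args = (
            resp[:, :7].astype(np.int64) if resp.size else np.zeros((0, 7), np.int64),
            resp[:, 7].copy() if resp.size else empty_f,
            self._omit_idx.astype(np.int64),
            self._omit_counts.astype(float),
            sr[:, :11].astype(np.int64) if sr.size else np.zeros((0, 11), np.int64),
            sr[:, 11].copy() if sr.size else empty_f,
            sr[:, 12].copy() if sr.size else empty_f,
            inhib[:, :11].astype(np.int64) if inhib.size else np.zeros((0, 11), np.int64),
            inhib[:, 11].copy() if inhib.size else empty_f,
            self._inhib_counts.astype(float),
            self._g_of_r,
            self._stop_groups,
            self._gl_a[0], self._gl_a[1], self._gl_b[0], self._gl_b[1],
            float(self.stop_lower), float(self.stop_upper),
            self._scale_idx.astype(np.int64) if self._scale_idx.size else empty_i,
            float(self.scale_floor),
        )
        return self._nb_args

    def _loglik_many_numba(self, theta: np.ndarray) -> np.ndarray:
        from ._kernels import loglik_many_kernel

        return loglik_many_kernel(np.ascontiguousarray(theta), *self._numba_args())

    def loglik(self, flat: np.ndarray) -> float:
        """Joint log-likelihood of a single parameter vector."""
        return float(self.loglik_many(np.asarray(flat, dtype=float)[None, :])[0])
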