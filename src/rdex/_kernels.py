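"""Numba-accelerated joint log-likelihood kernel.

Mirrors the vectorized numpy path in :mod:`rdex.likelihood` exactly (same
quadrature panels, same stability switches); :class:`CompiledTrials`
dispatches here when numba is importable. The two paths agree to ~1e-10 and
are cross-checked in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba as nb

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

_SQRT1_2 = 0.7071067811865476
_LOG_2PI = 1.8378770664093453
_LOG_SQRT_2PI = 0.9189385332046727

if HAVE_NUMBA:

    @nb.njit(inline="always", cache=False)
    def _ndtr(x):
        return 0.5 * math.erfc(-x * _SQRT1_2)

    @nb.njit(inline="always", cache=False)
    def _log_ndtr(x):
        if x > -20.0:
            return math.log(0.5 * math.erfc(-x * _SQRT1_2))
        # asymptotic expansion of the normal tail for x << 0
        xx = x * x
        return (
            -0.5 * xx
            - math.log(-x)
            - _LOG_SQRT_2PI
            + math.log1p(-1.0 / xx + 3.0 / (xx * xx) - 15.0 / (xx * xx * xx))
        )

    @nb.njit(inline="always", cache=False)
    def _wald_logpdf(t, v, b):
        if t <= 0.0:
            return -np.inf
        return (
            math.log(b)
            - 0.5 * (_LOG_2PI + 3.0 * math.log(t))
            - (v * t - b) ** 2 / (2.0 * t)
        )

    @nb.njit(inline="always", cache=False)
    def _wald_sf(t, v, b):
        if t <= 0.0:
            return 1.0
        st = math.sqrt(t)
        z2 = (v * t + b) / st
        bv2 = 2.0 * b * v
        term1 = _ndtr(-(v * t - b) / st)
        if bv2 < 500.0:
            term2 = math.exp(bv2) * _ndtr(-z2)
        else:
            term2 = math.exp(bv2 + _log_ndtr(-z2))
        s = term1 - term2
        if s < 0.0:
            return 0.0
        if s > 1.0:
            return 1.0
        return s

    @nb.njit(inline="always", cache=False)
    def _exg_cdf(t, mu, sig, tau):
        z = (t - mu) / sig
        lt = sig * sig / (2.0 * tau * tau) - (t - mu) / tau + _log_ndtr(z - sig / tau)
        val = _ndtr(z) - math.exp(lt)
        if val < 0.0:
            return 0.0
        if val > 1.0:
            return 1.0
        return val

    @nb.njit(inline="always", cache=False)
    def _exg_pdf(t, mu, sig, tau):
        expo = (mu - t) / tau + sig * sig / (2.0 * tau * tau)
        arg = (t - mu) / sig - sig / tau
        if expo < 600.0 and arg > -30.0:
            return math.exp(expo) * _ndtr(arg) / tau
        return math.exp(expo + _log_ndtr(arg)) / tau

    @nb.njit(cache=False)
    def loglik_many_kernel(
        theta,
        resp_idx,      # (Nr, 7) int64: v_w B_w t0_w v_l B_l t0_l zgf
        resp_rt,       # (Nr,)
        omit_idx,      # (No,) int64 zgf indices
        omit_counts,   # (No,)
        sr_idx,        # (Ns, 11) int64: go(6) mu sig tau zgf ztf
        sr_ssd,        # (Ns,)
        sr_rt,         # (Ns,)
        in_idx,        # (Ni, 11) int64 as sr
        in_ssd,        # (Ni,)
        in_counts,     # (Ni,)
        g_of_r,        # (Ni,) int64 -> stop group
        stop_groups,   # (G, 3) int64: mu sig tau indices
        glx_a, glw_a, glx_b, glw_b,
        stop_lower, stop_upper,
        scale_idx, scale_floor,
    ):
        K = theta.shape[0]
        out = np.zeros(K)
        Ma = glx_a.size
        Mb = glx_b.size
        M = Ma + 4 * Mb
        G = stop_groups.shape[0]
        s_all = np.empty((G, M))
        wf_all = np.empty((G, M))
        upper_finite = math.isfinite(stop_upper)

        for k in range(K):
            th = theta[k]
            bad = False
            for i in range(scale_idx.size):
                if th[scale_idx[i]] < scale_floor:
                    bad = True
            if bad:
                out[k] = -np.inf
                continue
            tot = 0.0

            # go responses
            for r in range(resp_idx.shape[0]):
                rt = resp_rt[r]
                lf = _wald_logpdf(
                    rt - th[resp_idx[r, 2]], th[resp_idx[r, 0]], th[resp_idx[r, 1]]
                )
                sl = _wald_sf(
                    rt - th[resp_idx[r, 5]], th[resp_idx[r, 3]], th[resp_idx[r, 4]]
                )
                pgf = _ndtr(th[resp_idx[r, 6]])
                if sl <= 0.0 or pgf >= 1.0 or lf == -np.inf:
                    tot = -np.inf
                    break
                tot += lf + math.log(sl) + math.log1p(-pgf)

            # go omissions
            if tot > -np.inf:
                for r in range(omit_idx.size):
                    pgf = _ndtr(th[omit_idx[r]])
                    if pgf <= 0.0:
                        tot = -np.inf
                        break
                    tot += omit_counts[r] * math.log(pgf)

            # signal-respond trials
            if tot > -np.inf:
                for r in range(sr_idx.shape[0]):
                    rt = sr_rt[r]
                    lf = _wald_logpdf(
                        rt - th[sr_idx[r, 2]], th[sr_idx[r, 0]], th[sr_idx[r, 1]]
                    )
                    sl = _wald_sf(
                        rt - th[sr_idx[r, 5]], th[sr_idx[r, 3]], th[sr_idx[r, 4]]
                    )
                    mu = th[sr_idx[r, 6]]
                    sig = th[sr_idx[r, 7]]
                    tau = th[sr_idx[r, 8]]
                    pgf = _ndtr(th[sr_idx[r, 9]])
                    ptf = _ndtr(th[sr_idx[r, 10]])
                    t_stop = rt - sr_ssd[r]
                    if t_stop <= stop_lower:
                        s_stop = 1.0
                    elif upper_finite and t_stop >= stop_upper:
                        s_stop = 0.0
                    else:
                        fl = _exg_cdf(stop_lower, mu, sig, tau)
                        fu = _exg_cdf(stop_upper, mu, sig, tau) if upper_finite else 1.0
                        mass = fu - fl
                        if mass < 1e-300:
                            mass = 1e-300
                        s_stop = (fu - _exg_cdf(t_stop, mu, sig, tau)) / mass
                        if s_stop < 0.0:
                            s_stop = 0.0
                        elif s_stop > 1.0:
                            s_stop = 1.0
                    mix = ptf + (1.0 - ptf) * s_stop
                    if sl <= 0.0 or mix <= 0.0 or pgf >= 1.0 or lf == -np.inf:
                        tot = -np.inf
                        break
                    tot += lf + math.log(sl) + math.log1p(-pgf) + math.log(mix)

            # successful inhibitions: nodes and weighted stop density per
            # stop-parameter group, survivals per unique (indices, ssd) row
            if tot > -np.inf and in_idx.shape[0] > 0:
                for g in range(G):
                    mu = th[stop_groups[g, 0]]
                    sig = th[stop_groups[g, 1]]
                    tau = th[stop_groups[g, 2]]
                    lo = stop_lower
                    hi = stop_upper if upper_finite else mu + 10.0 * sig + 20.0 * tau
                    fl = _exg_cdf(lo, mu, sig, tau)
                    fu = _exg_cdf(hi, mu, sig, tau) if upper_finite else 1.0
                    mass = fu - fl
                    if mass < 1e-300:
                        mass = 1e-300
                    c = mu + 6.0 * sig
                    if c < lo:
                        c = lo
                    elif c > hi:
                        c = hi
                    a0 = mu - 6.0 * sig
                    if a0 < lo:
                        a0 = lo
                    elif a0 > hi:
                        a0 = hi
                    half_a = 0.5 * (c - a0)
                    for m in range(Ma):
                        s = a0 + half_a * (glx_a[m] + 1.0)
                        s_all[g, m] = s
                        wf_all[g, m] = half_a * glw_a[m] * _exg_pdf(s, mu, sig, tau) / mass
                    pos = Ma
                    e_prev = c
                    for seg in range(4):
                        if seg == 0:
                            e_next = c + tau
                        elif seg == 1:
                            e_next = c + 3.0 * tau
                        elif seg == 2:
                            e_next = c + 7.0 * tau
                        else:
                            e_next = hi
                        if e_next > hi:
                            e_next = hi
                        u_max = -math.expm1(-(e_next - e_prev) / tau)
                        half_b = 0.5 * u_max
                        for m in range(Mb):
                            u = half_b * (glx_b[m] + 1.0)
                            if u < 0.0:
                                u = 0.0
                            elif u > 1.0 - 1e-12:
                                u = 1.0 - 1e-12
                            s = e_prev - tau * math.log1p(-u)
                            s_all[g, pos] = s
                            wf_all[g, pos] = (
                                half_b * glw_b[m] * tau / (1.0 - u)
                                * _exg_pdf(s, mu, sig, tau) / mass
                            )
                            pos += 1
                        e_prev = e_next

                for r in range(in_idx.shape[0]):
                    g = g_of_r[r]
                    ssd = in_ssd[r]
                    v_i = th[in_idx[r, 0]]
                    b_i = th[in_idx[r, 1]]
                    t0_i = th[in_idx[r, 2]]
                    v_j = th[in_idx[r, 3]]
                    b_j = th[in_idx[r, 4]]
                    t0_j = th[in_idx[r, 5]]
                    pgf = _ndtr(th[in_idx[r, 9]])
                    ptf = _ndtr(th[in_idx[r, 10]])
                    # hoist the exp(2bv) factors out of the node loop; the
                    # rare 2bv >= 500 case falls back to the log-space form
                    bv_i = 2.0 * b_i * v_i
                    bv_j = 2.0 * b_j * v_j
                    plain = bv_i < 500.0 and bv_j < 500.0
                    acc = 0.0
                    if plain:
                        e_i = math.exp(bv_i)
                        e_j = math.exp(bv_j)
                        for m in range(M):
                            t_go = s_all[g, m] + ssd
                            t_i = t_go - t0_i
                            if t_i <= 0.0:
                                s_i = 1.0
                            else:
                                st = math.sqrt(t_i)
                                z2 = (v_i * t_i + b_i) / st
                                s_i = _ndtr(-(v_i * t_i - b_i) / st)
                                if z2 < 37.0:  # else ndtr(-z2) underflows
                                    s_i -= e_i * _ndtr(-z2)
                                    if s_i < 0.0:
                                        s_i = 0.0
                            t_j = t_go - t0_j
                            if t_j <= 0.0:
                                s_j = 1.0
                            else:
                                st = math.sqrt(t_j)
                                z2 = (v_j * t_j + b_j) / st
                                s_j = _ndtr(-(v_j * t_j - b_j) / st)
                                if z2 < 37.0:
                                    s_j -= e_j * _ndtr(-z2)
                                    if s_j < 0.0:
                                        s_j = 0.0
                            acc += wf_all[g, m] * s_i * s_j
                    else:
                        for m in range(M):
                            t_go = s_all[g, m] + ssd
                            acc += (
                                wf_all[g, m]
                                * _wald_sf(t_go - t0_i, v_i, b_i)
                                * _wald_sf(t_go - t0_j, v_j, b_j)
                            )
                    if acc < 0.0:
                        acc = 0.0
                    elif acc > 1.0:
                        acc = 1.0
                    p = pgf + (1.0 - pgf) * (1.0 - ptf) * acc
                    if p <= 0.0:
                        tot = -np.inf
                        break
                    tot += in_counts[r] * math.log(p)

            out[k] = tot if not math.isnan(tot) else -np.inf
        return out
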