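"""Numba kernels for the hot loops: the compound Poisson-gamma series
normaliser, the recursive mean propagation of the standard model, and the
fused likelihood-tilt evaluations used inside the sampler.

The series follows Dunn & Smyth's evaluation of the Tweedie density for
1 < p < 2: the density factorises as

    f(y) = c(y; phi, p) * exp{(y*theta - kappa(theta)) / phi},

where the mean enters only through the exponential tilt.  ``logc_array``
computes log c (the series part), which the sampler caches across all
updates that move the mean but not (phi, p).
"""

import math

import numba
import numpy as np

# Series summand j at log scale is j*base - lgamma(j+1) - lgamma(j*a) with
# a = (2-p)/(p-1); it peaks near jmax = y^(2-p)/(phi*(2-p)) and is
# log-concave in j, so expanding from the peak until terms fall below
# max*1e-15 bounds the dropped tail far inside 1e-12 of the retained sum.
_LOG_TINY = math.log(1e-15)


@numba.njit(cache=True)
def logc_array(y, logy, phi, p, out):
    """log of the mu-free series factor c(y; phi, p); 0 where y == 0.

    Returns False if any cell failed to converge (never observed in
    practice; guarded for the error contract).
    """
    a = (2.0 - p) / (p - 1.0)
    c0 = -a * math.log(p - 1.0) - (1.0 + a) * math.log(phi) - math.log(2.0 - p)
    # shared factorial / gamma tables over the union of j-ranges
    jmax_all = 1
    coef = math.exp(-math.log(phi * (2.0 - p)))
    for i in range(y.shape[0]):
        if y[i] > 0.0:
            jm = int(y[i] ** (2.0 - p) * coef)
            if jm > jmax_all:
                jmax_all = jm
    jup = jmax_all + int(10.0 * math.sqrt(jmax_all)) + 60
    lg1 = np.empty(jup + 2)
    lga = np.empty(jup + 2)
    for j in range(1, jup + 2):
        lg1[j] = math.lgamma(j + 1.0)
        lga[j] = math.lgamma(j * a)
    ok = True
    for i in range(y.shape[0]):
        if y[i] <= 0.0:
            out[i] = 0.0
            continue
        base = a * logy[i] + c0
        jm = int(y[i] ** (2.0 - p) * coef)
        if jm < 1:
            jm = 1
        wmax = jm * base - lg1[jm] - lga[jm]
        total = 1.0
        j = jm - 1
        while j >= 1:
            t = j * base - lg1[j] - lga[j] - wmax
            if t < _LOG_TINY:
                break
            total += math.exp(t)
            j -= 1
        j = jm + 1
        while j <= jup + 1:
            t = j * base - lg1[j] - lga[j] - wmax
            if t < _LOG_TINY:
                break
            total += math.exp(t)
            j += 1
        if j > jup + 1:
            ok = False
        out[i] = wmax + math.log(total) - logy[i]
    return ok


@numba.njit(cache=True)
def standard_logmu(log_mu0, drive, gamma_dd, dd_scale, first_t, logmu):
    """Recursive standard-model means.

    log mu_{i,t} = log mu_{i,t-1} + drive_{i,t} + gamma_dd * mu_{i,t-1}/dd_scale,
    anchored at the augmented pre-survey mean mu_{i,0} in the year before
    each site's first observed year.  Years before a site's entry are left
    untouched (the caller masks them).  Returns False if any log-mean
    leaves [-50, 50].
    """
    S, T = drive.shape
    ok = True
    for i in range(S):
        prev = log_mu0[i]
        for t in range(first_t[i], T):
            cur = prev + drive[i, t]
            if gamma_dd != 0.0:
                cur += gamma_dd * math.exp(prev) / dd_scale
            if not (-50.0 <= cur <= 50.0):
                ok = False
                cur = 50.0 if cur > 0 else -50.0
            logmu[i, t] = cur
            prev = cur
    return ok


@numba.njit(cache=True)
def standard_site_tilt(mu0, design, gamma, eps, gamma_dd, dd_scale, first_t,
                       y_f, col_f, starts, counts, phi, p,
                       logmu, site_tilt):
    """Fused standard-model pass: recursion + per-site tilt log-likelihood.

    The tilt is the mu-dependent part of the log density,
    (y*mu^(1-p)/(1-p) - mu^(2-p)/(2-p)) / phi, summed per site over that
    site's observed cells (y_f, col_f grouped by site via starts/counts).
    Returns False on divergent means.
    """
    S, T, K = design.shape
    q1 = 1.0 - p
    q2 = 2.0 - p
    ok = True
    for i in range(S):
        if mu0[i] <= 0.0:
            ok = False
            break
        prev = math.log(mu0[i])
        c = starts[i]
        stop = starts[i] + counts[i]
        acc = 0.0
        for t in range(first_t[i], T):
            d = 0.0
            for k in range(K):
                d += design[i, t, k] * gamma[k]
            cur = prev + d + eps[i]
            if gamma_dd != 0.0:
                cur += gamma_dd * math.exp(prev) / dd_scale
            if not (-50.0 <= cur <= 50.0):
                # only an observed year makes a divergent mean fatal
                cur = 50.0 if cur > 0 else -50.0
            logmu[i, t] = cur
            prev = cur
            if c < stop and col_f[c] == t:
                if cur >= 50.0 or cur <= -50.0:
                    ok = False
                acc += (y_f[c] * math.exp(q1 * cur) / q1
                        - math.exp(q2 * cur) / q2) / phi
                c += 1
        site_tilt[i] = acc
        if not ok:
            break
    return ok


@numba.njit(cache=True)
def change_site_tilt(mu0, design, gamma, eps, first_t,
                     y_f, col_f, starts, counts, phi, p,
                     logmu, site_tilt):
    """Fused change-model pass: baseline-anchored shifts + per-site tilt."""
    S, T, K = design.shape
    q1 = 1.0 - p
    q2 = 2.0 - p
    ok = True
    for i in range(S):
        if mu0[i] <= 0.0:
            ok = False
            break
        lmu0 = math.log(mu0[i])
        c = starts[i]
        stop = starts[i] + counts[i]
        acc = 0.0
        for t in range(first_t[i], T):
            if t == first_t[i]:
                cur = lmu0
            else:
                d = 0.0
                for k in range(K):
                    d += design[i, t, k] * gamma[k]
                cur = lmu0 + d + eps[i]
            if not (-50.0 <= cur <= 50.0):
                cur = 50.0 if cur > 0 else -50.0
            logmu[i, t] = cur
            if c < stop and col_f[c] == t:
                if cur >= 50.0 or cur <= -50.0:
                    ok = False
                acc += (y_f[c] * math.exp(q1 * cur) / q1
                        - math.exp(q2 * cur) / q2) / phi
                c += 1
        site_tilt[i] = acc
        if not ok:
            break
    return ok
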