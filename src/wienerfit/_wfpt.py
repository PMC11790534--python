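"""Numba kernels for the Wiener first-passage-time (WFPT) density and simulator.

The density of the first hit of the *lower* absorbing boundary of a Wiener
process with drift ``v``, boundary separation ``a``, relative start point
``w`` (fraction of ``a``) and unit diffusion coefficient factorises as

    f_lower(td) = (1 / a**2) * exp(-v*a*w - v**2*td/2) * f1(td / a**2, w)

where ``td`` is the decision time and ``f1`` is the standardised density
(zero drift, unit boundary).  ``f1`` has two series representations — one
converging fast for small scaled times, one for large — and the kernel picks
whichever needs fewer terms for the requested truncation error, following
the classic dual-series treatment of this density.  The upper-boundary
density is the lower-boundary density of the reflected process
(``v -> -v``, ``w -> 1 - w``).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "f1_small",
    "f1_large",
    "logf_lower",
    "loglik_terms",
    "loglik_sum",
    "simulate_many",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True)
def _n_terms_small(u, err):
    # terms needed by the small-time expansion for truncation error <= err
    if 2.0 * math.sqrt(2.0 * math.pi * u) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * err * math.sqrt(2.0 * math.pi * u)))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0
    return int(math.ceil(ks))


@njit(cache=True)
def _n_terms_large(u, err):
    # terms needed by the large-time expansion for truncation error <= err
    if math.pi * u * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * err) / (math.pi * math.pi * u))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    return int(math.ceil(kl))


@njit(cache=True)
def f1_small(u, w, err):
    """Small-time series of the standardised density at scaled time ``u``."""
    K = _n_terms_small(u, err)
    lo = -((K - 1) // 2)
    hi = (K - 1) // 2 + (K - 1) % 2
    acc = 0.0
    for k in range(lo, hi + 1):
        x = w + 2.0 * k
        acc += x * math.exp(-x * x / (2.0 * u))
    return acc / math.sqrt(2.0 * math.pi * u ** 3)


@njit(cache=True)
def f1_large(u, w, err):
    """Large-time series of the standardised density at scaled time ``u``."""
    K = _n_terms_large(u, err)
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
    return math.pi * acc


@njit(cache=True)
def logf_lower(td, v, a, w, err):
    """Log density of absorption at the lower boundary at decision time td.

    Returns -inf for td <= 0 or when the density underflows.  The series
    selection and summation are inlined: this function sits in the inner
    loop of every likelihood evaluation.
    """
    if td <= 0.0:
        return -np.inf
    u = td / (a * a)
    # term counts of both expansions for truncation error <= err
    if 2.0 * math.sqrt(2.0 * math.pi * u) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * err * math.sqrt(2.0 * math.pi * u)))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0
    if math.pi * u * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * err) / (math.pi * math.pi * u))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    if ks < kl:
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        f1 = 0.0
        for k in range(lo, hi + 1):
            x = w + 2.0 * k
            f1 += x * math.exp(-x * x / (2.0 * u))
        f1 /= math.sqrt(2.0 * math.pi * u ** 3)
    else:
        K = int(math.ceil(kl))
        f1 = 0.0
        for k in range(1, K + 1):
            f1 += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
        f1 *= math.pi
    if f1 <= 0.0:
        return -np.inf
    return math.log(f1) - v * a * w - 0.5 * v * v * td - 2.0 * math.log(a)


@njit(cache=True)
def loglik_terms(rt, hit_upper, v, a, z, t, err, out):
    """Per-trial WFPT log densities written into ``out``.

    Parameters are per-trial arrays; ``hit_upper`` selects the boundary
    (reflection handles the upper one).  ``rt`` at or below the non-decision
    time yields -inf.
    """
    n = rt.shape[0]
    for i in range(n):
        td = rt[i] - t[i]
        if hit_upper[i]:
            out[i] = logf_lower(td, -v[i], a[i], 1.0 - z[i], err)
        else:
            out[i] = logf_lower(td, v[i], a[i], z[i], err)


@njit(cache=True)
def loglik_sum(rt, hit_upper, v, a, z, t, err):
    """Summed WFPT log likelihood over trials with per-trial parameters."""
    total = 0.0
    n = rt.shape[0]
    for i in range(n):
        td = rt[i] - t[i]
        if hit_upper[i]:
            ll = logf_lower(td, -v[i], a[i], 1.0 - z[i], err)
        else:
            ll = logf_lower(td, v[i], a[i], z[i], err)
        if ll == -np.inf:
            return -np.inf
        total += ll
    return total


@njit(cache=True)
def simulate_many(v, a, z, t, dt, s, max_time, seed):
    """Euler–Maruyama first-passage simulation for per-trial parameters.

    Returns (rt, hit_upper, truncated); walks exceeding ``max_time`` of
    decision time are flagged truncated and assigned the boundary they are
    closest to at the cap.
    """
    np.random.seed(seed)
    n = v.shape[0]
    rt = np.empty(n)
    hit_upper = np.empty(n, np.bool_)
    truncated = np.zeros(n, np.bool_)
    sq = s * math.sqrt(dt)
    for i in range(n):
        x = z[i] * a[i]
        elapsed = 0.0
        vi_dt = v[i] * dt
        ai = a[i]
        while True:
            x += vi_dt + sq * np.random.normal()
            elapsed += dt
            if x >= ai:
                hit_upper[i] = True
                break
            if x <= 0.0:
                hit_upper[i] = False
                break
            if elapsed >= max_time:
                hit_upper[i] = x >= 0.5 * ai
                truncated[i] = True
                break
        rt[i] = elapsed + t[i]
    return rt, hit_upper, truncated
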