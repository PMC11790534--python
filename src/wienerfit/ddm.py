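"""Two-boundary Wiener diffusion: exact density, choice probability, simulation.

This is the computational core every fit builds on.  A single diffusion
process is described by :class:`DDMParams`: drift rate ``v`` (evidence per
second, signed toward the upper boundary), boundary separation ``a``,
relative starting point ``z`` (fraction of ``a``), non-decision time ``t``
(seconds) and the within-trial diffusion coefficient ``s`` (a fixed scaling
constant, 1.0 by convention).  Intertrial variabilities (``sv``, ``sz``,
``st``) are carried for completeness but fixed at zero: every fit in this
package uses the basic four-parameter model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _wfpt

__all__ = [
    "DDMParams",
    "BoundaryOutcome",
    "wfpt_density",
    "wfpt_loglik",
    "choice_probability",
    "simulate_trial",
    "simulate_trials",
    "LOGLIK_SENTINEL",
]

#: absolute truncation error of the density series
DENSITY_ERR = 1e-10
#: series truncation used inside MCMC likelihood evaluation (speed matters)
FIT_DENSITY_ERR = 1e-7

LOGLIK_SENTINEL = -np.inf


@dataclass(frozen=True)
class DDMParams:
    """One parameterisation of the two-boundary diffusion process.

    Raises ``ValueError`` for out-of-domain values; the intertrial
    variabilities must stay at zero.
    """

    v: float
    a: float
    z: float
    t: float
    s: float = 1.0
    sv: float = 0.0
    sz: float = 0.0
    st: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ValueError(f"drift rate must be finite, got {self.v}")
        if not (self.a > 0):
            raise ValueError(f"boundary separation must be > 0, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative starting point must be in (0, 1), got {self.z}")
        if not (self.t >= 0):
            raise ValueError(f"non-decision time must be >= 0, got {self.t}")
        if not (self.s > 0):
            raise ValueError(f"diffusion coefficient must be > 0, got {self.s}")
        if self.sv != 0.0 or self.sz != 0.0 or self.st != 0.0:
            raise ValueError("intertrial variabilities are fixed at zero in this model")

    def _unit_scale(self) -> tuple[float, float]:
        """Drift and boundary re-expressed for a unit diffusion coefficient."""
        return self.v / self.s, self.a / self.s


@dataclass(frozen=True)
class BoundaryOutcome:
    """A simulated trial outcome: which boundary was absorbed, and when."""

    boundary: str  # "upper" | "lower"
    rt: float  # seconds, decision time + non-decision time
    truncated: bool = False


def _check_boundary(boundary: str) -> bool:
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return boundary == "upper"


def wfpt_density(rt, boundary: str, params: DDMParams, err: float = DENSITY_ERR):
    """Defective first-passage density of reaching ``boundary`` at time ``rt``.

    ``rt`` may be a scalar or array (seconds, full response time including
    non-decision time).  Zero is returned at and below the non-decision
    time.  The density at the lower boundary is the upper-boundary density
    of the reflected process (v -> -v, z -> 1 - z).
    """
    upper = _check_boundary(boundary)
    v, a = params._unit_scale()
    z = params.z
    if upper:
        v, z = -v, 1.0 - z
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    if not np.all(np.isfinite(rt_arr)):
        raise ValueError("rt must be finite")
    out = np.empty_like(rt_arr)
    for i, r in enumerate(rt_arr):
        logf = _wfpt.logf_lower(r - params.t, v, a, z, err)
        out[i] = 0.0 if logf == -np.inf else np.exp(logf)
    return out[0] if np.isscalar(rt) or np.ndim(rt) == 0 else out


def wfpt_loglik(trials, params: DDMParams, err: float = FIT_DENSITY_ERR) -> float:
    """Summed log likelihood (nats) of ``trials`` under one parameter set.

    ``trials`` is a sequence of ``(rt, boundary)`` pairs.  Any trial with
    ``rt <= t`` lies outside the support and makes the whole sum the
    ``-inf`` sentinel.  An empty trial list is an error.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("trial list is empty")
    rts = np.array([rt for rt, _ in trials], dtype=float)
    if not np.all(np.isfinite(rts)):
        raise ValueError("rt must be finite")
    upper = np.array([_check_boundary(b) for _, b in trials])
    v, a = params._unit_scale()
    n = len(trials)
    return _wfpt.loglik_sum(
        rts,
        upper,
        np.full(n, v),
        np.full(n, a),
        np.full(n, params.z),
        np.full(n, params.t),
        err,
    )


def choice_probability(params: DDMParams) -> float:
    """Probability of absorption at the upper boundary (closed form).

    For drift v, boundary a, start z·a and diffusion s this is
    ``(1 - exp(-2*v*a*z/s^2)) / (1 - exp(-2*v*a/s^2))``, with the driftless
    limit ``z`` handled analytically.
    """
    v, a = params._unit_scale()
    if v == 0.0:
        return params.z
    # expm1 keeps the ratio stable for small |v|
    num = -np.expm1(-2.0 * v * a * params.z)
    den = -np.expm1(-2.0 * v * a)
    return float(num / den)


def simulate_trial(
    params: DDMParams,
    dt: float = 1e-4,
    seed: int | None = None,
    max_decision_time: float = 20.0,
) -> BoundaryOutcome:
    """Simulate one trial by an Euler–Maruyama walk from ``z*a``.

    ``dt`` should be small relative to ``a**2 / s**2`` (the diffusion time
    scale); the default 1e-4 s keeps the discrete crossing bias well below
    Monte-Carlo noise at the parameter scales used here.  Deterministic
    under a fixed ``seed``.  Walks that have not been absorbed after
    ``max_decision_time`` seconds of decision time are truncated and
    flagged rather than looping forever.
    """
    rt, upper, trunc = simulate_trials(params, 1, dt=dt, seed=seed, max_decision_time=max_decision_time)
    return BoundaryOutcome(
        boundary="upper" if upper[0] else "lower",
        rt=float(rt[0]),
        truncated=bool(trunc[0]),
    )


def simulate_trials(
    params: DDMParams,
    n: int,
    dt: float = 1e-4,
    seed: int | None = None,
    max_decision_time: float = 20.0,
):
    """Simulate ``n`` i.i.d. trials; returns ``(rt, hit_upper, truncated)`` arrays."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    return _wfpt.simulate_many(
        np.full(n, params.v),
        np.full(n, params.a),
        np.full(n, params.z),
        np.full(n, params.t),
        float(dt),
        params.s,
        float(max_decision_time),
        int(seed),
    )
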