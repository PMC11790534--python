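"""Hierarchical Bayesian estimation of diffusion parameters by MCMC.

The model places, for every diffusion parameter and design cell declared by
the :class:`~wienerfit.models.ModelSpec`, a group-level Normal on a
transformed scale (drift: identity; boundary separation and non-decision
time: log; starting point: logit) with subject-level values drawn from it.
The trial likelihood is the Wiener first-passage density under the
subject's cell parameters; proposals that put the non-decision time at or
above any of the cell's response times get a log likelihood of -inf and
are simply rejected, so no data trimming is needed.

Sampling is adaptive Metropolis-within-Gibbs: random-walk updates of each
subject-level parameter block against its conditional posterior, a
conjugate Gibbs draw for each group mean, and a random-walk update of each
group standard deviation on the log scale.  Proposal widths are tuned
during burn-in only, leaving the post-burn-in kernel fixed.  Two or more
independently seeded chains are run so convergence can be checked with the
Gelman–Rubin statistic.

The estimator follows scikit-learn conventions: constructor parameters are
plain values, :meth:`HierarchicalDDM.fit` runs the sampler, and fitted
attributes carry a trailing underscore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import _wfpt
from .models import PARAMS, ModelData, ModelSpec, build_model

try:  # estimator API niceties (get_params/set_params, clone support)
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

__all__ = [
    "Priors",
    "default_priors",
    "PosteriorSamples",
    "FitResult",
    "HierarchicalDDM",
    "fit_model",
    "sample_posterior",
    "gelman_rubin",
]


def _to_natural(param: str, x):
    if param in ("a", "t"):
        return np.exp(x)
    if param == "z":
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
    return x


def _transform_name(param: str) -> str:
    return {"v": "identity", "a": "log", "z": "logit", "t": "log"}[param]


@dataclass(frozen=True)
class Priors:
    """Group-level priors on the transformed scales.

    ``mu`` maps parameter -> (location, scale) of the Normal prior on the
    group mean; ``sigma_scale`` maps parameter -> scale of the half-Normal
    prior on the group standard deviation.  All on the sampling
    (transformed) scale.
    """

    mu: Mapping[str, tuple[float, float]]
    sigma_scale: Mapping[str, float]

    def sample_group(self, rng: np.random.Generator) -> dict[str, float]:
        """One prior draw of group means, mapped to the natural scale."""
        return {
            p: float(np.asarray(_to_natural(p, rng.normal(*self.mu[p]))))
            for p in PARAMS
        }


def default_priors(boundary_coding: str = "stimulus") -> Priors:
    """Weakly informative defaults covering plausible two-choice RT regimes.

    Under accuracy coding the drift prior is centred at 1 (above-chance
    performance is expected); under stimulus coding at 0 (no a-priori
    directional preference).
    """
    v_loc = 1.0 if boundary_coding == "accuracy" else 0.0
    return Priors(
        mu={
            "v": (v_loc, 2.0),
            "a": (math.log(1.5), 1.0),
            "z": (0.0, 1.5),
            "t": (math.log(0.4), 1.0),
        },
        sigma_scale={"v": 0.5, "a": 0.5, "z": 0.5, "t": 0.5},
    )


class PosteriorSamples:
    """MCMC draws indexed by (chain, iteration, parameter name).

    Burn-in draws are retained; summaries discard them via ``burn_in``.
    Group-level names are ``mu_<p>[<cell>]`` / ``sigma_<p>[<cell>]``
    (cell omitted for global parameters), subject-level names
    ``<p>[<cell>]_<subject>``; all on the sampling (transformed) scale.
    """

    def __init__(
        self,
        draws: dict[str, np.ndarray],
        burn_in: int,
        cells: dict[str, list[str]],
        subjects: list[str],
        boundary_coding: str,
    ):
        self.draws = draws
        self.burn_in = int(burn_in)
        self.cells = cells
        self.subjects = subjects
        self.boundary_coding = boundary_coding
        n_total = next(iter(draws.values())).shape[1]
        if n_total - self.burn_in < 1:
            raise ValueError("no draws remain after burn-in")

    @property
    def names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def post_burn(self, name: str) -> np.ndarray:
        """(chains, kept) array of post-burn-in draws of one parameter."""
        return self.draws[name][:, self.burn_in:]

    def flat(self, name: str) -> np.ndarray:
        return self.post_burn(name).reshape(-1)

    @staticmethod
    def _group_name(kind: str, param: str, cell: str) -> str:
        return f"{kind}_{param}" if cell == "all" else f"{kind}_{param}[{cell}]"

    def group_draws(self, param: str, cell: str | None = None, natural: bool = True) -> np.ndarray:
        """Flat post-burn-in draws of a group mean, natural scale by default."""
        cell = cell if cell is not None else self.cells[param][0]
        x = self.flat(self._group_name("mu", param, cell))
        return np.asarray(_to_natural(param, x)) if natural else x

    def subject_draws(self, param: str, cell: str, subject: str, natural: bool = True) -> np.ndarray:
        name = f"{param}_{subject}" if cell == "all" else f"{param}[{cell}]_{subject}"
        x = self.flat(name)
        return np.asarray(_to_natural(param, x)) if natural else x

    def subject_posterior_means(self, param: str, cell: str | None = None) -> np.ndarray:
        """Natural-scale posterior means of the subject-level values."""
        cell = cell if cell is not None else self.cells[param][0]
        return np.array([
            float(np.mean(self.subject_draws(param, cell, s))) for s in self.subjects
        ])


@dataclass
class FitResult:
    """A fitted hierarchical model: draws, deviance, DIC and diagnostics."""

    spec: ModelSpec
    samples: PosteriorSamples
    deviance: np.ndarray  # (chains, total iterations)
    dic: float
    p_d: float
    deviance_at_mean: float
    rhat: dict[str, float]
    data_hash: int
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def n_dependencies(self) -> int:
        return self.spec.n_dependencies

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")


def gelman_rubin(samples) -> dict[str, float]:
    """Potential scale reduction factor per parameter.

    Accepts a :class:`PosteriorSamples` (post-burn-in draws are used) or a
    mapping of name -> (chains, draws) arrays.  Uses the classic
    between-/within-chain variance-ratio formula; at least two chains with
    at least two draws each are required.
    """
    if isinstance(samples, PosteriorSamples):
        arrays = {name: samples.post_burn(name) for name in samples.names}
    else:
        arrays = {name: np.atleast_2d(np.asarray(x, dtype=float)) for name, x in samples.items()}
    out = {}
    for name, x in arrays.items():
        m, n = x.shape
        if m < 2:
            raise ValueError(
                "Gelman-Rubin requires >= 2 chains; rerun the sampler with multiple chains"
            )
        if n < 2:
            raise ValueError("Gelman-Rubin requires >= 2 draws per chain")
        chain_means = x.mean(axis=1)
        w = float(x.var(axis=1, ddof=1).mean())
        b_over_n = float(chain_means.var(ddof=1))
        if b_over_n == 0.0:
            out[name] = 1.0
            continue
        if w == 0.0:
            out[name] = float("inf")
            continue
        var_plus = (n - 1) / n * w + b_over_n
        out[name] = float(np.sqrt(var_plus / w))
    return out


# --- the sampler ----------------------------------------------------------

_INIT_THETA = {"v": 0.5, "a": math.log(1.8), "z": 0.0}
_ADAPT_EVERY = 25
_TARGET_ACCEPT = 0.44  # optimal acceptance for one-dimensional random walks
_SIGMA_SUBSTEPS = 5


def _run_chain(data: ModelData, priors: Priors, n_total: int, burn_in: int,
               rng: np.random.Generator, err: float):
    S = data.n_subjects
    ncells = {p: len(data.cells[p]) for p in PARAMS}

    theta = {}
    for p in PARAMS:
        if p == "t":
            col = np.array([math.log(0.7 * data.min_rt(s)) for s in range(S)])
            theta["t"] = np.repeat(col[:, None], ncells["t"], axis=1)
        else:
            theta[p] = np.full((S, ncells[p]), _INIT_THETA[p])
    mu = {p: theta[p].mean(axis=0).copy() for p in PARAMS}
    log_sigma = {p: np.full(ncells[p], math.log(0.2)) for p in PARAMS}

    # per-subject natural per-trial parameter arrays and cached log densities
    nat = {p: [] for p in PARAMS}
    cache = []
    pre = []  # per subject: {(p, ci): (idx, rt_sub, up_sub, sign_sub)}
    for s in range(S):
        cidx = data.cell_idx[s]
        nat["v"].append(data.sign[s] * _to_natural("v", theta["v"][s])[cidx["v"]])
        for p in ("a", "z", "t"):
            nat[p].append(np.asarray(_to_natural(p, theta[p][s]))[cidx[p]])
        ll = np.empty(len(data.rt[s]))
        _wfpt.loglik_terms(data.rt[s], data.hit_upper[s],
                           nat["v"][s], nat["a"][s], nat["z"][s], nat["t"][s], err, ll)
        if not np.all(np.isfinite(ll)):
            raise RuntimeError(
                f"non-finite initial likelihood for subject {data.subjects[s]}"
            )
        cache.append(ll)
        subs = {}
        for key, idx in data.subsets[s].items():
            subs[key] = (idx, data.rt[s][idx].copy(), data.hit_upper[s][idx].copy(),
                         data.sign[s][idx].copy())
        pre.append(subs)

    steps = {p: np.full((S, ncells[p]), 0.3) for p in PARAMS}
    acc = {p: np.zeros((S, ncells[p])) for p in PARAMS}
    win_prop = {p: np.zeros((S, ncells[p])) for p in PARAMS}
    acc_total = {p: np.zeros((S, ncells[p])) for p in PARAMS}
    n_total_prop = {p: np.zeros((S, ncells[p])) for p in PARAMS}
    sig_steps = {p: np.full(ncells[p], 0.3) for p in PARAMS}
    sig_acc = {p: np.zeros(ncells[p]) for p in PARAMS}

    out = {}
    for p in PARAMS:
        for ci, label in enumerate(data.cells[p]):
            out[PosteriorSamples._group_name("mu", p, label)] = np.empty(n_total)
            out[PosteriorSamples._group_name("sigma", p, label)] = np.empty(n_total)
            for s, sid in enumerate(data.subjects):
                name = f"{p}_{sid}" if label == "all" else f"{p}[{label}]_{sid}"
                out[name] = np.empty(n_total)
    deviance = np.empty(n_total)

    # two full sweeps per iteration: subject-level blocks are cheap relative
    # to the group updates' convergence cost, and the extra sweep roughly
    # doubles the effective sample size per stored draw
    sweep_params = PARAMS + PARAMS

    for it in range(n_total):
        # subject-level Metropolis updates
        for s in range(S):
            for p in sweep_params:
                for ci in range(ncells[p]):
                    y = theta[p][s, ci]
                    yp = y + steps[p][s, ci] * rng.standard_normal()
                    sig = math.exp(log_sigma[p][ci])
                    dprior = -0.5 * ((yp - mu[p][ci]) ** 2 - (y - mu[p][ci]) ** 2) / (sig * sig)
                    idx, rt_sub, up_sub, sign_sub = pre[s][(p, ci)]
                    natp = float(np.asarray(_to_natural(p, yp)))
                    m = len(idx)
                    if p == "v":
                        v_arr = sign_sub * natp
                        a_arr = nat["a"][s][idx]; z_arr = nat["z"][s][idx]; t_arr = nat["t"][s][idx]
                    elif p == "a":
                        v_arr = nat["v"][s][idx]
                        a_arr = np.full(m, natp)
                        z_arr = nat["z"][s][idx]; t_arr = nat["t"][s][idx]
                    elif p == "z":
                        v_arr = nat["v"][s][idx]; a_arr = nat["a"][s][idx]
                        z_arr = np.full(m, natp)
                        t_arr = nat["t"][s][idx]
                    else:
                        v_arr = nat["v"][s][idx]; a_arr = nat["a"][s][idx]; z_arr = nat["z"][s][idx]
                        t_arr = np.full(m, natp)
                    ll_vec = np.empty(m)
                    _wfpt.loglik_terms(rt_sub, up_sub, v_arr, a_arr, z_arr, t_arr, err, ll_vec)
                    ll_new = ll_vec.sum()
                    n_total_prop[p][s, ci] += 1
                    win_prop[p][s, ci] += 1
                    if ll_new == -np.inf:
                        continue
                    ll_old = cache[s][idx].sum()
                    if math.log(rng.uniform()) < dprior + ll_new - ll_old:
                        theta[p][s, ci] = yp
                        if p == "v":
                            nat["v"][s][idx] = v_arr
                        else:
                            nat[p][s][idx] = natp
                        cache[s][idx] = ll_vec
                        acc[p][s, ci] += 1
                        acc_total[p][s, ci] += 1

        # group-level updates
        for p in PARAMS:
            loc0, scale0 = priors.mu[p]
            hs = priors.sigma_scale[p]
            for ci in range(ncells[p]):
                th = theta[p][:, ci]
                sig = math.exp(log_sigma[p][ci])
                prec = 1.0 / (scale0 * scale0) + S / (sig * sig)
                mean = (loc0 / (scale0 * scale0) + th.sum() / (sig * sig)) / prec
                mu[p][ci] = mean + rng.standard_normal() / math.sqrt(prec)

                # several cheap MH sub-steps: the conditional of the group
                # sd involves no trial likelihood, so this is nearly a
                # full conditional draw
                ss = float(((th - mu[p][ci]) ** 2).sum())

                def logtarget(l):
                    s2 = math.exp(2.0 * l)
                    return -S * l - ss / (2.0 * s2) - s2 / (2.0 * hs * hs) + l

                accepted = 0
                for _ in range(_SIGMA_SUBSTEPS):
                    ls = log_sigma[p][ci]
                    lsp = ls + sig_steps[p][ci] * rng.standard_normal()
                    if math.log(rng.uniform()) < logtarget(lsp) - logtarget(ls):
                        log_sigma[p][ci] = lsp
                        accepted += 1
                sig_acc[p][ci] += accepted / _SIGMA_SUBSTEPS

        # burn-in step-size adaptation
        if it < burn_in and (it + 1) % _ADAPT_EVERY == 0:
            for p in PARAMS:
                rate = acc[p] / np.maximum(win_prop[p], 1)
                steps[p] *= np.exp(1.2 * (rate - _TARGET_ACCEPT))
                np.clip(steps[p], 1e-3, 5.0, out=steps[p])
                acc[p][:] = 0.0
                win_prop[p][:] = 0.0
                srate = sig_acc[p] / _ADAPT_EVERY
                sig_steps[p] *= np.exp(1.2 * (srate - _TARGET_ACCEPT))
                np.clip(sig_steps[p], 1e-3, 5.0, out=sig_steps[p])
                sig_acc[p][:] = 0.0

        # record
        for p in PARAMS:
            for ci, label in enumerate(data.cells[p]):
                out[PosteriorSamples._group_name("mu", p, label)][it] = mu[p][ci]
                out[PosteriorSamples._group_name("sigma", p, label)][it] = math.exp(log_sigma[p][ci])
                for s, sid in enumerate(data.subjects):
                    name = f"{p}_{sid}" if label == "all" else f"{p}[{label}]_{sid}"
                    out[name][it] = theta[p][s, ci]
        deviance[it] = -2.0 * sum(c.sum() for c in cache)

    accept_rate = {
        p: float((acc_total[p] / np.maximum(n_total_prop[p], 1)).mean()) for p in PARAMS
    }
    theta_last = theta
    return out, deviance, accept_rate, theta_last


def fit_model(
    model: ModelData | ModelSpec | str,
    trials: pd.DataFrame | None = None,
    draws: int = 5000,
    burn_in: int = 500,
    chains: int = 2,
    seed: int | None = None,
    priors: Priors | None = None,
    err: float = 1e-7,
) -> FitResult:
    """Fit a hierarchical diffusion model and return the full result.

    ``draws`` is the total number of MCMC iterations per chain, of which
    the first ``burn_in`` are discarded from summaries (but retained in
    the stored draws).  Deterministic under a fixed ``seed``.
    """
    if isinstance(model, (ModelSpec, str)):
        if trials is None:
            raise ValueError("trials are required when passing a model spec")
        data = build_model(model, trials)
    else:
        data = model
    if draws <= burn_in:
        raise ValueError("draws must exceed burn_in")
    if chains < 1:
        raise ValueError("at least one chain is required")
    priors = priors or default_priors(data.spec.boundary_coding)

    seed_seq = np.random.SeedSequence(seed if seed is not None else 0)
    chain_out = []
    devs = []
    acc = []
    for child in seed_seq.spawn(chains):
        rng = np.random.default_rng(child)
        o, d, a, _ = _run_chain(data, priors, draws, burn_in, rng, err)
        chain_out.append(o)
        devs.append(d)
        acc.append(a)

    stacked = {
        name: np.stack([o[name] for o in chain_out]) for name in chain_out[0]
    }
    samples = PosteriorSamples(
        stacked, burn_in, data.cells, data.subjects, data.spec.boundary_coding
    )
    deviance = np.stack(devs)

    # deviance at the posterior-mean subject parameters (sampling scale,
    # mapped back) -> Spiegelhalter effective-parameter penalty
    dev_hat = _deviance_at_mean(data, samples, err)
    d_bar = float(deviance[:, burn_in:].mean())
    p_d = d_bar - dev_hat
    dic = d_bar + p_d

    rhat = gelman_rubin(samples) if chains >= 2 else {}
    accept = {p: float(np.mean([a[p] for a in acc])) for p in PARAMS}
    return FitResult(
        spec=data.spec,
        samples=samples,
        deviance=deviance,
        dic=float(dic),
        p_d=float(p_d),
        deviance_at_mean=float(dev_hat),
        rhat=rhat,
        data_hash=data.data_hash,
        acceptance=accept,
    )


def _deviance_at_mean(data: ModelData, samples: PosteriorSamples, err: float) -> float:
    total = 0.0
    for s, sid in enumerate(data.subjects):
        cidx = data.cell_idx[s]
        vals = {}
        for p in PARAMS:
            cell_means = []
            for label in data.cells[p]:
                name = f"{p}_{sid}" if label == "all" else f"{p}[{label}]_{sid}"
                cell_means.append(float(samples.flat(name).mean()))
            vals[p] = np.asarray(_to_natural(p, np.array(cell_means)))
        v_arr = data.sign[s] * vals["v"][cidx["v"]]
        a_arr = vals["a"][cidx["a"]]
        z_arr = vals["z"][cidx["z"]]
        t_arr = vals["t"][cidx["t"]]
        ll = _wfpt.loglik_sum(data.rt[s], data.hit_upper[s], v_arr, a_arr, z_arr, t_arr, err)
        total += ll
    return -2.0 * total


def sample_posterior(
    model: ModelData | ModelSpec | str,
    trials: pd.DataFrame | None = None,
    n_samples: int = 5000,
    burn_in: int = 500,
    n_chains: int = 2,
    seed: int | None = None,
    priors: Priors | None = None,
) -> PosteriorSamples:
    """Draw from the joint posterior (thin wrapper over :func:`fit_model`)."""
    return fit_model(model, trials, draws=n_samples, burn_in=burn_in,
                     chains=n_chains, seed=seed, priors=priors).samples


class HierarchicalDDM(BaseEstimator):
    """scikit-learn style estimator wrapping the hierarchical sampler.

    Parameters
    ----------
    model : str or ModelSpec, default "M1"
        Catalogue name or explicit specification.
    draws, burn_in, chains : int
        Total MCMC iterations per chain, burn-in length, chain count.
        The defaults mirror common practice for this model family
        (5000 draws, 500 burn-in).
    seed : int or None
        Seed for all chains (chains are spawned independently from it).
    priors : Priors or None
        Transformed-scale group priors; sensible defaults per coding.

    Attributes (after ``fit``)
    --------------------------
    result_ : FitResult
    samples_ : PosteriorSamples
    dic_ : float
    rhat_ : dict[str, float]
    """

    def __init__(self, model="M1", draws: int = 5000, burn_in: int = 500,
                 chains: int = 2, seed: int | None = None,
                 priors: Priors | None = None, err: float = 1e-7):
        self.model = model
        self.draws = draws
        self.burn_in = burn_in
        self.chains = chains
        self.seed = seed
        self.priors = priors
        self.err = err

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalDDM":
        """Run the sampler on a trial table ``X``."""
        self.result_ = fit_model(
            self.model, X, draws=self.draws, burn_in=self.burn_in,
            chains=self.chains, seed=self.seed, priors=self.priors, err=self.err,
        )
        self.samples_ = self.result_.samples
        self.dic_ = self.result_.dic
        self.rhat_ = self.result_.rhat
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise AttributeError("this HierarchicalDDM instance is not fitted yet")

    def group_draws(self, param: str, cell: str | None = None, natural: bool = True) -> np.ndarray:
        self._check_fitted()
        return self.samples_.group_draws(param, cell, natural)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and 95% credible interval per parameter."""
        self._check_fitted()
        rows = []
        for name in self.samples_.names:
            x = self.samples_.flat(name)
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append({
                "parameter": name, "mean": x.mean(), "sd": x.std(ddof=1),
                "hdi_2.5%": lo, "hdi_97.5%": hi,
                "rhat": self.rhat_.get(name, np.nan),
            })
        return pd.DataFrame(rows)
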