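"""Model comparison and posterior hypothesis tests.

Three ingredients of the analysis workflow live here:

* the deviance information criterion (DIC) in the classic Spiegelhalter
  form, ``DIC = D_bar + p_D`` with ``p_D = D_bar - D(theta_bar)``, and a
  ranking of fitted models by it (lower = better fit);
* the posterior-overlap directional test: the probability ``P_p|D`` that
  one parameter exceeds another (or zero), estimated from MCMC draws,
  with the 5%-overlap significance convention (significant iff
  ``P >= 0.95`` or ``P <= 0.05``);
* the cross-modality Pearson correlation of subject-level posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sampler import FitResult

__all__ = [
    "dic",
    "dic_from_deviance",
    "ModelScore",
    "compare_models",
    "OverlapResult",
    "posterior_overlap_test",
    "cross_modality_correlation",
    "CorrelationResult",
]


def dic_from_deviance(deviance_trace: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """(DIC, p_D) from a posterior deviance trace and the plug-in deviance."""
    trace = np.asarray(deviance_trace, dtype=float).ravel()
    if trace.size == 0:
        raise ValueError("empty deviance trace")
    if not np.all(np.isfinite(trace)) or not np.isfinite(deviance_at_mean):
        bad = [int(i) for i in np.flatnonzero(~np.isfinite(trace))[:10]]
        raise ValueError(f"non-finite deviances (draws {bad})")
    d_bar = float(trace.mean())
    p_d = d_bar - float(deviance_at_mean)
    return d_bar + p_d, p_d


def dic(fit: FitResult) -> float:
    """DIC of a fitted model, recomputed from its post-burn-in deviance trace."""
    trace = fit.deviance[:, fit.samples.burn_in:]
    value, _ = dic_from_deviance(trace, fit.deviance_at_mean)
    return value


class ModelScore(NamedTuple):
    """Lightweight stand-in for a fit when only the DIC value is at hand."""

    name: str
    dic: float
    description: str = ""
    n_dependencies: int = 0
    data_hash: int = 0


def compare_models(fits: Sequence) -> pd.DataFrame:
    """Rank >= 2 fits of the same data by ascending DIC.

    Accepts :class:`~wienerfit.sampler.FitResult` objects or
    :class:`ModelScore` tuples.  Ties are broken in favour of the model
    with fewer declared dependencies; fits on differing data are refused.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("model comparison needs at least two fits")
    hashes = {getattr(f, "data_hash", 0) for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were computed on differing trial data")
    rows = []
    for f in fits:
        desc = getattr(f, "description", "") or getattr(getattr(f, "spec", None), "description", "")
        rows.append({
            "model": f.name,
            "dependencies": desc,
            "dic": float(f.dic),
            "n_dependencies": int(getattr(f, "n_dependencies", 0)),
        })
    table = pd.DataFrame(rows).sort_values(
        ["dic", "n_dependencies"], kind="stable"
    ).reset_index(drop=True)
    table["delta_dic"] = table["dic"] - table["dic"].iloc[0]
    return table.drop(columns="n_dependencies")


@dataclass(frozen=True)
class OverlapResult:
    """A directional posterior probability and its 5%-rule verdict."""

    label: str
    probability: float
    significant: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        star = " *" if self.significant else ""
        return f"P_p|D[{self.label}] = {self.probability:.3f}{star}"


def posterior_overlap_test(
    a: np.ndarray,
    b: np.ndarray | float = 0.0,
    label: str = "a > b",
    paired: bool | None = None,
    n_resample: int = 100_000,
    seed: int = 0,
) -> OverlapResult:
    """Posterior probability that parameter ``a`` exceeds ``b``.

    ``b`` may be a constant (comparison of an effect with zero) or a second
    draw array.  Draws of equal length from one joint fit are compared
    pairwise within draw (the default); otherwise independent product
    resampling with a fixed seed is used — enable it explicitly via
    ``paired=False`` when the arrays come from separate fits.  Ties count
    half, so ``P(a > b) + P(b > a) = 1`` exactly.
    """
    a = np.asarray(a, dtype=float).ravel()
    if a.size < 2:
        raise ValueError("need posterior draws for a")
    if np.isscalar(b) or np.ndim(b) == 0:
        diff = a - float(b)
    else:
        b = np.asarray(b, dtype=float).ravel()
        if paired is None:
            paired = a.size == b.size
        if paired:
            if a.size != b.size:
                raise ValueError(
                    "paired comparison needs equal draw counts; pass paired=False "
                    "to resample independent draws"
                )
            diff = a - b
        else:
            rng = np.random.default_rng(seed)
            diff = rng.choice(a, n_resample) - rng.choice(b, n_resample)
    p = float(np.mean(diff > 0) + 0.5 * np.mean(diff == 0))
    return OverlapResult(label=label, probability=p, significant=p >= 0.95 or p <= 0.05)


class CorrelationResult(NamedTuple):
    r: float
    df: int
    p: float


def cross_modality_correlation(fit_point, fit_swipe, parameter: str,
                               cell: str | None = None) -> CorrelationResult:
    """Pearson correlation of subject-level posterior means across two fits.

    ``fit_point`` / ``fit_swipe`` may be :class:`FitResult` objects (fitted
    to the same subjects) or plain per-subject value arrays.  Returns
    ``(r, df, p)`` with ``df = n_subjects - 2`` and a two-sided p-value
    from the t transform of r.
    """
    x = _subject_means(fit_point, parameter, cell)
    y = _subject_means(fit_swipe, parameter, cell)
    if isinstance(fit_point, FitResult) and isinstance(fit_swipe, FitResult):
        if fit_point.samples.subjects != fit_swipe.samples.subjects:
            raise ValueError("the two fits cover different subjects")
    if x.shape != y.shape:
        raise ValueError("subject mismatch between the two fits")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), df=n - 2, p=float(res.pvalue))


def _subject_means(fit, parameter: str, cell: str | None) -> np.ndarray:
    if isinstance(fit, FitResult):
        return fit.samples.subject_posterior_means(parameter, cell)
    return np.asarray(fit, dtype=float).ravel()
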