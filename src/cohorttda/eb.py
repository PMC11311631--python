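"""Empirical Bayes significance of barcode durations.

Durations of spurious topological features in unstructured data are well
described by an exponential distribution, while real features of the
underlying manifold live in the long right tail.  Observed durations are
therefore modeled as a two-group mixture

    f(x) = p0 * f0(x) + (1 - p0) * f1(x),      f0(x) = lambda * exp(-lambda x)

where f0 is the null, f1 is an unspecified alternative, and p0 is the prior
probability that a duration is null.  The exponential rate is estimated
robustly by median matching (lambda = ln 2 / median, insensitive to the
alternative tail), the marginal density f-hat by a
penalized Gamma-family smooth, and p0 as the largest ("most conservative")
prior that keeps every posterior non-negative:

    p0 = min(1, min_x f-hat(x) / f0(x))        over observed durations x.

The posterior probability that a duration x belongs to the alternative is
then 1 - p0 * f0(x) / f-hat(x), clamped to [0, 1].
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist
from scipy.stats import gaussian_kde

from .rips import BarcodeSet

__all__ = [
    "EBModel",
    "fit_null_rate",
    "fit_density",
    "fit_conservative_prior",
    "fit_eb",
    "posterior_alternative",
    "score_barcodes",
]

MIN_DURATIONS = 10


def _as_positive_array(durations: Sequence[float]) -> np.ndarray:
    x = np.asarray(durations, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("durations must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("durations must be positive and finite")
    return x


def fit_null_rate(durations: Sequence[float]) -> float:
    """Robust exponential rate: lambda = ln 2 / median(durations).

    The median of Exp(lambda) is ln 2 / lambda, so median matching recovers
    the rate exactly under the null while ignoring a minority of long
    alternative durations.
    """
    x = _as_positive_array(durations)
    if x.size < MIN_DURATIONS:
        warnings.warn(
            f"only {x.size} durations (< {MIN_DURATIONS}); rate estimate is unstable",
            stacklevel=2,
        )
    return math.log(2.0) / float(np.median(x))


GAMMA_PRIOR_WEIGHT = 10.0


def fit_density(
    durations: Sequence[float],
    bandwidth: str | float = "silverman",
    estimator: str = "gamma",
):
    """Marginal density estimate f-hat.

    The default is a penalized Gamma fit: maximum likelihood over shape and
    scale with the shape constrained to be at least 1 and its logarithm
    shrunk toward 0 (the exponential boundary) with the weight of a few
    pseudo-observations.  This is the Efron-style smooth marginal restricted
    to the Gamma exponential family: under null (exponential-like) durations
    the ratio f-hat/f0 stays close to 1 across the whole range instead of
    developing spurious bumps at the few dozen bars a single cohort
    produces, while genuinely long alternative durations still inflate the
    fitted scale and score near 1.  The shape floor at 1 also makes the
    posterior monotone in the tail.

    ``estimator="kde"`` gives a Gaussian kernel density on log durations
    back-transformed (f-hat(x) = kde(log x) / x, Silverman bandwidth) --
    more faithful to local structure, noisier in the ratio.
    """
    x = _as_positive_array(durations)
    if x.size < 3:
        raise ValueError("need at least 3 durations for a density estimate")
    if np.ptp(np.log(x)) == 0:
        raise ValueError("degenerate duration set: all values identical")
    if estimator == "kde":
        kde = gaussian_kde(np.log(x), bw_method=bandwidth)

        def density(v):
            vv = np.atleast_1d(np.asarray(v, dtype=float))
            ok = vv > 0
            res = np.zeros(vv.shape)
            res[ok] = kde(np.log(vv[ok])) / vv[ok]
            return res if np.ndim(v) else float(res[0])

        return density
    if estimator != "gamma":
        raise ValueError(f"unknown density estimator {estimator!r}")
    shape, scale = _fit_penalized_gamma(x)

    def density(v):
        vv = np.atleast_1d(np.asarray(v, dtype=float))
        res = gamma_dist.pdf(vv, shape, loc=0, scale=scale)
        return res if np.ndim(v) else float(res[0])

    density.shape_ = shape  # type: ignore[attr-defined]
    density.scale_ = scale  # type: ignore[attr-defined]
    return density


def _fit_penalized_gamma(
    x: np.ndarray, prior_weight: float = GAMMA_PRIOR_WEIGHT
) -> tuple[float, float]:
    """Gamma(shape >= 1) fit by penalized profile likelihood.

    The scale is profiled out (its MLE given the shape is mean/shape); the
    log-shape gets a quadratic penalty centered at 0 worth ``prior_weight``
    pseudo-observations, anchoring the fit at the exponential null unless
    the data pull away from it.
    """
    n = x.size
    sum_x = float(x.sum())
    sum_logx = float(np.log(x).sum())

    def neg_penalized_profile(log_a: float) -> float:
        a = math.exp(log_a)
        s = sum_x / (n * a)
        ll = (a - 1) * sum_logx - n * a - n * (a * math.log(s) + gammaln(a))
        return -ll + 0.5 * prior_weight * log_a * log_a

    res = minimize_scalar(neg_penalized_profile, bounds=(0.0, 3.0), method="bounded")
    shape = math.exp(res.x)
    return shape, sum_x / (n * shape)


def _histogram_density(durations: np.ndarray):
    """Alternative histogram estimator of f-hat (config flag)."""
    x = _as_positive_array(durations)
    counts, edges = np.histogram(x, bins="auto", density=True)
    # floor at a small positive value so posteriors stay defined
    floor = 0.5 / (x.size * (edges[-1] - edges[0]))
    counts = np.maximum(counts, floor)

    def density(v):
        vv = np.atleast_1d(np.asarray(v, dtype=float))
        idx = np.clip(np.searchsorted(edges, vv, side="right") - 1, 0, counts.size - 1)
        res = counts[idx]
        return res if np.ndim(v) else float(res[0])

    return density


def fit_conservative_prior(
    durations: Sequence[float],
    rate: float,
    density: Callable | None = None,
) -> float:
    """Largest prior null probability keeping all posteriors non-negative."""
    x = _as_positive_array(durations)
    if density is None:
        density = fit_density(x)
    f0 = rate * np.exp(-rate * x)
    fhat = np.asarray(density(x), dtype=float)
    ratio = fhat / f0
    return float(min(1.0, np.min(ratio)))


@dataclass
class EBModel:
    """Fitted exponential-null mixture for one homology dimension."""

    rate: float
    p0: float
    durations: np.ndarray
    dim: int | None = None
    density: Callable = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must be in (0, 1]")
        if self.density is None:
            self.density = fit_density(self.durations)

    def null_density(self, x):
        x = np.asarray(x, dtype=float)
        return self.rate * np.exp(-self.rate * x)

    def posterior(self, x):
        """Posterior probability that duration x arises from the alternative."""
        arr = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(arr < 0):
            raise ValueError("durations must be non-negative")
        fhat = np.asarray(self.density(arr), dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            post = 1.0 - self.p0 * self.null_density(arr) / fhat
        post = np.where(fhat <= 0, 1.0, post)
        post = np.clip(post, 0.0, 1.0)
        return post if np.ndim(x) else float(post[0])

    def summary(self) -> dict:
        return {
            "dim": self.dim,
            "rate": self.rate,
            "p0": self.p0,
            "n": int(self.durations.size),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def fit_eb(
    durations: Sequence[float],
    dim: int | None = None,
    bandwidth: str | float = "silverman",
    estimator: str = "gamma",
) -> EBModel:
    """Fit the full empirical Bayes mixture to a set of positive durations."""
    x = _as_positive_array(durations)
    rate = fit_null_rate(x)
    if estimator == "histogram":
        density = _histogram_density(x)
    else:
        density = fit_density(x, bandwidth, estimator=estimator)
    p0 = fit_conservative_prior(x, rate, density)
    return EBModel(rate=rate, p0=p0, durations=x, dim=dim, density=density)


def posterior_alternative(model: EBModel, x) -> float:
    """Posterior probability that duration ``x`` arises from the alternative."""
    return model.posterior(x)


def score_barcodes(
    bars: BarcodeSet,
    pool_dimensions: bool = False,
    bandwidth: str | float = "silverman",
    estimator: str = "gamma",
) -> tuple[pd.DataFrame, dict[int, EBModel]]:
    """Score every finite bar in dimensions >= 1 with its posterior probability.

    One mixture model is fit per homology dimension (optionally pooled across
    dimensions via ``pool_dimensions``).  Returns the scored table sorted by
    posterior descending plus the fitted models keyed by dimension.
    Dimensions with fewer than 10 bars are scored but flagged ``unstable``.
    """
    rows = []
    models: dict[int, EBModel] = {}
    dims = [d for d in range(1, bars.max_dim + 1) if bars.finite(d)]
    if not dims:
        empty = pd.DataFrame(
            columns=["dim", "birth", "death", "duration", "posterior", "unstable"]
        )
        return empty, models

    pooled_model = None
    if pool_dimensions:
        pooled = np.concatenate([bars.durations(d) for d in dims])
        pooled_model = fit_eb(pooled, dim=None, bandwidth=bandwidth, estimator=estimator)

    for d in dims:
        durs = bars.durations(d)
        unstable = durs.size < MIN_DURATIONS
        if unstable:
            warnings.warn(
                f"dimension {d}: only {durs.size} finite bars; EB fit flagged unstable",
                stacklevel=2,
            )
        if pooled_model is not None:
            model = pooled_model
        elif durs.size >= 3 and np.ptp(np.log(durs)) > 0:
            model = fit_eb(durs, dim=d, bandwidth=bandwidth, estimator=estimator)
        else:
            continue
        models[d] = model
        for p in bars.finite(d):
            rows.append(
                {
                    "dim": d,
                    "birth": p.birth,
                    "death": p.death,
                    "duration": p.duration,
                    "posterior": model.posterior(p.duration),
                    "unstable": unstable,
                }
            )
    table = pd.DataFrame(rows).sort_values("posterior", ascending=False, kind="stable")
    return table.reset_index(drop=True), models
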