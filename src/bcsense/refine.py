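"""Refinement of raw camera BCS series: robust loess + Tukey outlier removal.

A camera can mis-score a cow badly (occlusion, posture, tag mis-read)
without returning an invalid value, so after sign-filtering a per-cow
robust smoother is fitted to the score-vs-time series and observations
whose residuals fall outside Tukey's fences are removed.  The smoother is
local quadratic regression (loess) with tricube neighbourhood weights and
iterated bisquare down-weighting of large residuals ("symmetric" family),
so the fitted trend itself is barely influenced by the very points the rule
is meant to flag, while genuine body-condition trends over time are
followed.

This is deliberately different from the vendor's trimmed rolling average
(:func:`bcsense.records.vendor_rolling_average`), which discards a fixed
20% of each window tail whether or not anything is outlying.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import observation_times

logger = logging.getLogger(__name__)

#: minimum series length for a quadratic loess fit
def _min_points(degree: int) -> int:
    return max(degree + 2, 4)


@dataclass(frozen=True)
class LoessFit:
    """Result of one robust loess fit."""

    times: np.ndarray
    observed: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    robustness_weights: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.residuals, self.observed - self.fitted, equal_nan=True):
            raise ValueError("residuals must equal observed - fitted")


def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return out


def _bisquare(u: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - u**2, 0.0, None) ** 2


def robust_loess(
    times,
    values,
    span: float = 0.5,
    degree: int = 2,
    robust_iterations: int = 4,
) -> LoessFit:
    """Robust local polynomial smoother evaluated at the observation times.

    At each point, a weighted polynomial of the given degree is fitted to
    the ``ceil(span * n)`` nearest neighbours with tricube weights scaled by
    the neighbourhood radius.  After the initial fit, ``robust_iterations``
    rounds of bisquare reweighting (weights ``(1-(r/6m)^2)^2`` with ``m``
    the median absolute residual) damp the influence of outlying points.

    Ties in ``times`` are permitted; strict ordering is not required but
    times should be distinct for a well-conditioned local fit (AM/PM scores
    get fractional-day offsets upstream).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    n = t.size
    if y.size != n:
        raise ValueError("times and values must have equal length")
    if n < _min_points(degree):
        raise ValueError(f"robust_loess needs >= {_min_points(degree)} points, got {n}")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")

    k = min(n, int(np.ceil(span * n)))
    k = max(k, degree + 1)

    order = np.argsort(t, kind="stable")
    ts, ys = t[order], y[order]
    delta = np.ones(n)  # robustness weights, in sorted order

    fitted_s = np.empty(n)
    for iteration in range(robust_iterations + 1):
        for i in range(n):
            fitted_s[i] = _local_fit(ts, ys, delta, i, k, degree)
        resid = ys - fitted_s
        if iteration < robust_iterations:
            s = np.median(np.abs(resid))
            if s <= 0:
                delta = np.ones(n)
            else:
                delta = _bisquare(resid / (6.0 * s))

    # map back to the input order
    fitted = np.empty(n)
    fitted[order] = fitted_s
    robustness = np.empty(n)
    robustness[order] = delta
    return LoessFit(
        times=t,
        observed=y,
        fitted=fitted,
        residuals=y - fitted,
        robustness_weights=robustness,
    )


def _local_fit(ts, ys, delta, i, k, degree) -> float:
    """Weighted polynomial fit around point i, returning the fit at ts[i]."""
    d = np.abs(ts - ts[i])
    # k nearest neighbours (partition keeps this O(n))
    idx = np.argpartition(d, k - 1)[:k]
    h = d[idx].max()
    if h <= 0:
        w = delta[idx]
    else:
        w = _tricube(d[idx] / h) * delta[idx]
    wsum = w.sum()
    if wsum <= 0:  # every neighbour fully down-weighted: fall back to plain kernel
        w = _tricube(d[idx] / h) if h > 0 else np.ones(idx.size)
    x = ts[idx] - ts[i]  # centre for conditioning; fit at x = 0
    X = np.vander(x, degree + 1, increasing=True)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], ys[idx] * sw, rcond=None)
    return float(beta[0])


def tukey_outliers(residuals, k: float = 1.5) -> np.ndarray:
    """Flag residuals outside Tukey's fences Q1 - k*IQR, Q3 + k*IQR.

    Quartiles are linearly interpolated order statistics (type 7, the numpy
    default) — stated because quartile conventions change flags on tiny
    samples.  With fewer than 4 residuals no flags are raised and a warning
    is emitted.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 4:
        warnings.warn(
            f"tukey_outliers: need >= 4 residuals for quartiles, got {r.size}; "
            "no points flagged",
            stacklevel=2,
        )
        return np.zeros(r.size, dtype=bool)
    q1, q3 = np.percentile(r, [25, 75])
    iqr = q3 - q1
    return (r < q1 - k * iqr) | (r > q3 + k * iqr)


def refine_cow_series(
    records: pd.DataFrame,
    span: float = 0.5,
    tukey_k: float = 1.5,
    degree: int = 2,
    robust_iterations: int = 4,
    pool_residuals: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cow loess refinement of validity-filtered camera records.

    For each cow a robust loess is fitted to its score-vs-time series and
    observations flagged by Tukey's rule on the fit residuals are removed.
    Returns ``(refined, removed)``: a disjoint, exhaustive partition of the
    input rows.  Cows with too few points for the smoother are kept
    unrefined (logged).  Deterministic.

    ``pool_residuals=True`` computes a single set of fences from all cows'
    residuals instead of per-cow fences (off by default: the smoother — and
    the residual spread it leaves — is per cow).
    """
    if records.empty:
        return records.copy(), records.iloc[0:0].copy()
    df = records.reset_index(drop=True)
    times = observation_times(df)

    residuals = np.full(len(df), np.nan)
    fittable = np.zeros(len(df), dtype=bool)
    for animal, idx in df.groupby("animal_id").groups.items():
        idx = np.asarray(idx)
        if idx.size < _min_points(degree):
            logger.warning(
                "cow %s has %d points (< %d); kept unrefined",
                animal, idx.size, _min_points(degree),
            )
            continue
        fit = robust_loess(
            times[idx], df["value"].to_numpy()[idx],
            span=span, degree=degree, robust_iterations=robust_iterations,
        )
        residuals[idx] = fit.residuals
        fittable[idx] = True

    flags = np.zeros(len(df), dtype=bool)
    if pool_residuals:
        if fittable.any():
            flags[fittable] = tukey_outliers(residuals[fittable], k=tukey_k)
    else:
        for animal, idx in df.groupby("animal_id").groups.items():
            idx = np.asarray(idx)
            sub = idx[fittable[idx]]
            if sub.size:
                flags[sub] = tukey_outliers(residuals[sub], k=tukey_k)

    refined = df[~flags].reset_index(drop=True)
    removed = df[flags].reset_index(drop=True)
    logger.info(
        "refinement removed %d of %d records (%.1f%%)",
        len(removed), len(df), 100.0 * len(removed) / len(df),
    )
    return refined, removed
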