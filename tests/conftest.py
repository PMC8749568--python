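"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bcsense.simulate import GenerativeModel, HerdDesign


@pytest.fixture(scope="session")
def small_design() -> HerdDesign:
    """A reduced herd for fast end-to-end runs."""
    return HerdDesign(n_animals=8, n_weeks=4)


@pytest.fixture(scope="session")
def default_model() -> GenerativeModel:
    return GenerativeModel()


def make_records(
    values,
    animal="cow001",
    week=1,
    day=1,
    milking="AM",
    method="camera",
    device="cam1",
) -> pd.DataFrame:
    """Build a minimal record frame with the given values.

    Scalar key arguments broadcast; list arguments must match len(values).
    """
    n = len(values)

    def broadcast(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    return pd.DataFrame(
        {
            "animal_id": broadcast(animal),
            "week": broadcast(week),
            "day_in_week": broadcast(day),
            "milking": broadcast(milking),
            "method": broadcast(method),
            "device_id": broadcast(device),
            "value": list(values),
            "scale": ["s8"] * n,
        }
    )


# ---------------------------------------------------------------------------
# independent oracles


def loess_oracle(times, values, span=0.5, degree=2, robust_iterations=4):
    """Plain-loop robust loess: per-point tricube WLS with bisquare reweighting.

    Written independently of the package implementation (full sorts, no
    partial selection, polynomial solve via numpy polyfit weights trick).
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    n = t.size
    k = max(int(np.ceil(span * n)), degree + 1)
    delta = np.ones(n)
    fitted = np.zeros(n)
    for it in range(robust_iterations + 1):
        for i in range(n):
            d = np.abs(t - t[i])
            nearest = np.argsort(d, kind="stable")[:k]
            h = d[nearest].max()
            if h > 0:
                w = (1 - (d[nearest] / h) ** 3) ** 3
                w[w < 0] = 0.0
            else:
                w = np.ones(k)
            w = w * delta[nearest]
            if w.sum() <= 0:
                w = (1 - (d[nearest] / h) ** 3) ** 3 if h > 0 else np.ones(k)
            # weighted polynomial fit centred at t[i]
            xs = t[nearest] - t[i]
            coeffs = np.polynomial.polynomial.polyfit(xs, y[nearest], degree, w=np.sqrt(w))
            fitted[i] = coeffs[0]
        resid = y - fitted
        if it < robust_iterations:
            s = np.median(np.abs(resid))
            if s <= 0:
                delta = np.ones(n)
            else:
                u = resid / (6.0 * s)
                delta = np.clip(1 - u**2, 0, None) ** 2
    return fitted


def one_way_anova_components(y: np.ndarray, groups: int, reps: int):
    """Closed-form expected-mean-squares estimators for a balanced one-way
    random-effects layout."""
    m = y.reshape(groups, reps)
    gbar = m.mean(axis=1)
    msa = reps * np.var(gbar, ddof=1)
    mse = np.sum((m - gbar[:, None]) ** 2) / (groups * (reps - 1))
    return (msa - mse) / reps, mse


def two_way_anova_components(y: np.ndarray, a: int, b: int, r: int):
    """EMS estimators for a balanced crossed two-way random layout
    (a x b cells, r reps): returns (sigma2_A, sigma2_B, sigma2_AB, sigma2_e)."""
    m = y.reshape(a, b, r)
    cell = m.mean(axis=2)
    abar = cell.mean(axis=1)
    bbar = cell.mean(axis=0)
    grand = cell.mean()
    msa = b * r * np.var(abar, ddof=1)
    msb = a * r * np.var(bbar, ddof=1)
    msab = r * np.sum((cell - abar[:, None] - bbar[None, :] + grand) ** 2) / ((a - 1) * (b - 1))
    mse = np.sum((m - cell[:, :, None]) ** 2) / (a * b * (r - 1))
    return (msa - msab) / (b * r), (msb - msab) / (a * r), (msab - mse) / r, mse
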