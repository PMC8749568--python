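"""Measurement sensitivity: compose variance components into signal and
error SDs of a cow-by-week mean, and derive comparison statistics.

The sensitivity of a measurement method (Mandel-Stiehler ratio) is

    Theta = sigma_a / sigma_m,

where sigma_a is the standard deviation of the *actual* quantity being
tracked and sigma_m the standard error of the reported cow-by-week mean.
Both are assembled from the variance components of the method's crossed
random-effects model:

* actual variance — for changes within a cow over time,
  sigma_a^2 = sigma_W^2 + sigma_WA^2; for differences between cows within a
  week, sigma_a^2 = sigma_A^2 + sigma_WA^2;
* error variance — sigma_m^2 = sum over the error terms of sigma_i^2 / n_i,
  where n_i is the number of independent draws of that effect averaged into
  one cow-week mean (e.g. 7 days, 2 camera units, 14 scores for the camera
  design; 3 scorers for the visual design).

Main effects of the measuring device (camera unit, scorer) are excluded
from sigma_m: a consistent per-device offset acts as a block effect
(scorers are orthogonal to cow-by-week; a camera offset can be blocked out)
and does not degrade comparisons over weeks or between cows.

Theta is dimensionless and invariant to affine rescaling of the score
scale.  The ratio of two methods' sensitivities, RS = Theta_1 / Theta_2,
gives via RS^2 the factor by which the weaker method's sampling intensity
would have to grow to match the stronger one.  With a rate of change beta
(BCS/month), a change becomes detectable — taken as 3 sigma_m — after
t = 3 sigma_m / |beta| months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import CAMERA, VISUAL

DAYS_PER_MONTH = 30.44  # 365.25 / 12

CHANGE_OVER_TIME = "change_over_time"
BETWEEN_ANIMALS = "between_animals"

#: terms whose variance is "actual" signal for each contrast
ACTUAL_TERMS = {
    CHANGE_OVER_TIME: ("W", "WA"),
    BETWEEN_ANIMALS: ("A", "WA"),
}

#: replication count of each factor within one cow-week mean
@dataclass(frozen=True)
class SamplingDesign:
    """Per-factor replication feeding the error-variance divisors."""

    n_scorers: int = 3
    n_days: int = 7
    n_milkings: int = 2
    n_cameras: int = 2

    @property
    def camera_obs(self) -> int:
        return self.n_days * self.n_milkings

    @property
    def visual_obs(self) -> int:
        return self.n_scorers


#: error terms per (method, contrast); divisor factor letters resolved at runtime
_ERROR_TERMS = {
    (CAMERA, CHANGE_OVER_TIME): (
        "WD", "WC", "WDM", "WDA", "WDC", "WAC", "WDMA", "WDMC", "WDAC", "WDMAC", "eps",
    ),
    (CAMERA, BETWEEN_ANIMALS): ("AC", "WDA", "WAC", "WDMA", "WDAC", "WDMAC", "eps"),
    (VISUAL, CHANGE_OVER_TIME): ("WS", "eps"),
    (VISUAL, BETWEEN_ANIMALS): ("AS", "eps"),
}


@dataclass(frozen=True)
class ContrastSpec:
    """One method x contrast combination with its error-term divisors."""

    kind: str
    method: str
    divisors: dict[str, int]

    def __post_init__(self) -> None:
        for term, n in self.divisors.items():
            if n < 1:
                raise ValueError(f"divisor for {term} must be >= 1, got {n}")


def _camera_divisor(term: str, design: SamplingDesign) -> int:
    """Independent draws of `term` averaged into one camera cow-week mean.

    Replicated factors within a cow-week are days (n_days), milkings
    (n_milkings) and camera units (n_cameras); the count is their product
    over the factors appearing in the term, capped at the number of scores.
    """
    reps = {"D": design.n_days, "M": design.n_milkings, "C": design.n_cameras}
    n = 1
    for f in term:
        n *= reps.get(f, 1)
    if term == "eps":
        n = design.camera_obs
    return min(n, design.camera_obs)


def contrast_spec(method: str, kind: str, design: SamplingDesign | None = None) -> ContrastSpec:
    """Build the error-term divisor map for a method and contrast."""
    design = design if design is not None else SamplingDesign()
    if kind not in ACTUAL_TERMS:
        raise ValueError(f"unknown contrast kind {kind!r}")
    try:
        error_terms = _ERROR_TERMS[(method, kind)]
    except KeyError:
        raise ValueError(f"unknown method {method!r}") from None
    if method == CAMERA:
        divisors = {t: _camera_divisor(t, design) for t in error_terms}
    else:
        divisors = {t: design.visual_obs for t in error_terms}
    return ContrastSpec(kind=kind, method=method, divisors=divisors)


def actual_sd(components: dict[str, float], kind: str) -> float:
    """sigma_a: SD of the true signal for the given contrast."""
    try:
        terms = ACTUAL_TERMS[kind]
    except KeyError:
        raise ValueError(f"unknown contrast kind {kind!r}") from None
    missing = [t for t in terms if t not in components]
    if missing:
        raise KeyError(f"components missing term(s): {', '.join(missing)}")
    return math.sqrt(sum(components[t] for t in terms))


def error_sd(components: dict[str, float], contrast: ContrastSpec) -> float:
    """sigma_m: standard error of a cow-by-week mean for the given contrast.

    sqrt of sum(sigma_i^2 / n_i) over the contrast's error terms.  Terms
    absent from ``components`` raise; a divisor missing for an included
    term raises.
    """
    total = 0.0
    for term, n in contrast.divisors.items():
        if term not in components:
            raise KeyError(f"components missing error term {term!r}")
        total += components[term] / n
    return math.sqrt(total)


def sensitivity(sigma_a: float, sigma_m: float) -> float:
    """Theta = sigma_a / sigma_m; undefined (raises) when sigma_m == 0."""
    if sigma_m <= 0:
        raise ZeroDivisionError("sensitivity undefined for sigma_m <= 0")
    return sigma_a / sigma_m


def relative_sensitivity(theta_test: float, theta_reference: float) -> float:
    """RS = Theta_test / Theta_reference."""
    if theta_reference <= 0:
        raise ZeroDivisionError("relative sensitivity undefined for zero reference")
    return theta_test / theta_reference


def equivalent_samplers(rs: float, n_current: int) -> int:
    """Samplers the weaker method needs to match the stronger: RS^2 * n."""
    if rs <= 0:
        raise ValueError(f"rs must be > 0, got {rs}")
    if n_current < 1:
        raise ValueError(f"n_current must be >= 1, got {n_current}")
    return int(round(rs * rs * n_current))


def rate_of_change(weekly_means: pd.DataFrame) -> float:
    """beta: pooled OLS slope of cow-by-week mean BCS on time, per month.

    ``weekly_means`` as produced by
    :func:`bcsense.records.weekly_animal_means`.  Times are week midpoints
    converted to months (30.44 d).  A single common slope is fitted across
    all cows.
    """
    if weekly_means["week"].nunique() < 2:
        raise ValueError("rate_of_change needs at least two distinct weeks")
    t = (weekly_means["week"].to_numpy(dtype=float) - 1.0) * 7.0 / DAYS_PER_MONTH
    y = weekly_means["mean_value"].to_numpy(dtype=float)
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def time_to_detect(
    sigma_m: float,
    beta: float,
    multiplier: float = 3.0,
    days_per_month: float = DAYS_PER_MONTH,
) -> float:
    """Days until a body-condition change of ``multiplier * sigma_m`` accrues.

    t = multiplier * sigma_m / |beta| months, converted to days and rounded
    to the nearest integer.  ``beta = 0`` yields ``inf`` (no trend, nothing
    to detect), not an exception.
    """
    if sigma_m < 0:
        raise ValueError("sigma_m must be >= 0")
    if beta == 0:
        return math.inf if sigma_m > 0 else 0.0
    months = multiplier * sigma_m / abs(beta)
    return float(round(months * days_per_month))


@dataclass(frozen=True)
class SensitivityReport:
    """Sensitivity summary for one method and contrast."""

    method: str
    kind: str
    sigma_a: float
    sigma_m: float
    theta: float
    beta: float | None = None
    detect_days: float | None = None
    rs_vs_reference: float | None = None
    equivalent_samplers: int | None = None


def sensitivity_report(
    components: dict[str, float],
    method: str,
    kind: str,
    design: SamplingDesign | None = None,
    beta: float | None = None,
    reference_theta: float | None = None,
    n_reference_samplers: int = 3,
) -> SensitivityReport:
    """Assemble the full sensitivity summary for one method and contrast."""
    spec = contrast_spec(method, kind, design)
    sa = actual_sd(components, kind)
    sm = error_sd(components, spec)
    theta = sensitivity(sa, sm)
    rs = detect = n_eq = None
    if reference_theta is not None:
        rs = relative_sensitivity(theta, reference_theta)
        n_eq = equivalent_samplers(rs, n_reference_samplers)
    if beta is not None:
        detect = time_to_detect(sm, beta)
    return SensitivityReport(
        method=method,
        kind=kind,
        sigma_a=sa,
        sigma_m=sm,
        theta=theta,
        beta=beta,
        detect_days=detect,
        rs_vs_reference=rs,
        equivalent_samplers=n_eq,
    )


def summary_from_components(
    components_by_method: dict[str, dict[str, float]],
    betas: dict[str, float] | None = None,
    design: SamplingDesign | None = None,
    reference_method: str | None = None,
    camera_like: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Recompute the full summary table from a variance-components table.

    ``components_by_method`` maps column names (e.g. raw_camera,
    refined_camera, visual) to term->sigma^2 maps.  Methods containing
    camera terms use the camera error formulas, the rest the visual ones.
    The visual-like ``reference_method`` (auto-detected if unique) anchors
    relative sensitivity and equivalent-sampler counts.

    Returns a tidy frame with one row per (method, contrast).
    """
    design = design if design is not None else SamplingDesign()
    betas = betas or {}
    if camera_like is None:
        camera_like = tuple(
            m for m, comps in components_by_method.items() if "C" in comps
        )
    visual_like = [m for m in components_by_method if m not in camera_like]
    if reference_method is None:
        if len(visual_like) != 1:
            raise ValueError("ambiguous reference method; pass reference_method")
        reference_method = visual_like[0]

    rows = []
    for kind in (CHANGE_OVER_TIME, BETWEEN_ANIMALS):
        ref_comps = components_by_method[reference_method]
        ref_model = VISUAL if reference_method not in camera_like else CAMERA
        ref_theta = sensitivity(
            actual_sd(ref_comps, kind),
            error_sd(ref_comps, contrast_spec(ref_model, kind, design)),
        )
        for name, comps in components_by_method.items():
            model = CAMERA if name in camera_like else VISUAL
            rep = sensitivity_report(
                comps,
                method=model,
                kind=kind,
                design=design,
                beta=betas.get(name),
                reference_theta=ref_theta if name != reference_method else None,
                n_reference_samplers=design.visual_obs,
            )
            rows.append(
                {
                    "method": name,
                    "contrast": kind,
                    "sigma_a": rep.sigma_a,
                    "sigma_m": rep.sigma_m,
                    "theta": rep.theta,
                    "rs_vs_reference": rep.rs_vs_reference,
                    "beta_per_month": rep.beta,
                    "detect_days": rep.detect_days,
                    "equivalent_samplers": rep.equivalent_samplers,
                }
            )
    return pd.DataFrame(rows)
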