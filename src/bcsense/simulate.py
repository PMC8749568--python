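"""Synthetic herd generator.

Emulates the study design the analysis pipeline assumes: a herd of cows in
early lactation scored on the 1-8 BCS scale by two routes —

* a 3D camera at each of two daily milkings, the cow self-selecting one of
  the camera units at random each time, and
* a weekly panel of independent visual scorers, all scoring on one day.

Each score is generated from a Gaussian crossed random-effects model: a
grand mean, a linear decline in time (early-lactation body-condition loss),
zero-mean Gaussian effects for every term of the method's sampling
structure, and a residual.  The biological terms — week, animal and
week-by-animal — describe the cows themselves and are therefore *shared*
between the camera and visual records of the same herd; measurement terms
and residuals are method-specific and independent.

Camera contamination is modelled separately by :func:`inject_contamination`:
a fraction of records is replaced by invalid (zero/negative) readings, and
an independent fraction is shifted by several residual standard deviations
(outliers).  Labels are retained so refinement can be scored against truth.

Default parameters are the reference-herd estimates (see
:mod:`bcsense.reference`): 32 cows, 7 weeks, 14 camera scores and 3 visual
scores per cow-week, a decline of 0.19 BCS/month, the refined-camera
variance components for the biological and camera-measurement process, the
visual components for the scorer panel, 8% invalid and 7% outlying camera
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .records import AM, CAMERA, PM, RECORD_COLUMNS, SCALE_8, VISUAL

DAYS_PER_MONTH = 30.44  # 365.25 / 12

#: biological terms shared between measurement methods
BIOLOGICAL_TERMS = ("W", "A", "WA")
#: camera-specific measurement terms (residual last)
CAMERA_MEASUREMENT_TERMS = (
    "C", "WD", "WC", "AC", "WDM", "WDA", "WDC", "WAC",
    "WDMA", "WDMC", "WDAC", "WDMAC", "eps",
)
#: visual-specific measurement terms (residual last)
VISUAL_MEASUREMENT_TERMS = ("S", "WS", "AS", "eps")

#: dimension key of each factor letter inside the generator
_FACTOR_FIELDS = {"W": "w", "D": "d", "M": "m", "A": "a", "C": "c", "S": "s"}


def _default_biological() -> dict[str, float]:
    comps = reference.load_reference_components()[reference.REFINED_CAMERA]
    return {t: comps[t] for t in BIOLOGICAL_TERMS}


def _default_camera_measurement() -> dict[str, float]:
    comps = reference.load_reference_components()[reference.REFINED_CAMERA]
    return {t: comps[t] for t in CAMERA_MEASUREMENT_TERMS}


def _default_visual_measurement() -> dict[str, float]:
    comps = reference.load_reference_components()[reference.VISUAL_METHOD]
    return {t: comps[t] for t in VISUAL_MEASUREMENT_TERMS}


def _default_outlier_reference_sd() -> float:
    """Raw-camera single-measurement residual SD from the reference herd.

    Outlying camera passes are gross scoring failures of the *raw* signal,
    so their size is expressed in multiples of the raw-data residual SD
    (~0.15 BCS), not of the much smaller refined residual.
    """
    comps = reference.load_reference_components()[reference.RAW_CAMERA]
    return float(np.sqrt(comps["eps"]))


@dataclass(frozen=True)
class HerdDesign:
    """Replication counts of the sampling design."""

    n_animals: int = 32
    n_weeks: int = 7
    days_per_week: int = 7
    milkings_per_day: int = 2
    n_cameras: int = 2
    n_scorers: int = 3
    visual_days_per_week: int = 1

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 1:
                raise ValueError(f"design count {name} must be >= 1, got {value}")

    @property
    def camera_obs_per_cow_week(self) -> int:
        return self.days_per_week * self.milkings_per_day

    @property
    def visual_obs_per_cow_week(self) -> int:
        return self.n_scorers * self.visual_days_per_week


@dataclass(frozen=True)
class GenerativeModel:
    """Parameters of the generative crossed random-effects model.

    Variances are absolute BCS^2; ``trend_slope`` is BCS per month;
    ``outlier_magnitude`` is in multiples of ``outlier_reference_sd``, which
    defaults to the raw-camera single-measurement residual SD of the
    reference herd (~0.15 BCS).
    """

    grand_mean: float = 4.5
    trend_slope: float = -0.19
    biological: dict[str, float] = field(default_factory=_default_biological)
    camera_measurement: dict[str, float] = field(default_factory=_default_camera_measurement)
    visual_measurement: dict[str, float] = field(default_factory=_default_visual_measurement)
    outlier_rate: float = 0.07
    outlier_magnitude: float = 4.0
    outlier_reference_sd: float = field(default_factory=_default_outlier_reference_sd)
    invalid_rate: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for rate_name in ("outlier_rate", "invalid_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{rate_name} must be in [0, 1], got {rate}")
        for group in (self.biological, self.camera_measurement, self.visual_measurement):
            for term, sigma2 in group.items():
                if sigma2 < 0:
                    raise ValueError(f"variance component {term} must be >= 0, got {sigma2}")

    def true_components(self, method: str) -> dict[str, float]:
        """Full generative term -> sigma^2 map for one method."""
        if method == CAMERA:
            return {**self.biological, **self.camera_measurement}
        if method == VISUAL:
            return {**self.biological, **self.visual_measurement}
        raise ValueError(f"unknown method {method!r}")


def _animal_ids(n: int) -> np.ndarray:
    return np.array([f"cow{i + 1:03d}" for i in range(n)])


def _term_effects(
    rng: np.random.Generator,
    term: str,
    sigma2: float,
    codes: dict[str, np.ndarray],
    dims: dict[str, int],
) -> np.ndarray:
    """Sample one zero-mean effect per realized level and broadcast to records.

    Levels are indexed over the full factorial of the term's factors so that
    the draw order (and hence reproducibility) does not depend on which
    cells happen to be observed.
    """
    factors = [f for f in term if f in _FACTOR_FIELDS]
    shape = [dims[_FACTOR_FIELDS[f]] for f in factors]
    level_effects = rng.normal(0.0, np.sqrt(sigma2), size=int(np.prod(shape)))
    idx = np.ravel_multi_index(
        tuple(codes[_FACTOR_FIELDS[f]] for f in factors), tuple(shape)
    )
    return level_effects[idx]


def simulate_herd(
    design: HerdDesign,
    model: GenerativeModel,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate clean (uncontaminated) camera and visual record frames.

    Biological effects (week, animal, week-by-animal, trend) are drawn once
    and shared by both methods; measurement effects and residuals are drawn
    independently per method.  Fully reproducible: the same seed yields
    byte-identical frames.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    dims = {
        "w": design.n_weeks,
        "d": design.days_per_week,
        "m": design.milkings_per_day,
        "a": design.n_animals,
        "c": design.n_cameras,
        "s": design.n_scorers,
    }
    animals = _animal_ids(design.n_animals)

    # biological effects, one draw per level, shared by both methods
    bio = {
        "W": rng.normal(0, np.sqrt(model.biological.get("W", 0.0)), design.n_weeks),
        "A": rng.normal(0, np.sqrt(model.biological.get("A", 0.0)), design.n_animals),
        "WA": rng.normal(
            0, np.sqrt(model.biological.get("WA", 0.0)),
            design.n_weeks * design.n_animals,
        ),
    }

    # ---- camera records: full factorial week x day x milking x animal ----
    w, d, m, a = np.meshgrid(
        np.arange(design.n_weeks),
        np.arange(design.days_per_week),
        np.arange(design.milkings_per_day),
        np.arange(design.n_animals),
        indexing="ij",
    )
    w, d, m, a = (x.ravel() for x in (w, d, m, a))
    n_cam = w.size
    c = rng.integers(0, design.n_cameras, size=n_cam)  # self-selected unit
    codes = {"w": w, "d": d, "m": m, "a": a, "c": c}

    t_days = w * 7 + d + np.where(m == 0, 0.25, 0.75)
    value = model.grand_mean + model.trend_slope * t_days / DAYS_PER_MONTH
    value = value + bio["W"][w] + bio["A"][a]
    value = value + bio["WA"][np.ravel_multi_index((w, a), (design.n_weeks, design.n_animals))]
    for term in CAMERA_MEASUREMENT_TERMS[:-1]:
        sigma2 = model.camera_measurement.get(term, 0.0)
        if sigma2 > 0:
            value = value + _term_effects(rng, term, sigma2, codes, dims)
        else:
            # keep the stream layout fixed so zeroing one component does not
            # reshuffle every other draw
            _term_effects(rng, term, 0.0, codes, dims)
    value = value + rng.normal(0, np.sqrt(model.camera_measurement.get("eps", 0.0)), n_cam)

    camera = pd.DataFrame(
        {
            "animal_id": animals[a],
            "week": w + 1,
            "day_in_week": d + 1,
            "milking": np.where(m == 0, AM, PM),
            "method": CAMERA,
            "device_id": np.char.add("cam", (c + 1).astype(str)),
            "value": value,
            "scale": SCALE_8,
        }
    )[RECORD_COLUMNS]

    # ---- visual records: week x scoring-day x animal x scorer ----
    visual_days = _visual_days(design)
    w, d, a, s = np.meshgrid(
        np.arange(design.n_weeks),
        np.arange(len(visual_days)),
        np.arange(design.n_animals),
        np.arange(design.n_scorers),
        indexing="ij",
    )
    w, d, a, s = (x.ravel() for x in (w, d, a, s))
    day_idx = np.asarray(visual_days)[d]
    codes_v = {"w": w, "d": day_idx, "a": a, "s": s}

    t_days = w * 7 + day_idx + 0.5
    value = model.grand_mean + model.trend_slope * t_days / DAYS_PER_MONTH
    value = value + bio["W"][w] + bio["A"][a]
    value = value + bio["WA"][np.ravel_multi_index((w, a), (design.n_weeks, design.n_animals))]
    for term in VISUAL_MEASUREMENT_TERMS[:-1]:
        sigma2 = model.visual_measurement.get(term, 0.0)
        value = value + _term_effects(rng, term, sigma2, codes_v, dims)
    value = value + rng.normal(
        0, np.sqrt(model.visual_measurement.get("eps", 0.0)), w.size
    )

    visual = pd.DataFrame(
        {
            "animal_id": animals[a],
            "week": w + 1,
            "day_in_week": day_idx + 1,
            "milking": None,
            "method": VISUAL,
            "device_id": np.char.add("scorer", (s + 1).astype(str)),
            "value": value,
            "scale": SCALE_8,
        }
    )[RECORD_COLUMNS]

    return camera, visual


def _visual_days(design: HerdDesign) -> list[int]:
    """0-based scoring days, spread evenly through the week (day 1 if weekly)."""
    k = design.visual_days_per_week
    step = design.days_per_week / k
    return [int(i * step) for i in range(k)]


def inject_contamination(
    records: pd.DataFrame,
    model: GenerativeModel,
    seed: int | None = None,
) -> pd.DataFrame:
    """Contaminate clean camera records with invalid values and outliers.

    Each record is independently made *invalid* with probability
    ``invalid_rate`` (value replaced by 0 with probability 1/2, otherwise a
    uniform draw from (-1, 0) — the magnitude is irrelevant since validity
    filtering acts on the sign) and, independently, made an *outlier* with
    probability ``outlier_rate`` (value shifted by ``±outlier_magnitude *
    outlier_reference_sd``, sign equiprobable).  A record hit by both is
    labelled invalid.  Returns a copy with a ``label`` column in
    {"clean", "outlier", "invalid"}.
    """
    rng = np.random.default_rng((model.seed if seed is None else seed) + 0x5EED)
    out = records.copy().reset_index(drop=True)
    n = len(out)
    invalid = rng.random(n) < model.invalid_rate
    outlier = rng.random(n) < model.outlier_rate
    outlier &= ~invalid

    values = out["value"].to_numpy(dtype=float).copy()
    zero_or_neg = rng.random(n) < 0.5
    neg_draw = rng.uniform(-1.0, 0.0, n)
    values[invalid] = np.where(zero_or_neg[invalid], 0.0, neg_draw[invalid])

    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    values[outlier] += sign[outlier] * model.outlier_magnitude * model.outlier_reference_sd

    out["value"] = values
    label = np.full(n, "clean", dtype=object)
    label[outlier] = "outlier"
    label[invalid] = "invalid"
    out["label"] = label
    return out


@dataclass(frozen=True)
class SimulatedStudy:
    """One simulated trial: contaminated camera data, visual data, truth."""

    camera_raw: pd.DataFrame  # contaminated, with `label` column
    camera_clean: pd.DataFrame  # pre-contamination
    visual: pd.DataFrame
    design: HerdDesign
    model: GenerativeModel
    seed: int


def simulate_study(
    design: HerdDesign | None = None,
    model: GenerativeModel | None = None,
    seed: int | None = None,
) -> SimulatedStudy:
    """Convenience wrapper: clean simulation plus camera contamination."""
    design = design if design is not None else HerdDesign()
    model = model if model is not None else GenerativeModel()
    use_seed = model.seed if seed is None else seed
    camera_clean, visual = simulate_herd(design, model, seed=use_seed)
    camera_raw = inject_contamination(camera_clean, model, seed=use_seed)
    return SimulatedStudy(
        camera_raw=camera_raw,
        camera_clean=camera_clean,
        visual=visual,
        design=design,
        model=model,
        seed=use_seed,
    )
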