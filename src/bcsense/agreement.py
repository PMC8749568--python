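"""Agreement between measurement methods on cow-by-week means.

Pearson correlation measures linear association; Lin's concordance
correlation additionally penalises deviation from the identity line
(location and scale shifts); Bland-Altman analysis summarises the paired
differences themselves — mean difference, SD of differences, 95% limits of
agreement, and the slope of difference against pair mean (a trend here
indicates proportional bias or unequal error variances).

All statistics use sample (n-1) variances and covariances.  Differences are
oriented camera - visual throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementReport:
    """Paired agreement statistics between two methods."""

    n_pairs: int
    pearson_cc: float
    lins_ccc: float
    mean_difference: float
    sd_difference: float
    limits_95: tuple[float, float]
    diff_vs_mean_slope: float
    empirical_range_95: tuple[float, float]


def paired_weekly_means(
    camera_means: pd.DataFrame, visual_means: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join two weekly-means frames on (animal, week).

    Returns columns animal_id, week, camera, visual.  Unmatched keys are
    logged; an empty intersection raises.
    """
    left = camera_means[["animal_id", "week", "mean_value"]].rename(
        columns={"mean_value": "camera"}
    )
    right = visual_means[["animal_id", "week", "mean_value"]].rename(
        columns={"mean_value": "visual"}
    )
    merged = left.merge(right, on=["animal_id", "week"], how="outer", indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        logger.info(
            "paired_weekly_means: %d unmatched (animal, week) key(s) dropped",
            len(unmatched),
        )
    paired = merged[merged["_merge"] == "both"].drop(columns="_merge")
    if paired.empty:
        raise ValueError("no (animal, week) keys in common between the two methods")
    return paired.reset_index(drop=True)


def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2), sample (n-1)
    moments.  Undefined (raises) when both inputs are constant with equal
    means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("lins_ccc needs at least 3 pairs")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    denom = vx + vy + (np.mean(x) - np.mean(y)) ** 2
    if denom == 0:
        raise ZeroDivisionError("LCCC undefined: both inputs constant with equal means")
    cov = float(np.cov(x, y, ddof=1)[0, 1])
    return 2.0 * cov / denom


def bland_altman(x, y) -> AgreementReport:
    """Agreement report for paired values, differences oriented x - y.

    The 95% limits are the conventional mean ± 1.96 SD of the differences;
    the empirical 2.5%/97.5% quantile range is reported alongside.  The
    slope is the OLS slope of difference on pair mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("bland_altman needs at least 3 pairs")

    d = x - y
    m = (x + y) / 2.0
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    limits = (mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d)
    emp = tuple(np.percentile(d, [2.5, 97.5]))

    if np.var(m) > 0:
        slope = float(np.polyfit(m, d, 1)[0])
    else:
        slope = 0.0
    if np.var(x, ddof=1) > 0 and np.var(y, ddof=1) > 0:
        pearson = float(stats.pearsonr(x, y)[0])
    else:
        pearson = float("nan")
    try:
        ccc = lins_ccc(x, y)
    except ZeroDivisionError:
        ccc = float("nan")

    return AgreementReport(
        n_pairs=int(n),
        pearson_cc=pearson,
        lins_ccc=ccc,
        mean_difference=mean_d,
        sd_difference=sd_d,
        limits_95=limits,
        diff_vs_mean_slope=slope,
        empirical_range_95=(float(emp[0]), float(emp[1])),
    )


def agreement_report(paired: pd.DataFrame) -> AgreementReport:
    """Bland-Altman + correlation report from a paired weekly-means frame."""
    return bland_altman(paired["camera"].to_numpy(), paired["visual"].to_numpy())


def bland_altman_plot(paired: pd.DataFrame, path, report: AgreementReport | None = None):
    """Save a difference-vs-mean plot with mean line and 95% limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = report if report is not None else agreement_report(paired)
    x = paired["camera"].to_numpy()
    y = paired["visual"].to_numpy()
    d, m = x - y, (x + y) / 2.0

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(m, d, s=12, color="k")
    ax.axhline(rep.mean_difference, linestyle=":", color="k")
    for lim in rep.limits_95:
        ax.axhline(lim, linestyle=":", color="grey")
    coef = np.polyfit(m, d, 1)
    xs = np.linspace(m.min(), m.max(), 50)
    ax.plot(xs, np.polyval(coef, xs), "--", color="k")
    ax.set_xlabel("Mean of methods (BCS)")
    ax.set_ylabel("Camera - visual (BCS)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def scatter_plot(paired: pd.DataFrame, path):
    """Save camera-vs-visual weekly means with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = paired["visual"].to_numpy()
    y = paired["camera"].to_numpy()
    lo, hi = min(x.min(), y.min()), max(x.max(), y.max())

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=12, color="k")
    ax.plot([lo, hi], [lo, hi], "-", color="grey")
    ax.set_xlabel("Visual BCS (cow-week mean)")
    ax.set_ylabel("Camera BCS (cow-week mean)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
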