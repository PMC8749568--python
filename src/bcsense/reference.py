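"""Reference estimates from the motivating herd study.

A 32-cow early-lactation Holstein-Friesian herd was scored on the 1-8 BCS
scale for seven consecutive weeks by two measurement routes: an overhead 3D
camera at each of the twice-daily milkings (two self-selected camera units)
and a weekly panel of three trained visual scorers.  Crossed random-effects
models fitted to those data yielded the variance components shipped here,
for three data sets:

``raw_camera``      camera records with invalid (<= 0) values excluded
``refined_camera``  additionally loess-refined and Tukey-outlier-filtered
``visual``          the scorer panel

Shipped as package data (``data/reference_components.csv``, absolute BCS^2
units; ``data/reference_rates.csv`` with mean BCS and the fitted rate of
body-condition change in BCS/month).  These tables drive the generator
defaults and the summary reproduction, and anchor the exact-arithmetic
tests of the sensitivity formulas.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

RAW_CAMERA = "raw_camera"
REFINED_CAMERA = "refined_camera"
VISUAL_METHOD = "visual"

REFERENCE_METHODS = (RAW_CAMERA, REFINED_CAMERA, VISUAL_METHOD)


def _data_path(name: str):
    return resources.files("bcsense.data").joinpath(name)


def load_reference_components(path=None) -> dict[str, dict[str, float]]:
    """Reference variance components, ``{method: {term: sigma2}}`` in BCS^2.

    ``path`` may point at a user CSV with columns method,term,sigma2; by
    default the packaged table is used.
    """
    src = path if path is not None else _data_path("reference_components.csv")
    df = pd.read_csv(src)
    required = {"method", "term", "sigma2"}
    if not required.issubset(df.columns):
        raise ValueError(f"components table needs columns {sorted(required)}")
    out: dict[str, dict[str, float]] = {}
    for method, sub in df.groupby("method", sort=False):
        out[str(method)] = dict(zip(sub["term"], sub["sigma2"].astype(float)))
    return out


def load_reference_rates(path=None) -> pd.DataFrame:
    """Reference mean BCS and rate of change (BCS/month) per method."""
    src = path if path is not None else _data_path("reference_rates.csv")
    df = pd.read_csv(src)
    return df.set_index("method")
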