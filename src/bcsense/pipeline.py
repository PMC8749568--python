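"""End-to-end orchestration: simulate -> filter -> refine -> fit ->
sensitivity -> agreement.

`run_full_pipeline` produces, side by side, the three analyses the study
design supports — raw camera (invalid values excluded, outliers retained),
refined camera (loess + Tukey refinement applied) and visual — each with
its REML variance components, sensitivity summary for both contrasts, and
camera-vs-visual agreement on cow-by-week means.  Everything is
deterministic given the seed; every output file embeds the seed and a hash
of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import agreement as agr
from . import records as rec
from . import refine as ref
from . import varcomp as vc
from .sensitivity import SamplingDesign, rate_of_change, summary_from_components
from .reference import RAW_CAMERA, REFINED_CAMERA, VISUAL_METHOD
from .simulate import GenerativeModel, HerdDesign, simulate_study

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run depends on."""

    design: HerdDesign = field(default_factory=HerdDesign)
    model: GenerativeModel = field(default_factory=GenerativeModel)
    span: float = 0.5
    tukey_k: float = 1.5
    seed: int = 0
    out_dir: str | None = None
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = HerdDesign(**raw.get("design", {}))
        model_kwargs = dict(raw.get("model", {}))
        model = GenerativeModel(**model_kwargs)
        return cls(
            design=design,
            model=model,
            span=raw.get("span", 0.5),
            tukey_k=raw.get("tukey_k", 1.5),
            seed=raw.get("seed", 0),
            out_dir=raw.get("out_dir"),
            make_plots=raw.get("make_plots", False),
        )

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        payload = _as_jsonable(self)
        payload.pop("out_dir", None)
        payload.pop("make_plots", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


@dataclass
class PipelineResult:
    """Bundle of every stage's output for one run."""

    config: PipelineConfig
    counts: dict
    components: dict[str, vc.VarianceComponents]
    betas: dict[str, float]
    summary: pd.DataFrame
    agreement: dict[str, agr.AgreementReport]


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on one simulated study; optionally write outputs."""
    study = simulate_study(config.design, config.model, seed=config.seed)

    # stage 1: validity filter
    kept, rejected = rec.filter_valid(study.camera_raw)
    logger.info(
        "validity filter: %d camera records in, %d kept, %d removed (%.1f%%)",
        len(study.camera_raw), len(kept), len(rejected),
        100.0 * len(rejected) / max(len(study.camera_raw), 1),
    )

    # stage 2: refinement
    refined, removed = ref.refine_cow_series(
        kept.drop(columns="label"), span=config.span, tukey_k=config.tukey_k
    )
    logger.info(
        "refinement: %d records in, %d kept, %d removed (%.1f%%)",
        len(kept), len(refined), len(removed),
        100.0 * len(removed) / max(len(kept), 1),
    )
    raw_cam = kept.drop(columns="label")

    datasets = {
        RAW_CAMERA: raw_cam,
        REFINED_CAMERA: refined,
        VISUAL_METHOD: study.visual,
    }

    # stage 3: variance components
    components: dict[str, vc.VarianceComponents] = {}
    for name, df in datasets.items():
        try:
            # the generator carries a fixed trend; model it as such so the
            # week component estimates wobble, not the systematic decline
            components[name] = vc.reml_variance_components(df, fixed_trend=True)
        except (vc.ConvergenceError, vc.SingularModelError) as exc:
            raise RuntimeError(f"variance-component stage failed for {name}: {exc}") from exc

    # stage 4: sensitivity
    design = SamplingDesign(
        n_scorers=config.design.n_scorers,
        n_days=config.design.days_per_week,
        n_milkings=config.design.milkings_per_day,
        n_cameras=config.design.n_cameras,
    )
    betas = {
        name: rate_of_change(rec.weekly_animal_means(df))
        for name, df in datasets.items()
    }
    summary = summary_from_components(
        {name: c.estimates for name, c in components.items()},
        betas=betas,
        design=design,
        reference_method=VISUAL_METHOD,
        camera_like=(RAW_CAMERA, REFINED_CAMERA),
    )

    # stage 5: agreement (each camera data set against visual)
    visual_means = rec.weekly_animal_means(study.visual)
    agreement = {}
    for name in (RAW_CAMERA, REFINED_CAMERA):
        paired = agr.paired_weekly_means(
            rec.weekly_animal_means(datasets[name]), visual_means
        )
        agreement[name] = agr.agreement_report(paired)

    counts = {
        "camera_records": int(len(study.camera_raw)),
        "invalid_removed": int(len(rejected)),
        "outliers_removed": int(len(removed)),
        "refined_records": int(len(refined)),
        "visual_records": int(len(study.visual)),
    }
    result = PipelineResult(
        config=config,
        counts=counts,
        components=components,
        betas=betas,
        summary=summary,
        agreement=agreement,
    )
    if config.out_dir is not None:
        write_result(result, Path(config.out_dir), datasets=datasets, study=study)
    return result


def components_frame(components: dict[str, vc.VarianceComponents]) -> pd.DataFrame:
    """Long frame of estimates with a x100 view matching reporting convention."""
    rows = []
    for name, comp in components.items():
        for term, sigma2 in comp.estimates.items():
            rows.append(
                {
                    "method": name,
                    "term": term,
                    "sigma2": sigma2,
                    "sigma2_x100": 100.0 * sigma2,
                }
            )
    return pd.DataFrame(rows)


def write_result(
    result: PipelineResult,
    out_dir: Path,
    datasets: dict[str, pd.DataFrame] | None = None,
    study=None,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "seed": result.config.seed,
        "config_hash": result.config.config_hash(),
    }

    result.summary.to_csv(out_dir / "summary.csv", index=False)
    components_frame(result.components).to_csv(out_dir / "components.csv", index=False)
    if datasets is not None:
        for name, df in datasets.items():
            rec.write_bcs_table(df, out_dir / f"{name}.csv")
    if study is not None:
        study.camera_raw.to_csv(out_dir / "camera_raw_labelled.csv", index=False)

    report = {
        **provenance,
        "counts": result.counts,
        "betas": result.betas,
        "convergence": {
            name: {
                "iterations": c.iterations,
                "loglik": c.loglik,
                "converged": c.converged,
                "constrained": list(c.constrained),
            }
            for name, c in result.components.items()
        },
        "agreement": {
            name: dataclasses.asdict(rep) for name, rep in result.agreement.items()
        },
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def reproduce_reference_summary(
    components_path=None, rates_path=None
) -> pd.DataFrame:
    """Recompute the full summary table from the shipped reference
    variance components and rates of change (or user-supplied tables)."""
    from . import reference

    comps = reference.load_reference_components(components_path)
    rates = reference.load_reference_rates(rates_path)
    betas = rates["beta_per_month"].to_dict()
    return summary_from_components(
        comps,
        betas=betas,
        design=SamplingDesign(),
        reference_method=VISUAL_METHOD,
        camera_like=tuple(m for m in comps if "C" in comps[m]),
    )
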