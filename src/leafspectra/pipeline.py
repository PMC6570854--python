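"""End-to-end analysis pipeline and interchange I/O.

Orchestrates: simulate (or ingest) → trait indices → PVI ANOVA with
letters → SMA fits (all trait pairs plus LPI–LTI) → one multimodel-
inference run per requested response (the seven per-trait PVIs and the
LTI/LPI spectrum ratio).  All interchange files are plain CSV with
floats at 12 significant digits so a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indices import TRAIT_COLUMNS, TraitCategoryMap, build_index_table, validate_trait_table
from .mmi import MMIResult, PredictorSchema, run_mmi
from .regression import AnovaLetters, pvi_anova, sma_fit, sma_pairwise
from .synthetic import (
    DRIVER_COLUMNS,
    KEY_COLUMNS,
    EffectModel,
    SurveyBundle,
    SurveyDesign,
    aggregate_to_populations,
    simulate_survey,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"
#: Response identifiers: seven trait-variation responses plus the spectrum.
RESPONSES = tuple(TRAIT_COLUMNS) + ("spectrum",)


@dataclass
class AnalysisConfig:
    """Configuration for one pipeline run.

    ``scope`` selects the analysis unit: ``plot`` keeps the 300 plot
    pairs, ``population`` averages them to the 66 sites first.  PVI
    extremes are always taken over population means, matching a survey
    where trait extremes are defined among populations.
    """

    seed: int = 0
    scope: str = "plot"                       # "plot" | "population"
    responses: tuple[str, ...] = RESPONSES
    level: float = 0.95
    conditional_averaging: bool = False
    traits_csv: str | None = None             # simulate when None
    environment_csv: str | None = None
    log_sma_traits: bool = True

    def __post_init__(self) -> None:
        if self.scope not in ("plot", "population"):
            raise ValueError(f"scope must be 'plot' or 'population', got {self.scope!r}")
        unknown = set(self.responses) - set(RESPONSES)
        if unknown:
            raise ValueError(f"unknown responses {sorted(unknown)}; choose from {RESPONSES}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything one pipeline run computes."""

    config: AnalysisConfig
    indices: pd.DataFrame
    anova: AnovaLetters
    sma_fits: pd.DataFrame
    mmi_results: dict[str, MMIResult]
    failures: dict[str, str]
    metadata: dict


def write_csv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def write_survey(bundle: SurveyBundle, out_dir) -> None:
    """Write a SurveyBundle to traits.csv / environment.csv / pairs.csv / ground_truth.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_csv(bundle.trait_table, out / "traits.csv")
    write_csv(bundle.environment_table, out / "environment.csv")
    write_csv(bundle.paired_table, out / "pairs.csv")
    truth = {
        "seed": bundle.seed,
        "trait_baselines": {k: float(v) for k, v in bundle.ground_truth.trait_baselines.items()},
        "noise_sd": {k: float(v) for k, v in bundle.ground_truth.noise_sd.items()},
        "invasion_shift": {k: float(v) for k, v in bundle.ground_truth.invasion_shift.items()},
        "effect_matrix": {
            trait: {
                drv: float(val)
                for drv, val in bundle.ground_truth.effect_matrix[trait].items()
                if val != 0.0
            }
            for trait in bundle.ground_truth.effect_matrix.columns
        },
    }
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


def read_survey_tables(traits_csv, environment_csv) -> tuple[pd.DataFrame, pd.DataFrame]:
    traits = validate_trait_table(pd.read_csv(traits_csv))
    env = pd.read_csv(environment_csv)
    missing = [c for c in DRIVER_COLUMNS if c not in env.columns]
    if missing:
        raise KeyError(f"environment table missing driver columns {missing}")
    if not traits["unit_id"].equals(env["unit_id"]):
        raise ValueError("traits and environment tables disagree on unit ids/order")
    return traits, env


def run_pipeline(
    config: AnalysisConfig,
    design: SurveyDesign | None = None,
    model: EffectModel | None = None,
    schema: PredictorSchema | None = None,
) -> ReportBundle:
    """Execute the full analysis and return a ReportBundle.

    A response whose MMI run fails is recorded in ``failures`` and does
    not abort the other responses.
    """
    schema = schema or PredictorSchema.survey_default()
    if config.traits_csv and config.environment_csv:
        traits, env = read_survey_tables(config.traits_csv, config.environment_csv)
    elif config.traits_csv or config.environment_csv:
        raise ValueError("supply both traits_csv and environment_csv, or neither (simulate)")
    else:
        logger.info("simulating survey with seed %d", config.seed)
        bundle = simulate_survey(design=design, model=model, seed=config.seed)
        traits, env = bundle.trait_table, bundle.environment_table

    if config.scope == "population":
        traits = aggregate_to_populations(traits)
        env = aggregate_to_populations(env)
    logger.info("analysis scope %s: %d units", config.scope, len(traits))

    # PVI extremes defined over population (site) means
    pop_means = traits.groupby("site")[list(TRAIT_COLUMNS)].mean()
    indices = build_index_table(traits, extremes_from=pop_means)
    indices.insert(0, "unit_id", traits["unit_id"].to_numpy())

    anova = pvi_anova(
        {t: indices[f"pvi_{t}"].to_numpy() for t in TRAIT_COLUMNS}
    )
    sma = sma_pairwise(traits, columns=list(TRAIT_COLUMNS), log_transform=config.log_sma_traits)
    lpi_lti = sma_fit(indices["lpi"], indices["lti"], log_transform=False)
    sma = pd.concat(
        [
            sma,
            pd.DataFrame(
                [
                    {"x": "lpi", "y": "lti", "slope": lpi_lti.slope,
                     "intercept": lpi_lti.intercept, "r": lpi_lti.r,
                     "r_squared": lpi_lti.r_squared, "p_value": lpi_lti.p_value,
                     "n": lpi_lti.n}
                ]
            ),
        ],
        ignore_index=True,
    )

    mmi_results: dict[str, MMIResult] = {}
    failures: dict[str, str] = {}
    for response in config.responses:
        y = indices["spectrum_ratio"] if response == "spectrum" else indices[f"pvi_{response}"]
        try:
            mmi_results[response] = run_mmi(
                env,
                y.to_numpy(),
                schema=schema,
                response_name=response,
                level=config.level,
                conditional=config.conditional_averaging,
            )
        except Exception as err:  # record and continue with other responses
            logger.error("MMI run for response %r failed: %s", response, err)
            failures[response] = f"{type(err).__name__}: {err}"

    metadata = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "scope": config.scope,
        "n_units": int(len(traits)),
        "package_version": __version__,
        "failed_responses": failures,
    }
    return ReportBundle(
        config=config,
        indices=indices,
        anova=anova,
        sma_fits=sma,
        mmi_results=mmi_results,
        failures=failures,
        metadata=metadata,
    )


def write_report(report: ReportBundle, out_dir, top_models: int = 20) -> Path:
    """Write a ReportBundle as the interchange CSV set plus run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_csv(report.indices, out / "indices.csv")
    anova_frame = report.anova.to_frame().rename_axis("trait").reset_index()
    write_csv(anova_frame, out / "pvi_anova.csv")
    write_csv(report.sma_fits, out / "sma_fits.csv")
    for response, result in report.mmi_results.items():
        pred = result.contributions.predictors.rename_axis("predictor").reset_index()
        write_csv(pred, out / f"contributions_{response}.csv")
        cats = result.contributions.categories.reset_index()
        write_csv(cats, out / f"category_contributions_{response}.csv")
        avg = result.averaged.rename_axis("predictor").reset_index()
        write_csv(avg, out / f"averaged_coefficients_{response}.csv")
        write_csv(result.model_set.to_frame(top=top_models), out / f"model_set_{response}.csv")
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def check_metadata(out_dir, config: AnalysisConfig) -> None:
    """Refuse to mix outputs produced under a different configuration."""
    meta_path = Path(out_dir) / "run_metadata.json"
    if not meta_path.exists():
        return
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("config_hash") != config.hash():
        raise ValueError(
            f"output directory {out_dir} holds results for config hash "
            f"{meta.get('config_hash')}, not {config.hash()}; use a fresh directory"
        )
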