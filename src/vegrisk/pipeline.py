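"""End-to-end orchestration: clean → screen → index → rank → centroid.

:func:`run_pipeline` runs every stage in order and writes the full output
bundle (cleaning report, assessment table, stratum table, vegetable and
province ranking tables, composition tables, descriptive statistics,
centroid track, run manifest). Each stage failure is re-raised with the
stage name so callers — the CLI in particular — can report where a run died.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .geodata import capitals_frame
from .compliance import CompliancePolicy, assess_records
from .ingest import (
    CleaningConfig,
    ConfigError,
    DataError,
    SchemaConfig,
    read_geo_table,
    read_mrl_table,
    read_records,
)
from .risk import (
    S_NONCOMPLIANT,
    ThresholdConfig,
    composition_stats,
    descriptive_stats,
    provincial_yearly_risk,
    render_risk_table,
    stratum_risk,
)
from .spatial import EARTH_RADIUS_KM, WHOLE_VEGETABLE, centroid_track, track_frame
from .synthetic import generate, paper_like_scenario


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One pipeline run: either input paths or the packaged scenario.

    Exactly one of ``records_path`` / ``scenario`` must be active.
    """

    records_path: Optional[Path] = None
    mrl_path: Optional[Path] = None
    geo_path: Optional[Path] = None
    scenario: bool = False
    seed: int = 0
    outdir: Path = Path("vegrisk_out")
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    policy: CompliancePolicy = field(default_factory=CompliancePolicy)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    schema: SchemaConfig = field(default_factory=SchemaConfig)
    s_denominator: str = S_NONCOMPLIANT
    earth_radius_km: float = EARTH_RADIUS_KM
    min_n_flag: int = 10
    scenario_scale: float = 1.0

    def validate(self) -> None:
        have_paths = self.records_path is not None
        if have_paths == self.scenario:
            raise ConfigError(
                "exactly one of records_path / scenario must be active"
            )
        if have_paths and self.mrl_path is None:
            raise ConfigError("records input requires an MRL table path")


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle under ``config.outdir``.

    Returns a dict of the in-memory results (frames and the manifest).
    """
    try:
        config.validate()
    except Exception as exc:
        raise StageError("config", exc) from exc

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, report, mrl_table, geo = _load_inputs(config)
    assessments = _assess(records, mrl_table, config)
    strata = _risk_tables(assessments, config, outdir)
    _spatial(assessments, geo, config, outdir)

    report_dict = report.to_dict() if report is not None else None
    with open(outdir / "cleaning_report.json", "w") as fh:
        json.dump(report_dict, fh, indent=2)
    assessments.to_csv(outdir / "assessments.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "scenario": config.scenario,
        "records_path": str(config.records_path) if config.records_path else None,
        "s_denominator": config.s_denominator,
        "threshold_ir0": config.threshold.ir0,
        "earth_radius_km": config.earth_radius_km,
        "n_batches": int(assessments["batch_id"].nunique()),
        "n_noncompliant": int((~assessments["compliant"].astype(bool)).sum()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "assessments": assessments,
        "strata": strata,
        "cleaning_report": report_dict,
        "manifest": manifest,
        "outdir": outdir,
    }


@_stage("ingest")
def _load_inputs(config: RunConfig):
    if config.scenario:
        gen = paper_like_scenario(seed=config.seed, scale=config.scenario_scale)
        records_df, mrl_df, geo_df = generate(gen)
        records, report = read_records(records_df, config.schema, config.cleaning)
        mrl_table = read_mrl_table(mrl_df)
        geo = read_geo_table(geo_df)
    else:
        assert config.records_path is not None and config.mrl_path is not None
        mrl_table = read_mrl_table(config.mrl_path)
        records, report = read_records(
            config.records_path, config.schema, config.cleaning, mrl_table=mrl_table
        )
        geo_source = config.geo_path if config.geo_path else capitals_frame()
        geo = read_geo_table(geo_source)
    return records, report, mrl_table, geo


@_stage("compliance")
def _assess(records, mrl_table, config: RunConfig) -> pd.DataFrame:
    return assess_records(records, mrl_table, config.policy)


@_stage("risk_index")
def _risk_tables(assessments: pd.DataFrame, config: RunConfig, outdir: Path) -> pd.DataFrame:
    from .risk import aggregate  # local import keeps stage traceback tight

    strata = stratum_risk(
        assessments, s_denominator=config.s_denominator, min_n_flag=config.min_n_flag
    )
    strata.to_csv(outdir / "strata.csv", index=False)
    for level in ("vegetable", "province"):
        agg = aggregate(strata, level, threshold=config.threshold)
        render_risk_table(agg, level).to_csv(outdir / f"{level}_risk.csv", index=False)
    for name, table in composition_stats(assessments).items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    if not strata.empty:
        descriptive_stats(strata).to_csv(outdir / "descriptive_stats.csv", index=False)
    return strata


@_stage("spatial")
def _spatial(assessments: pd.DataFrame, geo, config: RunConfig, outdir: Path) -> None:
    yearly = provincial_yearly_risk(assessments, s_denominator=config.s_denominator)
    if yearly.empty or yearly["ir"].sum() <= 0:
        track_frame([], []).to_csv(outdir / "centroid_track.csv", index=False)
        return
    cents, transfers = centroid_track(yearly, geo, scope=WHOLE_VEGETABLE)
    track_frame(cents, transfers).to_csv(outdir / "centroid_track.csv", index=False)
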