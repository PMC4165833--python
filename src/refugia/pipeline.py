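"""End-to-end pipeline: generate → rank → allocate → survey → evaluate.

A single :class:`PipelineConfig` holds every stage's parameters plus one
master seed; per-stage seeds are derived by hashing the master seed with
the stage name, so stages never share a random stream.  ``run_pipeline``
writes each stage's artifact (GeoJSON / CSV / JSON) into a run directory
together with a manifest of seeds and file hashes — rerunning with the
same config and seed reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .allocate import RefugeSet, SubsidyScheme, allocate_refuges
from .evaluate import (
    compare_densities,
    correlate,
    estimate_efficiency,
    fractile_coverage,
    merged_unit_table,
)
from .exceptions import RefugiaError
from .landscape import (
    DepositionModel,
    Landscape,
    SynthesisConfig,
    generate_landscape,
    simulate_deposition,
)
from .prioritize import compute_criteria, rank_fields
from .survey import SurveyDesign, run_survey

STAGES = ("generate", "rank", "allocate", "survey", "evaluate")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: sha256(master:stage) mod 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for a reproducible refuge-scheme simulation run."""

    synthesis: SynthesisConfig = dataclass_field(default_factory=SynthesisConfig)
    deposition: DepositionModel = dataclass_field(default_factory=DepositionModel)
    scheme: SubsidyScheme = dataclass_field(default_factory=SubsidyScheme)
    survey: SurveyDesign = dataclass_field(default_factory=SurveyDesign)
    neighbour_radius_m: float = 1000.0
    adjoin_bonus: float = 50.0
    adjacency_threshold_m: float = 20.0
    n_refuge_surveys: int = 90
    n_controls: int = 138
    master_seed: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["deposition"]["crop_multiplier"] = dict(self.deposition.crop_multiplier)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthesis" in d:
            s = dict(d["synthesis"])
            if "area_range_ha" in s:
                s["area_range_ha"] = tuple(s["area_range_ha"])
            d["synthesis"] = SynthesisConfig(**s)
        if "deposition" in d:
            d["deposition"] = DepositionModel(**d["deposition"])
        if "scheme" in d:
            d["scheme"] = SubsidyScheme(**d["scheme"])
        if "survey" in d:
            d["survey"] = SurveyDesign(**d["survey"])
        return cls(**d)


def _stage(name: str):
    """Wrap a stage body so failures carry the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, RefugiaError):
                exc.args = (f"[stage {name}] {exc.args[0]}",) + exc.args[1:]
            return False

    return _Ctx()


def evaluate_run(
    landscape: Landscape,
    ranking: pd.DataFrame,
    refuges: RefugeSet,
    survey_table: pd.DataFrame,
    min_stratum_n: int = 2,
) -> dict:
    """All evaluation statistics for one simulated (or loaded) run."""
    report: dict = {}

    comparisons = {}
    for crop in ("pasture", "stubble"):
        sub = survey_table[survey_table["crop"] == crop]
        r = sub.loc[sub["is_refuge"], "mean_density_per_m2"]
        c = sub.loc[~sub["is_refuge"], "mean_density_per_m2"]
        if len(r) >= min_stratum_n and len(c) >= min_stratum_n:
            comparisons[crop] = compare_densities(r, c, crop_stratum=crop).as_dict()
    report["comparisons"] = comparisons

    units = merged_unit_table(refuges, survey_table, ranking)
    correlations = {}
    if len(units) >= 3:
        try:
            correlations["density_vs_roost_distance"] = correlate(
                units["mean_density_per_m2"], units["roost_distance_m"]
            ).as_dict()
            correlations["density_vs_unit_area"] = correlate(
                units["mean_density_per_m2"], units["area_ha"]
            ).as_dict()
        except RefugiaError:
            pass
    report["correlations"] = correlations

    coverage = fractile_coverage(refuges, ranking)
    report["coverage_top5pct"] = float(coverage["cumulative_fraction"].iloc[0])
    report["coverage_top20pct"] = float(coverage["cumulative_fraction"].iloc[3])

    pasture_ha = sum(f.area_ha for f in landscape.fields if f.crop == "pasture")
    total_ha = landscape.total_area_ha()
    refuge_pasture_ha = sum(
        landscape.field(i).area_ha
        for i in refuges.member_ids
        if landscape.field(i).crop == "pasture"
    )
    pasture_survey = survey_table[survey_table["crop"] == "pasture"]
    dens_r = pasture_survey.loc[pasture_survey["is_refuge"], "mean_density_per_m2"]
    dens_c = pasture_survey.loc[~pasture_survey["is_refuge"], "mean_density_per_m2"]
    if len(dens_r) > 0 and len(dens_c) > 0 and pasture_ha > 0:
        eff = estimate_efficiency(
            suitable_area_km2=total_ha / 100.0,
            grass_fraction=pasture_ha / total_ha,
            refuge_pasture_km2=refuge_pasture_ha / 100.0,
            density_refuge=float(dens_r.mean()),
            density_nonrefuge=float(dens_c.mean()),
        )
        report["efficiency"] = eff.as_dict()

    member_areas = [landscape.field(i).area_ha for i in refuges.member_ids]
    report["refuges"] = {
        "n_fields": len(refuges.member_ids),
        "n_units": refuges.n_units,
        "n_adjoined_fields": sum(
            len(u) for u in refuges.merged_units if len(u) > 1
        ),
        "total_area_ha": float(np.sum(member_areas)) if member_areas else 0.0,
        "mean_field_area_ha": float(np.mean(member_areas)) if member_areas else 0.0,
        "mean_unit_area_ha": (
            float(np.mean(refuges.unit_areas_ha)) if refuges.unit_areas_ha else 0.0
        ),
        "cost_total_nok": refuges.cost_total,
    }
    report["coverage_table"] = coverage.reset_index().to_dict(orient="list")
    return report


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage; optionally write all artifacts to ``out_dir``.

    Returns a dict with the in-memory stage outputs (``landscape``,
    ``ranking``, ``refuges``, ``survey``, ``report``, ``seeds``).
    """
    seeds = {s: stage_seed(config.master_seed, s) for s in STAGES}

    with _stage("generate"):
        landscape = generate_landscape(config.synthesis, seeds["generate"])
    with _stage("rank"):
        criteria = compute_criteria(landscape, config.neighbour_radius_m)
        ranking = rank_fields(criteria)
    with _stage("allocate"):
        refuges = allocate_refuges(
            ranking,
            landscape,
            config.scheme,
            adjoin_bonus=config.adjoin_bonus,
            adjacency_threshold_m=config.adjacency_threshold_m,
        )
    with _stage("survey"):
        surface = simulate_deposition(landscape, refuges.member_ids, config.deposition)
        rng = np.random.default_rng(seeds["survey"])
        survey_table = run_survey(
            surface,
            refuges,
            config.survey,
            n_refuge_surveys=config.n_refuge_surveys,
            n_controls=config.n_controls,
            rng=rng,
        )
    with _stage("evaluate"):
        report = evaluate_run(landscape, ranking, refuges, survey_table)

    result = {
        "landscape": landscape,
        "ranking": ranking,
        "refuges": refuges,
        "survey": survey_table,
        "report": report,
        "seeds": seeds,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_yaml(config.to_dict(), out / "config.yaml")
        io.write_landscape(landscape, out / "landscape.geojson")
        io.write_ranking(ranking, out / "ranking.csv")
        io.write_refuges(refuges, landscape, out / "refuges.geojson")
        refuges.cost_ledger(landscape, config.scheme).to_csv(
            out / "cost_ledger.csv", index=False, float_format="%.6f"
        )
        io.write_survey(survey_table, out / "survey.csv")
        pd.DataFrame(report["coverage_table"]).to_csv(
            out / "coverage.csv", index=False, float_format="%.6f"
        )
        (out / "evaluation.json").write_text(json.dumps(report, indent=1))
        manifest = {
            "package": "refugia",
            "master_seed": config.master_seed,
            "stage_seeds": seeds,
            "files": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out.iterdir())
                if p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return result
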