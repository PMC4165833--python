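"""Canned simulation experiments at study scale.

These wire the stages together into the two replicate experiments used
to validate the workflow, and are shared by the test suite and the
reproduction script:

* :func:`correlation_replicate` — does the negative density–roost-distance
  relationship survive allocation, merging and count noise?
* :func:`recovery_replicate` — does the survey-plus-bookkeeping estimator
  recover the grazing-pressure share implied by the model's true
  intensity surface?

The recovery "truth" is the same area × density bookkeeping evaluated
with the noise-free expected survey densities of the same surveyed
fields; the comparison therefore isolates the estimation machinery
(design, counting noise, averaging) from the landscape-extrapolation
step that is common to both values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .allocate import SubsidyScheme, allocate_refuges
from .evaluate import correlate, estimate_efficiency, merged_unit_table
from .landscape import DepositionModel, SynthesisConfig, generate_landscape, simulate_deposition
from .pipeline import PipelineConfig, run_pipeline
from .prioritize import compute_criteria, rank_fields
from .survey import SurveyDesign, expected_field_density, survey_field


def correlation_replicate(
    seed: int,
    n_fields: int = 260,
    extent_m: float = 8_000.0,
    budget: float = 620_000.0,
) -> tuple[float, int]:
    """One seeded landscape → allocation → survey → unit-level Spearman rho.

    The landscape and budget are scaled so the allocation yields on the
    order of 78 merged refuge units, the sample size of the reference
    field campaign.  Every refuge member is surveyed with Poisson count
    noise; adjoined fields are pooled into units.  Returns
    ``(rho, n_units)`` for density vs roost distance.
    """
    cfg = SynthesisConfig(n_fields=n_fields, extent_m=extent_m)
    landscape = generate_landscape(cfg, seed=seed)
    ranking = rank_fields(compute_criteria(landscape))
    refuges = allocate_refuges(ranking, landscape, SubsidyScheme(budget=budget))
    surface = simulate_deposition(landscape, refuges.member_ids, DepositionModel())
    design = SurveyDesign()
    rng = np.random.default_rng(seed + 1)
    rows = [
        survey_field(surface, fid, True, design, rng)
        for fid in sorted(refuges.member_ids)
    ]
    units = merged_unit_table(refuges, pd.DataFrame(rows), ranking)
    res = correlate(units["mean_density_per_m2"], units["roost_distance_m"])
    return res.rho, len(units)


def recovery_replicate(seed: int) -> tuple[float, float]:
    """One full study-scale pipeline run → (estimated, true) captured share.

    Runs the default 1008-field configuration (90 refuge + 138 control
    surveys, refuge/non-refuge centre intensities 3.56/0.27), estimates
    the share of grazing pressure captured by refuges from the noisy
    survey means, and recomputes it with the noise-free expected
    densities of the same surveyed fields.
    """
    cfg = PipelineConfig(master_seed=seed)
    res = run_pipeline(cfg)
    eff = res["report"]["efficiency"]
    surface = simulate_deposition(
        res["landscape"], res["refuges"].member_ids, cfg.deposition
    )
    table = res["survey"]
    pasture = table[table["crop"] == "pasture"]
    refuge_ids = pasture.loc[pasture["is_refuge"], "field_id"]
    control_ids = pasture.loc[~pasture["is_refuge"], "field_id"]
    d_r = float(
        np.mean([expected_field_density(surface, i, cfg.survey) for i in refuge_ids])
    )
    d_c = float(
        np.mean([expected_field_density(surface, i, cfg.survey) for i in control_ids])
    )
    truth = estimate_efficiency(
        eff["suitable_area_km2"],
        eff["grass_fraction"],
        eff["refuge_pasture_km2"],
        d_r,
        d_c,
    ).share_captured
    return eff["share_captured"], truth
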