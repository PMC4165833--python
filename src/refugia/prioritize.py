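"""Rank-sum prioritization of fields for goose accommodation.

Each field is scored on four suitability criteria — size, connectivity to
other fields, years of historic goose use, and proximity to the nearest
roost — and ranked within each criterion (rank 1 = most suitable, ties
averaged).  The per-field sum of the four ranks orders the whole pool;
the ordered list is then cut into priority fractiles (5 % slices 1..20
and 20 % slices A..E) that drive subsidy allocation and its evaluation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .exceptions import IncompleteCriteriaError, InvalidWidthError
from .landscape import Landscape, roost_distance

CRITERIA_COLUMNS = ["size_ha", "connectivity_ha", "historic_use_years", "roost_distance_m"]

FRACTILE_20_LABELS = ["A", "B", "C", "D", "E"]


def compute_criteria(landscape: Landscape, neighbour_radius_m: float = 1000.0) -> pd.DataFrame:
    """Tabulate the four ranking criteria for every field.

    Connectivity is the summed area (ha) of all *other* fields whose
    centroids lie within ``neighbour_radius_m`` of the field's centroid —
    a simple proxy that grows with local field aggregation.

    Returns a DataFrame indexed by field id with columns
    ``size_ha, connectivity_ha, historic_use_years, roost_distance_m``.
    """
    ids = landscape.field_ids
    cents = np.array(
        [(f.centroid.x, f.centroid.y) for f in landscape.fields]
    )
    areas = np.array([f.area_ha for f in landscape.fields])
    tree = cKDTree(cents)
    neighbour_lists = tree.query_ball_point(cents, r=neighbour_radius_m)
    connectivity = np.array(
        [areas[nbrs].sum() - areas[i] for i, nbrs in enumerate(neighbour_lists)]
    )
    dists = [roost_distance(f, landscape.roosts) for f in landscape.fields]
    return pd.DataFrame(
        {
            "size_ha": areas,
            "connectivity_ha": connectivity,
            "historic_use_years": [f.historic_use_years for f in landscape.fields],
            "roost_distance_m": dists,
        },
        index=pd.Index(ids, name="field_id"),
    )


def rank_fields(criteria: pd.DataFrame) -> pd.DataFrame:
    """Rank every field by the four-criterion rank sum.

    Rank 1 is the most suitable field per criterion: largest size,
    largest connectivity, most historic-use seasons, smallest roost
    distance.  Ties receive average ranks, keeping rank sums comparable.
    The overall order ascends by rank sum, breaking ties by smaller roost
    distance and then lexicographic field id so the output is fully
    deterministic.

    Returns the criteria table augmented with ``rank_size``,
    ``rank_connectivity``, ``rank_use``, ``rank_distance``, ``rank_sum``,
    ``overall_rank``, ``fractile_5`` and ``fractile_20``.
    """
    if len(criteria) < 2:
        raise IncompleteCriteriaError("ranking needs at least 2 fields")
    missing = [c for c in CRITERIA_COLUMNS if c not in criteria.columns]
    if missing:
        raise IncompleteCriteriaError(f"criteria table lacks columns {missing}")
    if criteria[CRITERIA_COLUMNS].isna().any().any():
        bad = criteria.index[criteria[CRITERIA_COLUMNS].isna().any(axis=1)]
        raise IncompleteCriteriaError(
            f"missing criterion values for fields {list(bad[:5])}"
        )

    out = criteria.copy()
    out.index = out.index.astype(str)
    out.index.name = "field_id"
    out["rank_size"] = rankdata(-out["size_ha"], method="average")
    out["rank_connectivity"] = rankdata(-out["connectivity_ha"], method="average")
    out["rank_use"] = rankdata(-out["historic_use_years"], method="average")
    out["rank_distance"] = rankdata(out["roost_distance_m"], method="average")
    out["rank_sum"] = (
        out["rank_size"]
        + out["rank_connectivity"]
        + out["rank_use"]
        + out["rank_distance"]
    )
    # Deterministic order: rank_sum, then roost distance, then field id.
    order = out.reset_index().sort_values(
        ["rank_sum", "roost_distance_m", "field_id"], kind="mergesort"
    )["field_id"]
    out.loc[order, "overall_rank"] = np.arange(1, len(out) + 1)
    out["overall_rank"] = out["overall_rank"].astype(int)
    out["fractile_5"] = assign_fractiles(out, width=0.05)
    out["fractile_20"] = [
        FRACTILE_20_LABELS[k - 1] for k in assign_fractiles(out, width=0.20)
    ]
    return out


def assign_fractiles(ranking: pd.DataFrame, width: float) -> pd.Series:
    """Partition fields, in overall-rank order, into equal-width fractiles.

    With n fields and k = round(1/width) fractiles, group sizes are
    ``n // k`` with the remainder distributed one-per-group to the
    earliest (highest-priority) fractiles, so sizes differ by at most 1.
    Returns an integer Series (1 = highest priority) aligned to the
    ranking's index.
    """
    if not (0.0 < width < 1.0):
        raise InvalidWidthError(f"fractile width must be in (0, 1), got {width}")
    if "overall_rank" not in ranking.columns:
        raise IncompleteCriteriaError("ranking lacks overall_rank")
    n = len(ranking)
    k = round(1.0 / width)
    q, r = divmod(n, k)
    sizes = [q + 1] * r + [q] * (k - r)
    bounds = np.cumsum(sizes)
    labels = np.searchsorted(bounds, ranking["overall_rank"].to_numpy(), side="left") + 1
    return pd.Series(labels.astype(int), index=ranking.index, name=f"fractile_{width:g}")
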