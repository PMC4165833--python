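"""Budget-constrained allocation of subsidies to priority fields.

The subsidy scheme pays farmers per hectare to let geese forage
undisturbed (a higher rate for pasture than for newly sown cereal;
stubble destined for sowing is paid at the new-sown rate).  Funds are
limited, so fields are taken greedily in priority order; because the
managing authorities also preferred to adjoin subsidized fields into
larger contiguous refuges, a candidate adjacent to an already-selected
field gets a configurable rank-credit (``adjoin_bonus``) that can pull it
forward in the queue.  Selected fields are finally merged into connected
refuge units by boundary-to-boundary adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import networkx as nx
import pandas as pd
from shapely import STRtree

from .exceptions import InvalidConfigurationError, UnknownFieldError
from .landscape import Landscape

#: Crops eligible for subsidy and the rate key they are costed at.
#: Stubble fields are included because they were to be turned into
#: new-sown fields, and are costed at the new-sown rate.
ELIGIBLE_RATE_KEY = {"pasture": "pasture", "new_sown": "new_sown", "stubble": "new_sown"}

DEFAULT_ADJACENCY_THRESHOLD_M = 20.0


@dataclass(frozen=True)
class SubsidyScheme:
    """Budget and per-hectare subsidy rates (NOK)."""

    budget: float = 1_440_000.0
    rate_pasture: float = 3_000.0
    rate_new_sown: float = 1_000.0

    def __post_init__(self) -> None:
        if self.budget <= 0:
            raise InvalidConfigurationError("budget must be positive")
        if self.rate_pasture <= 0 or self.rate_new_sown <= 0:
            raise InvalidConfigurationError("rates must be positive")
        if self.rate_pasture <= self.rate_new_sown:
            raise InvalidConfigurationError(
                "pasture rate must exceed the new-sown rate"
            )

    def field_cost(self, crop: str, area_ha: float) -> float | None:
        """Subsidy cost of a whole field, or None if the crop is ineligible."""
        key = ELIGIBLE_RATE_KEY.get(crop)
        if key is None:
            return None
        rate = self.rate_pasture if key == "pasture" else self.rate_new_sown
        return rate * area_ha


@dataclass
class RefugeSet:
    """A budget-feasible refuge selection with its merged units and costs."""

    member_ids: set[str]
    cost_total: float
    merged_units: list[set[str]]
    unit_areas_ha: list[float]
    status: str = "ok"  # "ok" or "empty-budget"

    @property
    def n_units(self) -> int:
        return len(self.merged_units)

    def cost_ledger(self, landscape: Landscape, scheme: SubsidyScheme) -> pd.DataFrame:
        """Per-field cost table (field_id, crop, area_ha, rate, cost_nok, unit_id)."""
        unit_of = {
            fid: u for u, unit in enumerate(self.merged_units, start=1) for fid in unit
        }
        rows = []
        for fid in sorted(self.member_ids):
            f = landscape.field(fid)
            cost = scheme.field_cost(f.crop, f.area_ha)
            rows.append(
                {
                    "field_id": fid,
                    "crop": f.crop,
                    "area_ha": f.area_ha,
                    "cost_nok": cost,
                    "unit_id": unit_of.get(fid, 0),
                }
            )
        return pd.DataFrame(rows)


def adjacency_pairs(
    landscape: Landscape,
    ids: list[str],
    threshold_m: float = DEFAULT_ADJACENCY_THRESHOLD_M,
) -> set[tuple[str, str]]:
    """Unordered pairs of fields whose boundaries lie within ``threshold_m``.

    Uses an STR-tree distance query; touching polygons have distance 0.
    """
    geoms = [landscape.field(i).boundary for i in ids]
    tree = STRtree(geoms)
    pairs: set[tuple[str, str]] = set()
    left, right = tree.query(geoms, predicate="dwithin", distance=threshold_m)
    for a, b in zip(left, right):
        if a < b:
            pairs.add((ids[a], ids[b]))
    return pairs


def merge_adjacent(
    member_ids: set[str],
    landscape: Landscape,
    adjacency_threshold_m: float = DEFAULT_ADJACENCY_THRESHOLD_M,
) -> tuple[list[set[str]], list[float]]:
    """Group member fields into connected refuge units.

    Units are the connected components of the graph joining member fields
    whose boundary-to-boundary distance is at most the threshold.
    Returns ``(units, unit_areas_ha)`` sorted by descending area then by
    the smallest member id, for deterministic output.
    """
    unknown = member_ids - set(landscape.field_ids)
    if unknown:
        raise UnknownFieldError(f"member ids not in landscape: {sorted(unknown)}")
    ids = sorted(member_ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(adjacency_pairs(landscape, ids, adjacency_threshold_m))
    units = [set(c) for c in nx.connected_components(g)]
    areas = [sum(landscape.field(i).area_ha for i in u) for u in units]
    order = sorted(range(len(units)), key=lambda k: (-areas[k], min(units[k])))
    return [units[k] for k in order], [areas[k] for k in order]


def allocate_refuges(
    ranking: pd.DataFrame,
    landscape: Landscape,
    scheme: SubsidyScheme,
    adjoin_bonus: float = 0.0,
    adjacency_threshold_m: float = DEFAULT_ADJACENCY_THRESHOLD_M,
) -> RefugeSet:
    """Greedily select refuge fields under the budget, favouring adjacency.

    Candidates are the eligible fields (pasture, new-sown, stubble) taken
    in effective-priority order: a candidate's effective score is its
    rank sum, minus ``adjoin_bonus`` once it is adjacent to an
    already-selected field.  At each step the best-scoring candidate is
    examined; it is selected iff its whole-field cost fits the remaining
    budget, otherwise it is removed from the queue.  Ties break by
    overall rank then field id, so the result is deterministic.

    With ``adjoin_bonus=0`` and uniform costs this reduces exactly to the
    top-k of the overall ranking.
    """
    if adjoin_bonus < 0:
        raise InvalidConfigurationError("adjoin_bonus must be >= 0")
    unknown = set(ranking.index) - set(landscape.field_ids)
    if unknown:
        raise UnknownFieldError(f"ranked ids not in landscape: {sorted(unknown)}")

    cand: dict[str, tuple[float, float, int]] = {}  # id -> (rank_sum, cost, overall)
    for fid in ranking.index:
        f = landscape.field(fid)
        cost = scheme.field_cost(f.crop, f.area_ha)
        if cost is None:
            continue
        cand[fid] = (
            float(ranking.at[fid, "rank_sum"]),
            cost,
            int(ranking.at[fid, "overall_rank"]),
        )

    neighbours: dict[str, set[str]] = {fid: set() for fid in cand}
    for a, b in adjacency_pairs(landscape, sorted(cand), adjacency_threshold_m):
        neighbours[a].add(b)
        neighbours[b].add(a)

    selected: set[str] = set()
    adjacent_credit: set[str] = set()
    remaining = scheme.budget
    cost_total = 0.0
    queue = dict(cand)
    while queue:
        fid = min(
            queue,
            key=lambda i: (
                queue[i][0] - (adjoin_bonus if i in adjacent_credit else 0.0),
                queue[i][2],
                i,
            ),
        )
        rank_sum, cost, _ = queue.pop(fid)
        if cost <= remaining + 1e-9:
            selected.add(fid)
            remaining -= cost
            cost_total += cost
            adjacent_credit.update(n for n in neighbours[fid] if n in queue)

    if not selected:
        warnings.warn(
            "budget below the cheapest eligible field: empty refuge set",
            stacklevel=2,
        )
        return RefugeSet(set(), 0.0, [], [], status="empty-budget")

    units, areas = merge_adjacent(selected, landscape, adjacency_threshold_m)
    return RefugeSet(selected, cost_total, units, areas)
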