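"""Simulation of the dropping-count survey and control-field selection.

Grazing pressure is measured by counting goose droppings in three 2-m
radius circles per field: one at the field centre, one two-thirds of the
way from the edge to the centre, one a third of the way — a transect
along the inward normal from the nearest boundary point.  The mean count
divided by circle area estimates the field's dropping density
(droppings m⁻²), an accumulated-use proxy since droppings persist for
3–4 weeks.  Control (non-refuge) fields are drawn at random from the
pool within 2 km of any refuge, weighted by similarity in circumference
to the refuge fields so that the comparison is not confounded by parcel
size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import nearest_points

from .allocate import RefugeSet
from .exceptions import (
    InvalidConfigurationError,
    ModelIntegrityError,
    ProtocolInfeasibleError,
)
from .landscape import DepositionSurface, Field, Landscape


@dataclass(frozen=True)
class SurveyDesign:
    """Protocol constants of the dropping survey."""

    circle_radius_m: float = 2.0
    circles_per_field: int = 3
    control_pool_radius_m: float = 2_000.0
    seed: int = 0
    #: Negative-binomial overdispersion (variance = mu + mu^2/dispersion);
    #: None selects plain Poisson counts.
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.circle_radius_m <= 0:
            raise InvalidConfigurationError("circle_radius_m must be positive")
        if self.circles_per_field != 3:
            raise InvalidConfigurationError(
                "the protocol uses exactly 3 circles per field"
            )
        if self.dispersion is not None and self.dispersion <= 0:
            raise InvalidConfigurationError("dispersion must be positive")

    @property
    def circle_area_m2(self) -> float:
        return math.pi * self.circle_radius_m**2


def place_circles(field: Field, design: SurveyDesign) -> list[Point]:
    """Deterministic centres of the three survey circles.

    Circle 1 sits at the field's representative centre.  Let E be the
    nearest boundary point to that centre and D the edge-to-centre
    distance: circle 2 is placed two-thirds of the way from E to the
    centre (D/3 from the centre) and circle 3 one-third of the way
    (2D/3 from the centre).
    """
    centre = field.representative_centre()
    edge = nearest_points(field.boundary.exterior, centre)[0]
    depth = centre.distance(edge)
    if depth <= design.circle_radius_m:
        raise ProtocolInfeasibleError(
            f"field {field.id}: inradius {depth:.1f} m cannot contain a "
            f"{design.circle_radius_m} m survey circle"
        )
    def along(frac_from_edge: float) -> Point:
        return Point(
            edge.x + frac_from_edge * (centre.x - edge.x),
            edge.y + frac_from_edge * (centre.y - edge.y),
        )

    return [centre, along(2.0 / 3.0), along(1.0 / 3.0)]


def sample_counts(
    surface: DepositionSurface,
    field_id: str,
    centres: list[Point],
    design: SurveyDesign,
    rng: np.random.Generator,
) -> list[int]:
    """Draw dropping counts for the three circles.

    Each count is Poisson with mean = local intensity at the circle
    centre × circle area; with ``design.dispersion`` set, a gamma-Poisson
    (negative binomial) mixture with that shape is used instead.
    """
    counts = []
    for c in centres:
        lam = surface.intensity_at(field_id, c)
        if lam < 0:
            raise ModelIntegrityError(
                f"negative intensity {lam} at field {field_id}"
            )
        mu = lam * design.circle_area_m2
        if design.dispersion is None:
            counts.append(int(rng.poisson(mu)))
        else:
            rate = rng.gamma(design.dispersion, mu / design.dispersion) if mu > 0 else 0.0
            counts.append(int(rng.poisson(rate)))
    return counts


def survey_field(
    surface: DepositionSurface,
    field_id: str,
    is_refuge: bool,
    design: SurveyDesign,
    rng: np.random.Generator,
) -> dict:
    """One survey record: counts in the three circles and the mean density."""
    field = surface.landscape.field(field_id)
    centres = place_circles(field, design)
    counts = sample_counts(surface, field_id, centres, design, rng)
    density = mean_density(counts, design)
    return {
        "field_id": field_id,
        "is_refuge": is_refuge,
        "crop": field.crop,
        "c1": counts[0],
        "c2": counts[1],
        "c3": counts[2],
        "mean_density_per_m2": density,
    }


def mean_density(counts: list[int], design: SurveyDesign) -> float:
    """Mean count over the circles divided by circle area (droppings m⁻²)."""
    if any(c < 0 for c in counts):
        raise ModelIntegrityError("counts must be non-negative")
    return sum(counts) / (len(counts) * design.circle_area_m2)


def expected_field_density(
    surface: DepositionSurface, field_id: str, design: SurveyDesign
) -> float:
    """Noise-free expectation of a field's surveyed mean density.

    The mean of the model intensities at the three circle centres — what
    the survey record's ``mean_density_per_m2`` estimates.
    """
    field = surface.landscape.field(field_id)
    centres = place_circles(field, design)
    return float(
        np.mean([surface.intensity_at(field_id, c) for c in centres])
    )


def similarity_weights(perimeters: np.ndarray, reference_perimeter: float) -> np.ndarray:
    """Perimeter-similarity sampling weights.

    w_j = 1 / (1 + |P_j - P̄| / P̄) with P̄ the mean refuge perimeter:
    bounded in (0, 1], symmetric and scale-free, giving weight 1 to a
    candidate matching the refuges exactly.
    """
    return 1.0 / (1.0 + np.abs(perimeters - reference_perimeter) / reference_perimeter)


def select_controls(
    refuges: RefugeSet,
    landscape: Landscape,
    design: SurveyDesign,
    n_controls: int,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Stratified-random control fields near refuges.

    The candidate pool is every non-refuge field whose centroid lies
    within ``design.control_pool_radius_m`` of any refuge field; drawing
    is without replacement with perimeter-similarity weights relative to
    the mean refuge perimeter.  If the pool is smaller than
    ``n_controls`` the entire pool is returned (with a warning).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    member_geoms = [landscape.field(i).boundary for i in refuges.member_ids]
    if not member_geoms:
        raise InvalidConfigurationError("refuge set is empty; no pool definable")
    pool = []
    for f in landscape.fields:
        if f.id in refuges.member_ids:
            continue
        c = f.centroid
        if any(c.distance(g) <= design.control_pool_radius_m for g in member_geoms):
            pool.append(f)
    if not pool:
        raise InvalidConfigurationError("control pool is empty")
    if len(pool) < n_controls:
        warnings.warn(
            f"control pool ({len(pool)}) smaller than requested "
            f"({n_controls}); returning the whole pool",
            stacklevel=2,
        )
        return sorted(f.id for f in pool)
    if len(pool) == n_controls:
        return sorted(f.id for f in pool)
    ref_perim = float(
        np.mean([landscape.field(i).perimeter_m for i in refuges.member_ids])
    )
    w = similarity_weights(np.array([f.perimeter_m for f in pool]), ref_perim)
    idx = rng.choice(len(pool), size=n_controls, replace=False, p=w / w.sum())
    return [pool[i].id for i in sorted(idx)]


def run_survey(
    surface: DepositionSurface,
    refuges: RefugeSet,
    design: SurveyDesign,
    n_refuge_surveys: int,
    n_controls: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Survey a subset of refuges plus matched controls.

    Mirrors the field campaign: a random subset of ``n_refuge_surveys``
    refuge fields (all, if fewer exist) and ``n_controls`` control
    fields are visited; fields too small for the circle protocol are
    skipped.  Returns the survey table with one row per field.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    members = sorted(refuges.member_ids)
    if len(members) > n_refuge_surveys:
        pick = rng.choice(len(members), size=n_refuge_surveys, replace=False)
        members = [members[i] for i in sorted(pick)]
    controls = select_controls(refuges, surface.landscape, design, n_controls, rng)

    rows = []
    for fid in members:
        try:
            rows.append(survey_field(surface, fid, True, design, rng))
        except ProtocolInfeasibleError:
            continue
    for fid in controls:
        try:
            rows.append(survey_field(surface, fid, False, design, rng))
        except ProtocolInfeasibleError:
            continue
    return pd.DataFrame(rows)
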