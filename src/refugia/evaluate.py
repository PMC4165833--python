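"""Evaluation statistics for the refuge scheme.

Four questions, four tools:

* Do refuges carry more grazing pressure than comparable non-refuge
  fields?  Two-sample t test on dropping densities, per crop stratum
  (pooled-variance Student form by default; Welch behind a flag).
* Does field use decline with roost distance (and vary with refuge
  size)?  Spearman rank correlations on merged refuge units.
* Did the subsidies follow the priority list?  Cumulative refuge area
  over 5 % priority fractiles.
* How much of the regional grazing pressure do refuges capture?  Area ×
  density bookkeeping over refuge and non-refuge grassland, yielding the
  scheme's headline efficiency share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allocate import RefugeSet
from .exceptions import (
    InconsistentInputsError,
    InfeasibleGeometryError,
    InvalidConfigurationError,
    NumericDegeneracyError,
    UndefinedCorrelationError,
)

KM2_PER_HA = 0.01
M2_PER_KM2 = 1e6


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample density comparison for one crop stratum."""

    t_statistic: float
    df: float
    p_value: float
    mean_refuge: float
    mean_control: float
    ratio: float
    crop_stratum: str
    test: str

    def as_dict(self) -> dict:
        return {
            "crop_stratum": self.crop_stratum,
            "test": self.test,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "mean_refuge_per_m2": self.mean_refuge,
            "mean_control_per_m2": self.mean_control,
            "ratio": self.ratio,
        }


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {"rho": self.rho, "p_value": self.p_value, "n": self.n}


@dataclass(frozen=True)
class EfficiencyReport:
    """Area × density bookkeeping behind the efficiency share.

    ``share_captured`` is the fraction of the total grazing pressure on
    grassland (area × dropping density, refuge + non-refuge) exerted on
    refuges; ``area_share`` is the refuges' fraction of the grassland
    area.  A large gap between the two is the scheme working.
    """

    suitable_area_km2: float
    grass_fraction: float
    grassland_area_km2: float
    refuge_pasture_km2: float
    nonrefuge_pasture_km2: float
    density_refuge: float
    density_nonrefuge: float
    pressure_refuge: float
    pressure_nonrefuge: float
    share_captured: float
    area_share: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compare_densities(
    refuge_densities: list[float] | np.ndarray,
    control_densities: list[float] | np.ndarray,
    crop_stratum: str = "pasture",
    test: str = "student",
) -> ComparisonResult:
    """Two-sided two-sample t test of refuge vs control dropping density.

    ``test="student"`` uses the pooled-variance form (df = n1 + n2 − 2);
    ``test="welch"`` the unequal-variance form with Welch–Satterthwaite
    df.  Also reports the group means and their ratio.
    """
    x = np.asarray(refuge_densities, dtype=float)
    y = np.asarray(control_densities, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise NumericDegeneracyError("need >= 2 observations per group")
    if test not in ("student", "welch"):
        raise InvalidConfigurationError(f"unknown test {test!r}")
    equal_var = test == "student"
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            t_stat, p, df = 0.0, 1.0, float(len(x) + len(y) - 2)
        else:
            raise NumericDegeneracyError(
                "both groups constant with different means: t undefined"
            )
    else:
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    mx, my = float(x.mean()), float(y.mean())
    ratio = np.inf if my == 0 and mx > 0 else (mx / my if my != 0 else 1.0)
    return ComparisonResult(t_stat, df, p, mx, my, float(ratio), crop_stratum, test)


def correlate(
    densities: list[float] | np.ndarray,
    covariate: list[float] | np.ndarray,
) -> CorrelationResult:
    """Spearman rank correlation of densities against a covariate.

    Average-rank transform then Pearson on ranks; the p-value uses the
    large-sample t approximation (appropriate for the n in play here, and
    for data that are neither normal nor log-normal).
    """
    x = np.asarray(densities, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InconsistentInputsError("inputs must be equal-length vectors")
    if len(x) < 3:
        raise NumericDegeneracyError("Spearman correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), int(len(x)))


def fractile_coverage(refuges: RefugeSet, ranking: pd.DataFrame) -> pd.DataFrame:
    """Refuge area per 5 % priority fractile and its cumulative fraction.

    Returns a 20-row table (fractile 1 = highest priority) with columns
    ``refuge_area_ha`` and ``cumulative_fraction`` (non-decreasing,
    ending at 1 whenever any refuge exists).
    """
    missing = refuges.member_ids - set(ranking.index)
    if missing:
        raise InconsistentInputsError(
            f"refuge members absent from ranking: {sorted(missing)}"
        )
    if "fractile_5" not in ranking.columns or "size_ha" not in ranking.columns:
        raise InconsistentInputsError("ranking lacks fractile_5/size_ha columns")
    members = ranking.loc[sorted(refuges.member_ids)]
    per = members.groupby("fractile_5")["size_ha"].sum()
    out = pd.DataFrame(
        {"refuge_area_ha": per.reindex(range(1, 21), fill_value=0.0)}
    )
    out.index.name = "fractile_5"
    total = out["refuge_area_ha"].sum()
    out["cumulative_fraction"] = (
        out["refuge_area_ha"].cumsum() / total if total > 0 else 0.0
    )
    return out


def estimate_efficiency(
    suitable_area_km2: float,
    grass_fraction: float,
    refuge_pasture_km2: float,
    density_refuge: float,
    density_nonrefuge: float,
) -> EfficiencyReport:
    """Share of the regional grazing pressure on grassland captured by refuges.

    Grassland area = suitable area × grass fraction; the non-refuge
    grassland is what remains after the refuge pasture.  Each stratum's
    grazing pressure is its area times its dropping density, and the
    share captured is the refuge pressure over the total.  No rounding
    is applied inside the computation.
    """
    if density_refuge < 0 or density_nonrefuge < 0:
        raise InvalidConfigurationError("densities must be >= 0")
    grassland = suitable_area_km2 * grass_fraction
    nonrefuge = grassland - refuge_pasture_km2
    if nonrefuge < 0:
        raise InfeasibleGeometryError(
            f"refuge pasture ({refuge_pasture_km2} km²) exceeds grassland "
            f"({grassland} km²)"
        )
    pressure_r = refuge_pasture_km2 * M2_PER_KM2 * density_refuge
    pressure_n = nonrefuge * M2_PER_KM2 * density_nonrefuge
    total = pressure_r + pressure_n
    share = pressure_r / total if total > 0 else 0.0
    area_share = refuge_pasture_km2 / grassland if grassland > 0 else 0.0
    return EfficiencyReport(
        suitable_area_km2=suitable_area_km2,
        grass_fraction=grass_fraction,
        grassland_area_km2=grassland,
        refuge_pasture_km2=refuge_pasture_km2,
        nonrefuge_pasture_km2=nonrefuge,
        density_refuge=density_refuge,
        density_nonrefuge=density_nonrefuge,
        pressure_refuge=pressure_r,
        pressure_nonrefuge=pressure_n,
        share_captured=share,
        area_share=area_share,
    )


def merged_unit_table(
    refuges: RefugeSet,
    survey: pd.DataFrame,
    ranking: pd.DataFrame,
) -> pd.DataFrame:
    """Per merged-unit area, mean density and roost distance.

    Adjoined refuge fields are analysed as one unit: the unit's area is
    the grouped field area, its density the average of the surveyed
    member densities, and its roost distance the minimum over members.
    Units with no surveyed member are dropped.
    """
    dens = survey.set_index("field_id")["mean_density_per_m2"]
    rows = []
    for uid, (unit, area) in enumerate(
        zip(refuges.merged_units, refuges.unit_areas_ha), start=1
    ):
        surveyed = [i for i in unit if i in dens.index]
        if not surveyed:
            continue
        rows.append(
            {
                "unit_id": uid,
                "n_fields": len(unit),
                "area_ha": area,
                "mean_density_per_m2": float(dens.loc[surveyed].mean()),
                "roost_distance_m": float(
                    ranking.loc[sorted(unit), "roost_distance_m"].min()
                ),
            }
        )
    return pd.DataFrame(rows)
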