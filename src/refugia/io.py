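"""GeoJSON / CSV / YAML readers and writers.

Coordinates are planar metres throughout (declared in the landscape's
``crs_note``), so GeoJSON is used purely as a feature-collection
container, without geographic CRS handling.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .allocate import RefugeSet
from .exceptions import InconsistentInputsError
from .landscape import Field, Landscape, Roost


def landscape_to_geojson(landscape: Landscape) -> dict:
    """Landscape as a GeoJSON FeatureCollection (fields + roosts)."""
    features = []
    for f in landscape.fields:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(f.boundary),
                "properties": {
                    "feature_type": "field",
                    "id": f.id,
                    "crop": f.crop,
                    "area_ha": round(f.area_ha, 6),
                    "historic_use_years": f.historic_use_years,
                },
            }
        )
    for r in landscape.roosts:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(r.geometry),
                "properties": {"feature_type": "roost", "id": r.id, "kind": r.kind},
            }
        )
    return {
        "type": "FeatureCollection",
        "crs_note": landscape.crs_note,
        "features": features,
    }


def landscape_from_geojson(doc: dict) -> Landscape:
    fields, roosts = [], []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        geom = shape(feat["geometry"])
        if props.get("feature_type") == "roost":
            roosts.append(Roost(props["id"], geom, props.get("kind", "coast")))
        else:
            fields.append(
                Field(
                    id=props["id"],
                    boundary=geom,
                    crop=props.get("crop", "other"),
                    historic_use_years=int(props.get("historic_use_years", 0)),
                )
            )
    return Landscape(
        fields=fields,
        roosts=roosts,
        crs_note=doc.get("crs_note", "planar metric coordinates"),
    )


def write_landscape(landscape: Landscape, path: str | Path) -> None:
    Path(path).write_text(json.dumps(landscape_to_geojson(landscape), indent=1))


def read_landscape(path: str | Path) -> Landscape:
    return landscape_from_geojson(json.loads(Path(path).read_text()))


def write_ranking(ranking: pd.DataFrame, path: str | Path) -> None:
    ranking.to_csv(path, float_format="%.6f")


def read_ranking(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="field_id", dtype={"field_id": str})


def refuges_to_geojson(refuges: RefugeSet, landscape: Landscape) -> dict:
    unit_of = {
        fid: u for u, unit in enumerate(refuges.merged_units, start=1) for fid in unit
    }
    features = []
    for fid in sorted(refuges.member_ids):
        f = landscape.field(fid)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(f.boundary),
                "properties": {
                    "id": fid,
                    "crop": f.crop,
                    "area_ha": round(f.area_ha, 6),
                    "unit_id": unit_of.get(fid, 0),
                },
            }
        )
    return {
        "type": "FeatureCollection",
        "cost_total_nok": refuges.cost_total,
        "status": refuges.status,
        "features": features,
    }


def write_refuges(refuges: RefugeSet, landscape: Landscape, path: str | Path) -> None:
    Path(path).write_text(json.dumps(refuges_to_geojson(refuges, landscape), indent=1))


def read_refuges(path: str | Path, landscape: Landscape) -> RefugeSet:
    """Rebuild a RefugeSet from its GeoJSON (unit structure from unit_id)."""
    doc = json.loads(Path(path).read_text())
    units: dict[int, set[str]] = {}
    members: set[str] = set()
    for feat in doc.get("features", []):
        fid = feat["properties"]["id"]
        members.add(fid)
        units.setdefault(int(feat["properties"].get("unit_id", 0)), set()).add(fid)
    unknown = members - set(landscape.field_ids)
    if unknown:
        raise InconsistentInputsError(
            f"refuge ids missing from landscape: {sorted(unknown)}"
        )
    ordered = [units[k] for k in sorted(units)]
    areas = [sum(landscape.field(i).area_ha for i in u) for u in ordered]
    return RefugeSet(
        member_ids=members,
        cost_total=float(doc.get("cost_total_nok", 0.0)),
        merged_units=ordered,
        unit_areas_ha=areas,
        status=doc.get("status", "ok"),
    )


def write_survey(survey: pd.DataFrame, path: str | Path) -> None:
    survey.to_csv(path, index=False, float_format="%.6f")


def read_survey(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"field_id": str})


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
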