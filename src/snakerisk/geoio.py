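"""Minimal GeoJSON reading and writing (planar coordinates in meters)."""

from __future__ import annotations

import json

from shapely.geometry import mapping, shape

__all__ = ["write_feature_collection", "read_feature_collection", "write_points"]


def write_feature_collection(path, geometries, properties) -> None:
    """Write shapely geometries + per-feature property dicts as GeoJSON."""
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(geometries, properties)
    ]
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_feature_collection(path):
    """Read GeoJSON -> (list of shapely geometries, list of property dicts)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    geoms, props = [], []
    for feat in doc["features"]:
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    return geoms, props


def write_points(path, xy_pairs, properties=None) -> None:
    from shapely.geometry import Point

    pts = [Point(x, y) for x, y in xy_pairs]
    if properties is None:
        properties = [{} for _ in pts]
    write_feature_collection(path, pts, properties)
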