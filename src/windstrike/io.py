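"""Plain-text I/O: GeoJSON for vector layers, CSV for point tables.

Coordinates are planar metres in an unspecified projected frame, stored
as-is in the GeoJSON coordinate arrays.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import shapely
import shapely.geometry

from .landscape import (
    BP_CLASS_LABELS,
    BP_LOWER_BORDERS,
    BreedingDensityMap,
    LandUseLayer,
)


def write_layer_geojson(layer: LandUseLayer, path) -> None:
    """One FeatureCollection per class, each polygon a feature."""
    geom = layer.geometry
    geoms = list(geom.geoms) if hasattr(geom, "geoms") else [geom]
    features = [
        {
            "type": "Feature",
            "properties": {"class": layer.class_name},
            "geometry": shapely.geometry.mapping(g),
        }
        for g in geoms
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_layer_geojson(path) -> LandUseLayer:
    with open(path) as fh:
        fc = json.load(fh)
    geoms = [shapely.geometry.shape(f["geometry"]) for f in fc["features"]]
    if not geoms:
        raise ValueError(f"no features in {path}")
    name = fc["features"][0]["properties"]["class"]
    return LandUseLayer(name, shapely.union_all(geoms))


def write_turbines_csv(turbines: pd.DataFrame, path) -> None:
    cols = [c for c in ("id", "x", "y", "status", "outcome", "probability") if c in turbines.columns]
    turbines[cols].to_csv(path, index=False)


def read_turbines_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_density_geojson(density: BreedingDensityMap, path) -> None:
    """Quadrant tiling with properties bp_class (1-based) and bp_lower."""
    x0, y0 = density.origin
    q = density.quadrant_size
    features = []
    n_rows, n_cols = density.classes.shape
    for r in range(n_rows):
        for c in range(n_cols):
            k = int(density.classes[r, c])
            poly = shapely.box(x0 + c * q, y0 + r * q, x0 + (c + 1) * q, y0 + (r + 1) * q)
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "bp_class": k + 1,
                        "bp_class_label": BP_CLASS_LABELS[k],
                        "bp_lower": int(BP_LOWER_BORDERS[k]),
                    },
                    "geometry": shapely.geometry.mapping(poly),
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_density_geojson(path) -> BreedingDensityMap:
    with open(path) as fh:
        fc = json.load(fh)
    cells = []
    for f in fc["features"]:
        minx, miny, maxx, maxy = shapely.geometry.shape(f["geometry"]).bounds
        cells.append((minx, miny, maxx - minx, f["properties"]["bp_class"] - 1))
    xs = sorted({c[0] for c in cells})
    ys = sorted({c[1] for c in cells})
    q = cells[0][2]
    classes = np.zeros((len(ys), len(xs)), dtype=int)
    x_index = {v: i for i, v in enumerate(xs)}
    y_index = {v: i for i, v in enumerate(ys)}
    for minx, miny, _, k in cells:
        classes[y_index[miny], x_index[minx]] = k
    return BreedingDensityMap((xs[0], ys[0]), q, classes)
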