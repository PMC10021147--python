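"""Areal and point geographies, neighborhood structure, and spatial weights.

Areal disease-mapping models operate on a neighborhood graph over the study
units (administrative regions or survey-cluster points).  This module builds
that graph from polygon contiguity or inter-point distances, attaches binary
or row-standardized weights, and reads/writes the two plain-text formats the
pipeline touches: GeoJSON (RFC 7946) for geometry and a GAL-style adjacency
list for graphs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "AdjacencyGraph",
    "SpatialWeights",
    "GeoLayer",
    "read_geojson",
    "read_polygons",
    "write_geojson",
    "queen_contiguity",
    "min_distance_band",
    "make_weights",
    "subgraph",
    "read_adjacency_list",
    "write_adjacency_list",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class AdjacencyGraph:
    """Symmetric neighborhood structure over ordered, uniquely-labelled units.

    Units are referred to by 0-based index internally; all I/O uses the
    original string labels in ``unit_ids``.
    """

    unit_ids: list[str]
    neighbors: list[set[int]]

    def __post_init__(self) -> None:
        n = len(self.unit_ids)
        if len(set(self.unit_ids)) != n:
            raise ValueError("unit_ids must be unique")
        if len(self.neighbors) != n:
            raise ValueError("neighbors list length must match unit_ids")
        self.neighbors = [set(int(j) for j in nb) for nb in self.neighbors]
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError(f"unit {self.unit_ids[i]} lists itself as neighbor")
            for j in nb:
                if not 0 <= j < n:
                    raise ValueError(f"neighbor index {j} out of range for unit {i}")
                if i not in self.neighbors[j]:
                    raise ValueError(
                        f"asymmetric adjacency: {self.unit_ids[i]} -> "
                        f"{self.unit_ids[j]} has no reverse link"
                    )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbors) // 2

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=int)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edge list with i < j."""
        return [(i, j) for i, nb in enumerate(self.neighbors) for j in nb if i < j]

    def isolated(self) -> list[int]:
        return [i for i, nb in enumerate(self.neighbors) if not nb]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_units))
        g.add_edges_from(self.edges())
        return g

    def component_labels(self) -> np.ndarray:
        """Index of the connected component each unit belongs to."""
        labels = np.empty(self.n_units, dtype=int)
        for k, comp in enumerate(nx.connected_components(self.to_networkx())):
            for i in comp:
                labels[i] = k
        return labels


@dataclass
class SpatialWeights:
    """Weight matrix over an adjacency graph, binary or row-standardized."""

    graph: AdjacencyGraph
    style: str = "row"  # "row" (row-standardized) or "binary"

    def __post_init__(self) -> None:
        if self.style not in ("row", "binary"):
            raise ValueError(f"unknown weights style {self.style!r}")
        n = self.graph.n_units
        w = np.zeros((n, n))
        for i, nb in enumerate(self.graph.neighbors):
            for j in nb:
                w[i, j] = 1.0
        if self.style == "row":
            deg = w.sum(axis=1)
            isolated = deg == 0
            if isolated.any():
                bad = [self.graph.unit_ids[i] for i in np.flatnonzero(isolated)]
                warnings.warn(
                    f"row-standardizing with isolated units (all-zero rows): {bad}"
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(isolated[:, None], 0.0, w / np.where(deg == 0, 1.0, deg)[:, None])
        self.matrix = w

    @property
    def s0(self) -> float:
        """Sum of all weights: 2x edge count (binary) or #non-isolated (row)."""
        return float(self.matrix.sum())

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Spatial lag Wx."""
        return self.matrix @ np.asarray(values, dtype=float)


@dataclass
class GeoLayer:
    """Units with one geometry each (polygon or point) plus attributes."""

    unit_ids: list[str]
    geometries: list[BaseGeometry]
    attributes: dict[str, list] = field(default_factory=dict)
    lonlat: bool = True  # coordinates interpreted as lon/lat degrees

    def __post_init__(self) -> None:
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit ids in layer")
        if len(self.geometries) != len(self.unit_ids):
            raise ValueError("one geometry required per unit id")
        for uid, g in zip(self.unit_ids, self.geometries):
            if not np.all(np.isfinite(np.asarray(g.bounds))):
                raise ValueError(f"non-finite coordinates for unit {uid}")
        for key, col in self.attributes.items():
            if len(col) != len(self.unit_ids):
                raise ValueError(f"attribute {key!r} length mismatch")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def with_attribute(self, name: str, values) -> "GeoLayer":
        attrs = dict(self.attributes)
        attrs[name] = list(values)
        return GeoLayer(list(self.unit_ids), list(self.geometries), attrs, self.lonlat)


def read_geojson(path, id_property: str = "id") -> GeoLayer:
    """Read a GeoJSON FeatureCollection into a GeoLayer.

    The unit id is taken from feature ``properties[id_property]`` (falling
    back to the top-level feature ``id``).  Feature order is preserved.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    ids: list[str] = []
    geoms: list[BaseGeometry] = []
    attrs: dict[str, list] = {}
    features = doc.get("features", [])
    for k, feat in enumerate(features):
        props = feat.get("properties") or {}
        uid = props.get(id_property, feat.get("id"))
        if uid is None:
            raise ValueError(f"feature {k}: missing id property {id_property!r}")
        uid = str(uid)
        if uid in ids:
            raise ValueError(f"feature {k}: duplicate id {uid!r}")
        ids.append(uid)
        geoms.append(shape(feat["geometry"]))
        for key, val in props.items():
            if key == id_property:
                continue
            attrs.setdefault(key, [None] * len(features))[k] = val
    return GeoLayer(ids, geoms, {k: list(v) for k, v in attrs.items()})


# Polygon reader named for its pipeline role; same format as read_geojson.
read_polygons = read_geojson


def write_geojson(layer: GeoLayer, path, id_property: str = "id") -> None:
    features = []
    for k, (uid, geom) in enumerate(zip(layer.unit_ids, layer.geometries)):
        props = {id_property: uid}
        for key, col in layer.attributes.items():
            val = col[k]
            if isinstance(val, (np.floating, np.integer)):
                val = val.item()
            props[key] = val
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def queen_contiguity(layer: GeoLayer) -> AdjacencyGraph:
    """Queen contiguity: units adjacent iff polygons share >= 1 boundary point."""
    n = layer.n_units
    if n < 2:
        raise ValueError("queen contiguity needs at least 2 polygons")
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if layer.geometries[i].intersects(layer.geometries[j]):
                neighbors[i].add(j)
                neighbors[j].add(i)
    graph = AdjacencyGraph(list(layer.unit_ids), neighbors)
    if graph.n_edges == 0:
        warnings.warn("queen contiguity produced no edges (all units isolated)")
    return graph


def _pairwise_distances(layer: GeoLayer) -> np.ndarray:
    coords = np.array([[g.x, g.y] for g in layer.geometries])
    if layer.lonlat:
        lon = np.radians(coords[:, 0])[:, None]
        lat = np.radians(coords[:, 1])[:, None]
        dlat = lat - lat.T
        dlon = lon - lon.T
        a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
        return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def min_distance_band(layer: GeoLayer) -> AdjacencyGraph:
    """Distance-band adjacency with the threshold set so every point gets
    at least one neighbor: d* = max over points of nearest-neighbor distance.

    Great-circle (haversine) distance when the layer declares lon/lat,
    Euclidean otherwise.  Coincident points are forced adjacent with a warning.
    """
    n = layer.n_units
    if n < 2:
        raise ValueError("distance-band adjacency needs at least 2 points")
    dist = _pairwise_distances(layer)
    np.fill_diagonal(dist, np.inf)
    nearest = dist.min(axis=1)
    if np.any(nearest == 0):
        warnings.warn("duplicate coordinates present; coincident pairs forced adjacent")
    d_star = float(nearest.max())
    # small relative tolerance so the defining nearest neighbor is never lost
    adj = dist <= d_star * (1 + 1e-12)
    neighbors = [set(np.flatnonzero(adj[i]).tolist()) for i in range(n)]
    return AdjacencyGraph(list(layer.unit_ids), neighbors)


def make_weights(graph: AdjacencyGraph, style: str = "row") -> SpatialWeights:
    """Attach binary or row-standardized weights to an adjacency graph."""
    return SpatialWeights(graph, style=style)


def subgraph(graph: AdjacencyGraph, keep: list[int]) -> AdjacencyGraph:
    """Induced subgraph on the given unit indices (order preserved)."""
    keep = list(keep)
    new_index = {old: new for new, old in enumerate(keep)}
    neighbors = [
        {new_index[j] for j in graph.neighbors[old] if j in new_index} for old in keep
    ]
    return AdjacencyGraph([graph.unit_ids[old] for old in keep], neighbors)


def write_adjacency_list(graph: AdjacencyGraph, path) -> None:
    """Write a GAL-style plain-text adjacency file.

    Format: first line ``n``; then for each unit a header line ``id k``
    followed by one line with its k neighbor ids (space separated).
    """
    with open(path, "w") as fh:
        fh.write(f"{graph.n_units}\n")
        for i, uid in enumerate(graph.unit_ids):
            nb = sorted(graph.neighbors[i])
            fh.write(f"{uid} {len(nb)}\n")
            fh.write(" ".join(graph.unit_ids[j] for j in nb) + "\n")


def read_adjacency_list(path) -> AdjacencyGraph:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    lines = [ln.strip() for ln in tokens if ln.strip()]
    n = int(lines[0])
    ids: list[str] = []
    raw: list[list[str]] = []
    pos = 1
    for _ in range(n):
        uid, k = lines[pos].rsplit(None, 1)
        k = int(k)
        ids.append(uid)
        raw.append(lines[pos + 1].split() if k > 0 else [])
        if len(raw[-1]) != k:
            raise ValueError(f"{path}: unit {uid} declares {k} neighbors, lists {len(raw[-1])}")
        pos += 2 if k > 0 else 1
    index = {uid: i for i, uid in enumerate(ids)}
    if len(index) != n:
        raise ValueError(f"{path}: duplicate unit ids")
    neighbors = [set() for _ in range(n)]
    for i, nb_ids in enumerate(raw):
        for nb in nb_ids:
            if nb not in index:
                raise ValueError(f"{path}: unknown neighbor id {nb!r} for unit {ids[i]}")
            neighbors[i].add(index[nb])
    for i in range(n):
        for j in neighbors[i]:
            if i not in neighbors[j]:
                raise ValueError(
                    f"{path}: asymmetric listing for pair ({ids[i]}, {ids[j]})"
                )
    return AdjacencyGraph(ids, neighbors)
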