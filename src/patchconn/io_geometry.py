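"""Read, repair, clip and measure polygon habitat layers.

A habitat layer is a set of identified polygons in a projected (metric)
coordinate system.  This module turns GeoJSON files into :class:`PatchLayer`
objects, fixes invalid geometries, clips to a boundary, computes the pairwise
edge-to-edge distances that all threshold graphs are built from, and reads and
writes Conefor-style node/connection text files.

Distances follow the edge-to-edge convention: the minimum Euclidean distance
between polygon boundaries, zero for touching or overlapping patches.  A
centroid convention is available as a switch but disconnects large adjacent
patches and is not the default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree
from shapely.validation import make_valid

from .errors import (
    ConeforFormatError,
    DuplicatePatchIdError,
    EmptyLayerError,
    GeographicCRSError,
    InvalidBoundaryError,
    LayerReadError,
)

__all__ = [
    "PatchLayer",
    "EdgeList",
    "read_patch_layer",
    "repair_and_clip",
    "pairwise_edge_distances",
    "write_conefor_files",
    "read_conefor_files",
]

_GEOGRAPHIC_CRS_TOKENS = ("4326", "CRS84", "crs84")

M2_PER_HA = 10_000.0


@dataclass
class PatchLayer:
    """Identified habitat polygons with areas in m².

    Attributes
    ----------
    ids
        Unique integer patch identifiers, one per polygon.
    geometries
        Valid (multi)polygons in a projected CRS with meter units.
    areas
        Polygon areas in m², recomputed from the geometries.
    """

    ids: list[int]
    geometries: list[BaseGeometry]
    areas: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.areas is None:
            self.areas = np.array([g.area for g in self.geometries], float)
        else:
            self.areas = np.asarray(self.areas, float)
        if len(set(self.ids)) != len(self.ids):
            raise DuplicatePatchIdError("duplicate patch id in layer")
        if len(self.ids) != len(self.geometries):
            raise ValueError("ids and geometries length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def areas_ha(self) -> np.ndarray:
        return self.areas / M2_PER_HA

    def area_map(self) -> dict[int, float]:
        """Map patch id -> area in m²."""
        return dict(zip(self.ids, self.areas.tolist()))

    def to_geojson(self, path: str | Path, extra_properties: dict[int, dict] | None = None) -> None:
        """Write the layer as a GeoJSON FeatureCollection.

        ``extra_properties`` maps patch id -> additional property dict
        (used e.g. for component labels or priority flags).
        """
        features = []
        for pid, geom, area in zip(self.ids, self.geometries, self.areas.tolist()):
            props = {"patch_id": pid, "area_m2": area, "area_ha": area / M2_PER_HA}
            if extra_properties and pid in extra_properties:
                props.update(extra_properties[pid])
            features.append(
                {"type": "Feature", "properties": props, "geometry": mapping(geom)}
            )
        doc = {"type": "FeatureCollection", "features": features}
        Path(path).write_text(json.dumps(doc, sort_keys=True), encoding="utf-8")


@dataclass
class EdgeList:
    """Pairwise edge-to-edge distances up to a cutoff.

    Pairs are stored once with ``id_a < id_b``; distances are in meters and
    never exceed ``cutoff``.  Touching or overlapping patches have distance 0.
    """

    id_a: np.ndarray
    id_b: np.ndarray
    distance: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.id_a = np.asarray(self.id_a, int)
        self.id_b = np.asarray(self.id_b, int)
        self.distance = np.asarray(self.distance, float)
        if np.any(self.id_a >= self.id_b):
            raise ValueError("edge pairs must satisfy id_a < id_b")
        if np.any(self.distance < 0) or np.any(self.distance > self.cutoff):
            raise ValueError("edge distances must lie in [0, cutoff]")

    def __len__(self) -> int:
        return len(self.id_a)

    def pairs(self) -> Iterable[tuple[int, int, float]]:
        return zip(self.id_a.tolist(), self.id_b.tolist(), self.distance.tolist())


def _looks_geographic(doc: dict) -> bool:
    crs = doc.get("crs")
    if not isinstance(crs, dict):
        return False
    name = str(crs.get("properties", {}).get("name", ""))
    return any(tok in name for tok in _GEOGRAPHIC_CRS_TOKENS)


def read_patch_layer(path: str | Path, id_field: str | None = None) -> PatchLayer:
    """Read a GeoJSON polygon layer into a :class:`PatchLayer`.

    Parameters
    ----------
    path
        GeoJSON FeatureCollection (or a bare geometry / single feature).
    id_field
        Property holding patch ids; if ``None``, sequential ids starting
        at 1 are assigned in file order.

    Raises
    ------
    LayerReadError
        Unreadable or non-GeoJSON file.
    GeographicCRSError
        The file declares a geographic (lon/lat) CRS; indices need meters.
    EmptyLayerError
        No polygonal features present.
    DuplicatePatchIdError
        ``id_field`` has repeated values.
    """
    p = Path(path)
    if not p.exists():
        raise LayerReadError(f"no such file: {p}")
    try:
        doc = json.loads(p.read_text(encoding="utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise LayerReadError(f"not a readable GeoJSON file: {p}: {exc}") from exc
    if not isinstance(doc, dict):
        raise LayerReadError(f"not a GeoJSON object: {p}")
    if _looks_geographic(doc):
        raise GeographicCRSError(
            "layer declares a geographic CRS (degrees); reproject to a metric CRS first"
        )

    if doc.get("type") == "FeatureCollection":
        features = doc.get("features", [])
    elif doc.get("type") == "Feature":
        features = [doc]
    elif "type" in doc:  # bare geometry
        features = [{"type": "Feature", "properties": {}, "geometry": doc}]
    else:
        raise LayerReadError(f"unrecognized GeoJSON structure in {p}")

    ids: list[int] = []
    geoms: list[BaseGeometry] = []
    for k, feat in enumerate(features):
        geom = shape(feat["geometry"])
        if geom.is_empty:
            continue
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise LayerReadError(
                f"feature {k}: expected polygonal geometry, got {geom.geom_type}"
            )
        if id_field is not None:
            props = feat.get("properties") or {}
            if id_field not in props:
                raise LayerReadError(f"feature {k}: missing id field {id_field!r}")
            ids.append(int(props[id_field]))
        else:
            ids.append(len(ids) + 1)
        geoms.append(geom)
    if not geoms:
        raise EmptyLayerError(f"no polygon features in {p}")
    layer = PatchLayer(ids, geoms)
    return repair_and_clip(layer, boundary=None)


def repair_and_clip(layer: PatchLayer, boundary: BaseGeometry | None = None) -> PatchLayer:
    """Fix invalid geometries and optionally clip to a boundary polygon.

    Invalid polygons (self-intersections, bow-ties) are repaired with
    ``make_valid``, which preserves the covered region.  With a boundary,
    each patch is replaced by its intersection with the boundary; patches
    falling entirely outside are dropped.  Areas are recomputed.
    """
    if boundary is not None and not boundary.is_valid:
        boundary = make_valid(boundary)
        if boundary.is_empty or not boundary.is_valid:
            raise InvalidBoundaryError("boundary polygon is invalid and unrepairable")

    ids: list[int] = []
    geoms: list[BaseGeometry] = []
    for pid, geom in zip(layer.ids, layer.geometries):
        if not geom.is_valid:
            geom = make_valid(geom)
            # make_valid may return a collection with stray lines/points
            if geom.geom_type == "GeometryCollection":
                polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
                geom = shapely.union_all(polys) if polys else shapely.Polygon()
        if boundary is not None:
            geom = geom.intersection(boundary)
            if geom.geom_type == "GeometryCollection":
                polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
                geom = shapely.union_all(polys) if polys else shapely.Polygon()
        if geom.is_empty or geom.area <= 0:
            continue
        ids.append(pid)
        geoms.append(geom)
    return PatchLayer(ids, geoms)


def pairwise_edge_distances(
    layer: PatchLayer, cutoff: float, *, method: str = "edge"
) -> EdgeList:
    """Find all unordered patch pairs within ``cutoff`` meters.

    Uses an STR packed R-tree so only nearby candidate pairs are measured;
    far-apart pairs are never enumerated.  ``method`` selects the distance
    convention: ``"edge"`` (minimum boundary-to-boundary, the default and the
    convention assumed throughout) or ``"centroid"``.

    Returns an :class:`EdgeList` with ``id_a < id_b`` and all distances
    ``<= cutoff`` (inclusive).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if method not in ("edge", "centroid"):
        raise ValueError(f"unknown distance method {method!r}")

    ids = np.asarray(layer.ids, int)
    if method == "centroid":
        pts = shapely.centroid(np.array(layer.geometries, dtype=object))
        geoms = pts
    else:
        geoms = np.array(layer.geometries, dtype=object)

    tree = STRtree(list(geoms))
    left, right = tree.query(list(geoms), predicate="dwithin", distance=cutoff)
    keep = left < right  # each unordered pair once, no self-pairs
    left, right = left[keep], right[keep]
    dist = shapely.distance(geoms[left], geoms[right])
    # dwithin is inclusive, but guard against FP noise at the boundary
    inside = dist <= cutoff
    left, right, dist = left[inside], right[inside], dist[inside]

    a, b = ids[left], ids[right]
    swap = a > b
    a[swap], b[swap] = b[swap], a[swap]
    order = np.lexsort((b, a))
    return EdgeList(a[order], b[order], dist[order], float(cutoff))


def write_conefor_files(
    layer: PatchLayer,
    edges: EdgeList,
    node_path: str | Path,
    connection_path: str | Path,
    *,
    area_unit: str = "ha",
) -> None:
    """Write Conefor-style node and connection text files.

    Node file: one ``id<TAB>area`` line per patch; connection file: one
    ``id_a<TAB>id_b<TAB>distance`` line per pair.  No headers.  Areas are
    written in hectares by default (``area_unit="m2"`` keeps m²); distances
    are meters.  Numbers carry 8 significant digits so a write/read cycle
    preserves values to better than 1e-6 relative.
    """
    known = set(layer.ids)
    for ea, eb in zip(edges.id_a.tolist(), edges.id_b.tolist()):
        if ea not in known or eb not in known:
            raise ConeforFormatError(f"edge references unknown patch id: ({ea}, {eb})")
    div = M2_PER_HA if area_unit == "ha" else 1.0
    with open(node_path, "w", encoding="utf-8") as fh:
        for pid, area in zip(layer.ids, layer.areas.tolist()):
            fh.write(f"{pid}\t{area / div:.8g}\n")
    with open(connection_path, "w", encoding="utf-8") as fh:
        for a, b, d in edges.pairs():
            fh.write(f"{a}\t{b}\t{d:.8g}\n")


def read_conefor_files(
    node_path: str | Path, connection_path: str | Path, *, cutoff: float | None = None
) -> tuple[list[tuple[int, float]], EdgeList]:
    """Read Conefor node/connection files back into tables.

    Returns ``(nodes, edges)`` where nodes is a list of ``(id, area)`` in the
    unit the file was written with, and edges an :class:`EdgeList` whose
    cutoff is ``cutoff`` or, if omitted, the maximum distance present.

    Raises
    ------
    ConeforFormatError
        Malformed lines, duplicate node ids, or a connection referencing an
        id absent from the node file.
    """
    nodes: list[tuple[int, float]] = []
    seen: set[int] = set()
    for ln, line in enumerate(Path(node_path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ConeforFormatError(f"{node_path}:{ln}: expected 'id area'")
        pid, area = int(parts[0]), float(parts[1])
        if pid in seen:
            raise ConeforFormatError(f"{node_path}:{ln}: duplicate patch id {pid}")
        seen.add(pid)
        nodes.append((pid, area))

    aa: list[int] = []
    bb: list[int] = []
    dd: list[float] = []
    for ln, line in enumerate(Path(connection_path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ConeforFormatError(f"{connection_path}:{ln}: expected 'id_a id_b dist'")
        a, b, d = int(parts[0]), int(parts[1]), float(parts[2])
        if a not in seen or b not in seen:
            raise ConeforFormatError(
                f"{connection_path}:{ln}: connection references unknown id"
            )
        if a == b:
            raise ConeforFormatError(f"{connection_path}:{ln}: self-pair {a}")
        if a > b:
            a, b = b, a
        aa.append(a)
        bb.append(b)
        dd.append(d)
    if cutoff is None:
        cutoff = max(dd) if dd else math.inf
    return nodes, EdgeList(np.array(aa, int), np.array(bb, int), np.array(dd), float(cutoff))
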