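"""Shared fixtures and oracle helpers for the patchconn test suite."""

from __future__ import annotations

import itertools
import json

import numpy as np
import pytest
from shapely.geometry import box, mapping

from patchconn import EdgeList, build_threshold_graph


def make_edge_list(pairs, cutoff):
    """EdgeList from (id_a, id_b, distance) triples (may be empty)."""
    if not pairs:
        return EdgeList(np.array([], int), np.array([], int), np.array([]), cutoff)
    a, b, d = zip(*pairs)
    a, b = np.asarray(a, int), np.asarray(b, int)
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    return EdgeList(a2, b2, np.asarray(d, float), cutoff)


def random_graph(rng, n_max=60, p_edge=0.12, area_range=(0.5, 5.0)):
    """A random threshold graph plus its raw (areas_ha, links) for oracles.

    Areas are drawn in ha and stored in the graph in m²; all link distances
    are 1 with threshold 1, so topology is what varies.
    """
    n = int(rng.integers(2, n_max + 1))
    ids = list(range(1, n + 1))
    areas_ha = {i: float(rng.uniform(*area_range)) for i in ids}
    links = [p for p in itertools.combinations(ids, 2) if rng.random() < p_edge]
    edges = make_edge_list([(a, b, 1.0) for a, b in links], cutoff=2.0)
    g = build_threshold_graph({i: a * 1e4 for i, a in areas_ha.items()}, edges, 1.0)
    return g, areas_ha, links


def brute_iic_num(areas_ha: dict, links: list) -> float:
    """Exhaustive ordered-pair IIC numerator with Floyd–Warshall link counts.

    Independent of the package path: dense Floyd–Warshall on unit weights,
    then a double loop over every ordered pair (diagonal included,
    unreachable pairs contribute zero).
    """
    ids = sorted(areas_ha)
    n = len(ids)
    pos = {i: k for k, i in enumerate(ids)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in links:
        dist[pos[a], pos[b]] = dist[pos[b], pos[a]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k][:, None] + dist[k, :][None, :])
    a = np.array([areas_ha[i] for i in ids])
    terms = np.where(np.isfinite(dist), np.outer(a, a) / (1.0 + dist), 0.0)
    return float(terms.sum())


def write_geojson(path, geoms, properties=None, crs_name=None):
    """Minimal GeoJSON writer for test inputs."""
    feats = []
    for k, g in enumerate(geoms):
        props = properties[k] if properties else {}
        feats.append({"type": "Feature", "properties": props, "geometry": mapping(g)})
    doc = {"type": "FeatureCollection", "features": feats}
    if crs_name:
        doc["crs"] = {"type": "name", "properties": {"name": crs_name}}
    path.write_text(json.dumps(doc))
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def unit_squares_layer(tmp_path):
    """Three disjoint unit squares as a GeoJSON file."""
    geoms = [box(0, 0, 1, 1), box(5, 0, 6, 1), box(0, 5, 1, 6)]
    return write_geojson(tmp_path / "squares.geojson", geoms)
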