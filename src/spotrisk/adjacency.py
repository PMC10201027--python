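"""Symmetric neighbourhood structures for intrinsic CAR priors.

An intrinsic conditional autoregressive (ICAR) prior smooths an area-level
random effect towards the average of its neighbours, so every model that
uses one needs a validated, symmetric adjacency structure.  This module
builds that structure from GAL neighbour files, edge-list CSVs, polygon
contiguity (GeoJSON) or programmatically, and records the properties the
ICAR conditional requires (no self-loops, symmetry, neighbour counts,
connectedness).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import scipy.sparse as sp
from shapely.geometry import shape

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "read_gal",
    "read_edge_list",
    "contiguity_from_polygons",
]


@dataclass
class AdjacencyGraph:
    """Binary, symmetric area adjacency.

    Attributes
    ----------
    area_ids : list
        Ordered area identifiers; the ordering defines the index used by
        every matrix-valued quantity downstream.
    neighbours : list of list of int
        For each area, the sorted indices of its neighbours.
    """

    area_ids: list
    neighbours: list = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("area_ids must be unique")
        n = len(self.area_ids)
        for i, nbrs in enumerate(self.neighbours):
            for j in nbrs:
                if j == i:
                    raise ValueError(f"self-loop at area {self.area_ids[i]}")
                if not 0 <= j < n:
                    raise ValueError("neighbour index out of range")
                if i not in self.neighbours[j]:
                    raise ValueError("adjacency is not symmetric")
        self.neighbours = [sorted(set(nbrs)) for nbrs in self.neighbours]

    # -- basic properties -------------------------------------------------

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_i(self) -> np.ndarray:
        """Neighbour count per area."""
        return np.array([len(nbrs) for nbrs in self.neighbours], dtype=int)

    @property
    def n_edges(self) -> int:
        return int(self.n_i.sum()) // 2

    @property
    def connected(self) -> bool:
        return nx.is_connected(self.to_networkx()) if self.n_areas else False

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        for i, nbrs in enumerate(self.neighbours):
            g.add_edges_from((i, j) for j in nbrs if j > i)
        return g

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse binary adjacency matrix in area order."""
        rows, cols = [], []
        for i, nbrs in enumerate(self.neighbours):
            rows.extend([i] * len(nbrs))
            cols.extend(nbrs)
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)),
                             shape=(self.n_areas, self.n_areas))

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - A (the ICAR precision up to tau)."""
        a = self.adjacency_matrix().toarray()
        return np.diag(self.n_i.astype(float)) - a

    def edge_list(self) -> np.ndarray:
        """(n_edges, 2) array of index pairs with i < j."""
        pairs = [(i, j) for i, nbrs in enumerate(self.neighbours)
                 for j in nbrs if j > i]
        return np.array(pairs, dtype=int).reshape(-1, 2)

    def colouring(self) -> list:
        """Greedy proper colouring; areas in one colour class share no edge.

        Used by the sampler to update ICAR components in conditionally
        independent blocks.
        """
        colours = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        k = max(colours.values(), default=-1) + 1
        classes = [[] for _ in range(k)]
        for node, c in colours.items():
            classes[c].append(node)
        return [np.array(sorted(c), dtype=int) for c in classes]

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_edges(cls, area_ids: list, edges: list) -> "AdjacencyGraph":
        """Build from (id_a, id_b) pairs; symmetry is implied."""
        index = {a: i for i, a in enumerate(area_ids)}
        neighbours = [set() for _ in area_ids]
        for a, b in edges:
            if a not in index or b not in index:
                missing = a if a not in index else b
                raise ValueError(f"edge references unknown area id {missing!r}")
            i, j = index[a], index[b]
            if i == j:
                raise ValueError(f"self-loop at area {a!r}")
            neighbours[i].add(j)
            neighbours[j].add(i)
        return cls(list(area_ids), [sorted(s) for s in neighbours])


def read_gal(path, area_ids: list | None = None) -> AdjacencyGraph:
    """Read a GAL neighbour file.

    The format is the standard GeoDa GAL layout: a header line whose last
    (or only) numeric token is the number of areas, then for each area a
    line ``id k`` followed by a line with its ``k`` neighbour ids.
    Asymmetric listings are symmetrised with a warning; ids absent from
    ``area_ids`` (when given) raise.
    """
    with open(path, "r", encoding="utf-8") as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    header = tokens_by_line[0]
    # header is either "n" or "0 n shapefile key"
    n = int(header[1]) if len(header) >= 2 else int(header[0])
    ids, nbr_ids = [], {}
    k = 1
    for _ in range(n):
        aid, deg = tokens_by_line[k][0], int(tokens_by_line[k][1])
        if deg > 0:
            nbrs = tokens_by_line[k + 1]
            if len(nbrs) != deg:
                raise ValueError(f"GAL: area {aid} declares {deg} neighbours, "
                                 f"lists {len(nbrs)}")
            k += 2
        else:
            nbrs = []
            k += 1
        ids.append(aid)
        nbr_ids[aid] = nbrs
    if area_ids is not None:
        known = set(map(str, area_ids))
        for aid in ids:
            if aid not in known:
                raise ValueError(f"GAL area id {aid!r} not in panel")
        order = [str(a) for a in area_ids]
    else:
        order = ids
    index = {a: i for i, a in enumerate(order)}
    neighbours = [set() for _ in order]
    asymmetric = False
    for aid, nbrs in nbr_ids.items():
        for b in nbrs:
            if b not in index:
                raise ValueError(f"GAL neighbour id {b!r} unknown")
            i, j = index[aid], index[b]
            if aid not in nbr_ids.get(b, []):
                asymmetric = True
            neighbours[i].add(j)
            neighbours[j].add(i)
    if asymmetric:
        warnings.warn("GAL file is asymmetric; symmetrised", stacklevel=2)
        logger.warning("GAL file %s is asymmetric; symmetrised", path)
    return AdjacencyGraph(list(order), [sorted(s) for s in neighbours])


def read_edge_list(path, area_ids: list) -> AdjacencyGraph:
    """Read an edge-list CSV with columns area_id_1, area_id_2."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs two columns")
    edges = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return AdjacencyGraph.from_edges([str(a) for a in area_ids], edges)


def contiguity_from_polygons(geojson_path, rule: str = "queen",
                             id_property: str = "area_id") -> AdjacencyGraph:
    """Polygon contiguity from a GeoJSON FeatureCollection.

    queen: polygons sharing at least one boundary point are neighbours.
    rook:  only a shared boundary segment of positive length counts.
    """
    if rule not in ("queen", "rook"):
        raise ValueError("rule must be 'queen' or 'rook'")
    with open(geojson_path, "r", encoding="utf-8") as fh:
        gj = json.load(fh)
    ids, geoms = [], []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ValueError(f"feature missing property {id_property!r}")
        ids.append(str(props[id_property]))
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for area {props[id_property]!r}")
        geoms.append(geom)
    n = len(ids)
    neighbours = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            inter = geoms[i].boundary.intersection(geoms[j].boundary)
            if inter.is_empty:
                continue
            if rule == "queen" or inter.length > 0:
                neighbours[i].add(j)
                neighbours[j].add(i)
    g = AdjacencyGraph(ids, [sorted(s) for s in neighbours])
    if n > 1 and not g.connected:
        logger.warning("polygon contiguity graph is disconnected")
    return g
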