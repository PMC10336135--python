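"""Spatial neighborhood graphs over cellular maps and architecture statistics.

A cellular map is a lattice of patches, each carrying a transcriptional-subtype
label. Two patches are neighbors when they lie within a two-patch Chebyshev
distance, so an interior patch has 24 neighbors (the 5x5 block minus itself).
On this graph we compute the per-class clustering coefficient

    Cluster(m) = I(M,M) / (I(M,M) + I(M,K)),

the fraction of class-m-incident edges joining two class-m patches, and the
interaction matrix

    Interaction(m,k) = I(M,K) / (total malignant-malignant edges),

with immune classes excluded from the denominator. ``abstractive_network``
iteratively collapses neighborhoods dominated by one subtype into super-nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: undirected offsets covering each Chebyshev<=2 lattice edge exactly once
_HALF_OFFSETS = [
    (dx, dy)
    for dx in (0, 1, 2)
    for dy in (-2, -1, 0, 1, 2)
    if (dx, dy) != (0, 0) and not (dx == 0 and dy < 0)
]
assert len(_HALF_OFFSETS) == 12


class DuplicatePositionError(ValueError):
    pass


class UndefinedStatistic(Exception):
    """A graph statistic has no value (class absent or isolated)."""


@dataclass
class CellularMap:
    """Lattice of patch subtype labels.

    ``labels`` is a 2-D array indexed [y, x] (row-major, 0-based); ``x`` is the
    column coordinate and ``y`` the row coordinate.
    """

    labels: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 2-D lattice")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted({str(v) for v in self.labels.ravel()})

    def to_frame(self) -> pd.DataFrame:
        ys, xs = np.indices(self.labels.shape)
        return pd.DataFrame(
            {"x": xs.ravel(), "y": ys.ravel(), "label": self.labels.ravel()}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str = "sample") -> "CellularMap":
        if df.duplicated(subset=["x", "y"]).any():
            raise DuplicatePositionError("duplicate (x, y) positions in label map")
        w = int(df["x"].max()) + 1
        h = int(df["y"].max()) + 1
        labels = np.full((h, w), None, dtype=object)
        labels[df["y"].to_numpy(int), df["x"].to_numpy(int)] = df["label"].to_numpy()
        if (labels == None).any():  # noqa: E711 -- object-array sentinel scan
            raise ValueError("label map does not cover the full lattice")
        return cls(labels=labels, sample_id=sample_id)


def build_neighborhood_graph(cmap: CellularMap) -> nx.Graph:
    """Build the Chebyshev-distance-<=2 neighborhood graph of a cellular map.

    Nodes are ``(x, y)`` tuples with a ``cls`` attribute; each undirected edge
    is stored once. Max degree is 24.
    """
    h, w = cmap.labels.shape
    if h * w < 2:
        raise ValueError("need at least 2 patches to build a graph")
    G = nx.Graph()
    G.graph["sample_id"] = cmap.sample_id
    for y in range(h):
        for x in range(w):
            G.add_node((x, y), cls=str(cmap.labels[y, x]))
    for dx, dy in _HALF_OFFSETS:
        for y in range(h):
            y2 = y + dy
            if not (0 <= y2 < h):
                continue
            for x in range(w):
                x2 = x + dx
                if 0 <= x2 < w:
                    G.add_edge((x, y), (x2, y2))
    return G


def nx_from_frame(df: pd.DataFrame) -> nx.Graph:
    """Neighborhood graph from a long-format (x, y, label) frame.

    Accepts partial lattices (e.g. malignant spots only); edges still follow
    the Chebyshev-distance-<=2 rule between the positions present.
    """
    if df.duplicated(subset=["x", "y"]).any():
        raise DuplicatePositionError("duplicate (x, y) positions")
    if len(df) < 2:
        raise ValueError("need at least 2 patches to build a graph")
    G = nx.Graph()
    pos_set = set()
    for _, row in df.iterrows():
        p = (int(row["x"]), int(row["y"]))
        G.add_node(p, cls=str(row["label"]))
        pos_set.add(p)
    for x, y in pos_set:
        for dx, dy in _HALF_OFFSETS:
            q = (x + dx, y + dy)
            if q in pos_set:
                G.add_edge((x, y), q)
    return G


def clustering_coefficient(G: nx.Graph, class_m: str) -> float:
    """Cluster(m): fraction of class-m-incident edges internal to class m.

    Raises :class:`UndefinedStatistic` when the class is absent from the graph
    or has no incident edges.
    """
    cls = nx.get_node_attributes(G, "cls")
    if class_m not in cls.values():
        raise UndefinedStatistic(f"class {class_m!r} absent from graph")
    i_mm = 0
    i_mk = 0
    for u, v in G.edges:
        um, vm = cls[u] == class_m, cls[v] == class_m
        if um and vm:
            i_mm += 1
        elif um or vm:
            i_mk += 1
    if i_mm + i_mk == 0:
        raise UndefinedStatistic(f"class {class_m!r} has no incident edges")
    return i_mm / (i_mm + i_mk)


def interaction_matrix(
    G: nx.Graph, immune_classes: frozenset[str] | set[str] = frozenset()
) -> pd.DataFrame:
    """Symmetric class-by-class matrix of edge-count fractions.

    Entry (M, K) is the number of M-K edges divided by the total number of
    edges between malignant classes; classes in ``immune_classes`` are excluded
    from both the matrix and the denominator. Fractions over unordered class
    pairs (diagonal plus upper triangle) sum to 1.
    """
    cls = nx.get_node_attributes(G, "cls")
    malignant = sorted({c for c in cls.values() if c not in immune_classes})
    idx = {c: i for i, c in enumerate(malignant)}
    counts = np.zeros((len(malignant), len(malignant)))
    total = 0
    for u, v in G.edges:
        cu, cv = cls[u], cls[v]
        if cu in idx and cv in idx:
            i, j = idx[cu], idx[cv]
            counts[i, j] += 1
            if i != j:
                counts[j, i] += 1
            total += 1
    if total == 0:
        raise UndefinedStatistic("no edges between malignant classes")
    return pd.DataFrame(counts / total, index=malignant, columns=malignant)


def _node_sort_key(members):
    return min(members)


def abstractive_network(
    G: nx.Graph,
    region: set | None = None,
    threshold: float = 0.7,
) -> tuple[nx.Graph, dict]:
    """Collapse subtype-dominated neighborhoods into super-nodes.

    Nodes are scanned in deterministic (sorted position) order; when the
    fraction of a node's neighbors sharing its class exceeds ``threshold``
    (for ``threshold >= 1`` the neighborhood must be entirely same-class), the
    node and its same-class neighbors are merged into one super-node that
    inherits the union of their edges. Passes repeat until no merge happens,
    so the result is idempotent. Only same-class neighbors are absorbed: every
    super-node is class-pure.

    Returns the aggregated graph and a mapping node-id -> list of original
    member positions.
    """
    if region is not None and len(region) == 0:
        raise ValueError("empty region")
    H = nx.Graph()
    for n, data in G.nodes(data=True):
        H.add_node(n, cls=data["cls"], members=list(data.get("members", [n])))
    H.add_edges_from(G.edges)
    in_region = (lambda mem: True) if region is None else (
        lambda mem: any(m in region for m in mem)
    )
    counter = 0
    changed = True
    while changed:
        changed = False
        order = sorted(H.nodes, key=lambda n: _node_sort_key(H.nodes[n]["members"]))
        for n in order:
            if n not in H:
                continue
            if not in_region(H.nodes[n]["members"]):
                continue
            nbrs = list(H.neighbors(n))
            if not nbrs:
                continue
            c = H.nodes[n]["cls"]
            same = [v for v in nbrs if H.nodes[v]["cls"] == c]
            frac = len(same) / len(nbrs)
            merge = frac >= 1.0 if threshold >= 1.0 else frac > threshold
            if not merge or not same:
                continue
            group = [n, *same]
            members = [m for g in group for m in H.nodes[g]["members"]]
            new_edges = {
                v for g in group for v in H.neighbors(g) if v not in group
            }
            H.remove_nodes_from(group)
            node_id = ("super", counter)
            counter += 1
            H.add_node(node_id, cls=c, members=sorted(members))
            H.add_edges_from((node_id, v) for v in new_edges)
            changed = True
    mapping = {n: H.nodes[n]["members"] for n in H.nodes}
    return H, mapping


def slide_features(
    G: nx.Graph, immune_classes: frozenset[str] | set[str] = frozenset()
) -> pd.Series:
    """Per-slide feature vector: class proportions, clustering coefficients and
    unordered-pair interaction fractions.

    Undefined statistics are reported as NaN; the reasons are collected in the
    series' ``attrs['missing']``.
    """
    cls = nx.get_node_attributes(G, "cls")
    labels = pd.Series(list(cls.values()))
    classes = sorted(labels.unique())
    feats: dict[str, float] = {}
    missing: dict[str, str] = {}
    props = labels.value_counts(normalize=True)
    for c in classes:
        feats[f"prop_{c}"] = float(props.get(c, 0.0))
    for c in classes:
        try:
            feats[f"cc_{c}"] = clustering_coefficient(G, c)
        except UndefinedStatistic as e:
            feats[f"cc_{c}"] = np.nan
            missing[f"cc_{c}"] = str(e)
    try:
        imat = interaction_matrix(G, immune_classes)
        mal = list(imat.index)
        for i, a in enumerate(mal):
            for b in mal[i:]:
                feats[f"int_{a}|{b}"] = float(imat.loc[a, b])
    except UndefinedStatistic as e:
        missing["interaction"] = str(e)
    out = pd.Series(feats)
    out.attrs["missing"] = missing
    if missing:
        log.info("slide_features: %d undefined statistics: %s", len(missing), missing)
    return out


# ---------------------------------------------------------------------------
# Fast lattice path (used inside simulation loops; equivalent to the graph
# route above, which tests assert).


def lattice_edge_counts(labels: np.ndarray) -> dict[tuple[str, str], int]:
    """Class-pair edge counts of the Chebyshev<=2 graph, via array shifts."""
    labels = np.asarray(labels, dtype=object)
    h, w = labels.shape
    classes = sorted({str(v) for v in labels.ravel()})
    code = {c: i for i, c in enumerate(classes)}
    L = np.vectorize(code.__getitem__, otypes=[int])(labels.astype(str))
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for dx, dy in _HALF_OFFSETS:
        ys = slice(max(0, -dy), h - max(0, dy))
        ys2 = slice(max(0, dy), h - max(0, -dy))
        xs = slice(0, w - dx)
        xs2 = slice(dx, w)
        a = L[ys, xs].ravel()
        b = L[ys2, xs2].ravel()
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        np.add.at(counts, (lo, hi), 1)
    return {
        (classes[i], classes[j]): int(counts[i, j])
        for i in range(k)
        for j in range(i, k)
        if counts[i, j] > 0
    }


def lattice_features(
    labels: np.ndarray, immune_classes: frozenset[str] | set[str] = frozenset()
) -> pd.Series:
    """Fast equivalent of :func:`slide_features` on a full lattice."""
    labels = np.asarray(labels, dtype=object)
    counts = lattice_edge_counts(labels)
    flat = pd.Series([str(v) for v in labels.ravel()])
    classes = sorted(flat.unique())
    feats: dict[str, float] = {}
    props = flat.value_counts(normalize=True)
    for c in classes:
        feats[f"prop_{c}"] = float(props.get(c, 0.0))
    for c in classes:
        i_mm = counts.get((c, c), 0)
        i_mk = sum(
            v for (a, b), v in counts.items() if (a == c) != (b == c)
        )
        feats[f"cc_{c}"] = i_mm / (i_mm + i_mk) if (i_mm + i_mk) else np.nan
    mal = [c for c in classes if c not in immune_classes]
    total = sum(
        v for (a, b), v in counts.items() if a in mal and b in mal
    )
    if total > 0:
        for i, a in enumerate(mal):
            for b in mal[i:]:
                feats[f"int_{a}|{b}"] = counts.get((min(a, b), max(a, b)), 0) / total
    return pd.Series(feats)


def export_graphml(G: nx.Graph, path) -> None:
    """Write the graph as GraphML (positions stringified for portability)."""
    H = nx.Graph()
    for n, d in G.nodes(data=True):
        H.add_node(str(n), cls=d.get("cls", ""))
    H.add_edges_from((str(u), str(v)) for u, v in G.edges)
    nx.write_graphml(H, path)


def export_edge_list(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(map(lambda e: tuple(sorted(map(str, e))), G.edges)):
            fh.write(f"{u}\t{v}\n")
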