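"""Cell-graph construction from nucleus detections.

Each selected interface patch is modeled as a graph: nodes are nucleus
centroids carrying a 5-dim morphology descriptor (area, eccentricity,
solidity, mean intensity, perimeter); edges connect spatially neighboring
nuclei (k-nearest within a distance gate, symmetrized by union) and are
weighted by the histomorphological similarity of the two nuclei, so the
graph reflects both spatial and functional cell relationships.

Nucleus detections arrive as a HoVer-Net-style JSON export (one instance
per nucleus with centroid, contour, and optional type code); morphology is
computed from the contour polygon when present, otherwise read from the
file's feature block — the synthetic-fixture writer uses the latter form,
making fixtures and real exports interchangeable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree, ConvexHull, QhullError

FEATURE_NAMES = ("area", "eccentricity", "solidity", "mean_intensity",
                 "perimeter")
N_FEATURES = len(FEATURE_NAMES)

__all__ = [
    "Nucleus",
    "CellGraph",
    "FeatureStats",
    "read_nucleus_export",
    "contour_morphology",
    "build_cell_graph",
    "fit_feature_stats",
    "standardize_features",
    "write_cell_graph",
    "read_cell_graph",
    "to_networkx",
]


@dataclass
class Nucleus:
    centroid: Tuple[float, float]  # (x, y) in patch pixels
    features: np.ndarray           # 5-dim morphology descriptor
    type_code: Optional[int] = None


@dataclass
class CellGraph:
    """Undirected weighted cell-graph of one patch.

    ``edges`` is an (m, 2) int array of node-index pairs (i < j);
    ``weights`` holds the matching similarity weights in (0, 1].
    Metadata carries the patch's slide, grid coordinates, hop distance d
    from the tumor-parenchyma interface, and (for training) the case label.
    """

    centroids: np.ndarray           # (n, 2)
    features: np.ndarray            # (n, 5)
    edges: np.ndarray               # (m, 2) int, i < j
    weights: np.ndarray             # (m,)
    slide_id: str = ""
    coords: Tuple[int, int] = (0, 0)
    hop_distance: int = 0
    label: Optional[str] = None
    standardized: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.centroids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _polygon_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_perimeter(contour: np.ndarray) -> float:
    diffs = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def _polygon_eccentricity(contour: np.ndarray) -> float:
    # eccentricity of the ellipse sharing the vertices' second central moments
    centered = contour - contour.mean(axis=0)
    cov = np.cov(centered.T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    if evals[1] <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - evals[0] / evals[1])))


def contour_morphology(contour: Sequence[Sequence[float]]) -> np.ndarray:
    """Morphology descriptor from a contour polygon.

    Shoelace area, ellipse-fit eccentricity, convex-hull solidity, and
    polygon perimeter; mean intensity is not derivable from geometry and
    defaults to 0.5 (overridden by a per-instance value when the export
    provides one).
    """
    contour = np.asarray(contour, dtype=float)
    area = _polygon_area(contour)
    try:
        hull_area = ConvexHull(contour).volume  # 2-D: volume == area
        solidity = min(1.0, area / hull_area) if hull_area > 0 else 1.0
    except QhullError:
        solidity = 1.0
    return np.array([
        area,
        _polygon_eccentricity(contour),
        solidity,
        0.5,
        _polygon_perimeter(contour),
    ])


def read_nucleus_export(path, patch_size: Optional[float] = None
                        ) -> List[Nucleus]:
    """Read a nucleus-detector JSON export into Nucleus records.

    Accepts the HoVer-Net dialect ({"nuc": {id: {...}}}) and a bare
    {id: {...}} mapping. Per instance: ``centroid`` is required; morphology
    comes from ``contour`` when present, otherwise from a ``features``
    block. ``mean_intensity``/``intensity`` keys override the contour
    default. Instances whose centroid falls outside ``patch_size`` bounds
    are dropped with a warning.
    """
    with open(path) as fh:
        data = json.load(fh)
    instances = data.get("nuc", data)
    if not isinstance(instances, dict):
        raise ValueError(f"{path}: malformed export, expected instance mapping")
    nuclei: List[Nucleus] = []
    for key, inst in instances.items():
        if not isinstance(inst, dict) or "centroid" not in inst:
            raise ValueError(f"{path}: instance {key!r} lacks a centroid")
        cen = tuple(float(v) for v in inst["centroid"])
        if len(cen) != 2 or not all(np.isfinite(cen)):
            raise ValueError(f"{path}: instance {key!r} has a bad centroid")
        if patch_size is not None and not (
                0 <= cen[0] <= patch_size and 0 <= cen[1] <= patch_size):
            warnings.warn(f"instance {key!r}: centroid outside patch bounds, "
                          "dropped", stacklevel=2)
            continue
        if "contour" in inst and inst["contour"]:
            feats = contour_morphology(inst["contour"])
            for k in ("mean_intensity", "intensity"):
                if k in inst:
                    feats[3] = float(inst[k])
                    break
        elif "features" in inst:
            fb = inst["features"]
            feats = np.array([float(fb[name]) for name in FEATURE_NAMES])
        else:
            raise ValueError(
                f"{path}: instance {key!r} has neither contour nor features")
        if not np.all(np.isfinite(feats)):
            raise ValueError(f"{path}: instance {key!r} has non-finite features")
        nuclei.append(Nucleus(centroid=cen, features=feats,
                              type_code=inst.get("type")))
    return nuclei


def _cosine_similarity_rows(Z: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Cosine similarity for the given index pairs of row vectors.

    Zero vectors arise when all nuclei share a feature value after
    within-patch standardization; two zero vectors are maximally similar
    (identical nuclei), a zero vs a nonzero vector scores 0.
    """
    a, b = Z[pairs[:, 0]], Z[pairs[:, 1]]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    sim = np.zeros(len(pairs))
    both = (na > 0) & (nb > 0)
    sim[both] = np.sum(a[both] * b[both], axis=1) / (na[both] * nb[both])
    sim[(na == 0) & (nb == 0)] = 1.0
    return np.clip(sim, -1.0, 1.0)


def build_cell_graph(
    nuclei: Sequence[Nucleus],
    k: int = 5,
    max_edge_dist: float = 50.0,
    similarity_threshold: float = 0.0,
    **metadata,
) -> CellGraph:
    """Build the cell-graph of one patch.

    Candidate edges are each nucleus's ``k`` nearest spatial neighbors
    within ``max_edge_dist``, symmetrized by union. Each candidate is
    weighted by the cosine similarity of the two nuclei's within-patch
    standardized morphology vectors mapped to (0, 1] via (cos+1)/2;
    candidates at or below ``similarity_threshold`` (and zero-weight
    candidates) are dropped. Isolated nodes are allowed.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not nuclei:
        raise ValueError("need at least one nucleus")
    centroids = np.array([n.centroid for n in nuclei], dtype=float)
    features = np.array([n.features for n in nuclei], dtype=float)
    n = len(nuclei)

    pairs = np.empty((0, 2), dtype=int)
    if n > 1:
        tree = cKDTree(centroids)
        kq = min(k + 1, n)
        dists, idx = tree.query(centroids, k=kq)
        cand = set()
        for i in range(n):
            for dist, j in zip(np.atleast_1d(dists[i]), np.atleast_1d(idx[i])):
                j = int(j)
                if j == i or dist > max_edge_dist:
                    continue
                cand.add((min(i, j), max(i, j)))
        if cand:
            pairs = np.array(sorted(cand), dtype=int)

    if len(pairs):
        mu = features.mean(axis=0)
        sd = features.std(axis=0)
        Z = np.where(sd > 0, (features - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        sim = _cosine_similarity_rows(Z, pairs)
        w = (sim + 1.0) / 2.0
        keep = (w > 0) & (w > similarity_threshold)
        pairs, w = pairs[keep], w[keep]
    else:
        w = np.empty(0)

    return CellGraph(centroids=centroids, features=features,
                     edges=pairs.reshape(-1, 2), weights=w, **metadata)


@dataclass
class FeatureStats:
    """Per-dimension feature mean/std fit on the training split only."""

    mean: np.ndarray
    std: np.ndarray

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureStats":
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]))


def fit_feature_stats(graphs: Sequence[CellGraph]) -> FeatureStats:
    """Pool node features of the training graphs and fit z-score statistics."""
    if not graphs:
        raise ValueError("no graphs")
    X = np.vstack([g.features for g in graphs])
    return FeatureStats(mean=X.mean(axis=0), std=X.std(axis=0))


def standardize_features(graphs: Sequence[CellGraph],
                         stats: Optional[FeatureStats]) -> List[CellGraph]:
    """Return copies of ``graphs`` with z-scored node features.

    Zero-variance dimensions pass through at 0. The statistics must come
    from the training split (stored alongside the model for inference);
    passing ``None`` is an error.
    """
    if stats is None:
        raise ValueError("no stored feature statistics; fit on the training "
                         "split first")
    sd = np.where(stats.std > 0, stats.std, 1.0)
    out = []
    for g in graphs:
        z = (g.features - stats.mean) / sd
        z[:, stats.std == 0] = 0.0
        out.append(CellGraph(
            centroids=g.centroids.copy(), features=z, edges=g.edges.copy(),
            weights=g.weights.copy(), slide_id=g.slide_id, coords=g.coords,
            hop_distance=g.hop_distance, label=g.label, standardized=True))
    return out


# ---------------------------------------------------------------------------
# Serialization: documented JSON schema, optional GraphML via networkx


def write_cell_graph(graph: CellGraph, path) -> None:
    doc = {
        "schema": "cell-graph/1",
        "slide_id": graph.slide_id,
        "coords": list(graph.coords),
        "hop_distance": graph.hop_distance,
        "label": graph.label,
        "standardized": graph.standardized,
        "feature_names": list(FEATURE_NAMES),
        "centroids": graph.centroids.tolist(),
        "features": graph.features.tolist(),
        "edges": graph.edges.tolist(),
        "weights": graph.weights.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_cell_graph(path) -> CellGraph:
    with open(path) as fh:
        doc = json.load(fh)
    return CellGraph(
        centroids=np.asarray(doc["centroids"], dtype=float).reshape(-1, 2),
        features=np.asarray(doc["features"], dtype=float).reshape(-1, N_FEATURES),
        edges=np.asarray(doc["edges"], dtype=int).reshape(-1, 2),
        weights=np.asarray(doc["weights"], dtype=float),
        slide_id=doc.get("slide_id", ""),
        coords=tuple(doc.get("coords", (0, 0))),
        hop_distance=int(doc.get("hop_distance", 0)),
        label=doc.get("label"),
        standardized=bool(doc.get("standardized", False)),
    )


def to_networkx(graph: CellGraph):
    """Export to a networkx Graph (e.g., for GraphML output)."""
    import networkx as nx

    g = nx.Graph()
    for i, (cen, feat) in enumerate(zip(graph.centroids, graph.features)):
        g.add_node(i, x=float(cen[0]), y=float(cen[1]),
                   **{name: float(v) for name, v in zip(FEATURE_NAMES, feat)})
    for (i, j), w in zip(graph.edges, graph.weights):
        g.add_edge(int(i), int(j), weight=float(w))
    return g
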