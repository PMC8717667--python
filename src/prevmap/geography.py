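"""Areal adjacency structures, intrinsic GMRF structure matrices, and Moran's I.

This module owns the lattice bookkeeping used everywhere else: a validated
adjacency graph over opaque region labels, the precision ("structure")
matrices of the intrinsic Gaussian Markov random fields placed on space
(ICAR), time (first-order random walk) and their Kronecker interaction, and
a permutation-based Moran's I test for spatial autocorrelation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AdjacencyGraph",
    "StructureMatrix",
    "MoranResult",
    "IslandRegionError",
    "build_adjacency_graph",
    "adjacency_from_edges",
    "adjacency_from_polygons",
    "read_edge_list",
    "write_edge_list",
    "icar_structure_matrix",
    "rw1_structure_matrix",
    "interaction_structure_matrix",
    "morans_i_test",
    "sample_intrinsic_gmrf",
]


class IslandRegionError(ValueError):
    """Raised when an operation requires every region to have a neighbor."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric areal adjacency over an ordered set of region labels.

    Parameters
    ----------
    region_ids
        Ordered, unique region labels. All downstream vectors/matrices use
        this ordering.
    edges
        Unordered pairs of region labels sharing a border. Stored as sorted
        tuples; self-edges are rejected.
    coords
        Optional map region -> (row, col) plotting/gradient coordinates
        (populated by the synthetic lattice generator).
    """

    region_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    coords: Mapping[str, tuple[float, float]] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if len(set(self.region_ids)) != len(self.region_ids):
            dupes = pd.Series(list(self.region_ids))
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate region ids: {dupes}")
        known = set(self.region_ids)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge on region {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown region")
        if self.islands:
            warnings.warn(
                f"island regions with no neighbors: {sorted(self.islands)}",
                stacklevel=2,
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.region_ids)}

    def adjacency_matrix(self) -> csr_matrix:
        """Binary symmetric a_ij as a sparse CSR matrix."""
        idx = self.index
        rows, cols = [], []
        for a, b in self.edges:
            i, j = idx[a], idx[b]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return csr_matrix(
            (data, (rows, cols)), shape=(self.n_regions, self.n_regions)
        )

    def neighbor_counts(self) -> np.ndarray:
        """N_i = number of neighbors per region, in region_ids order."""
        counts = np.zeros(self.n_regions, dtype=int)
        idx = self.index
        for a, b in self.edges:
            counts[idx[a]] += 1
            counts[idx[b]] += 1
        return counts

    @property
    def islands(self) -> frozenset[str]:
        counts = self.neighbor_counts()
        return frozenset(
            r for r, c in zip(self.region_ids, counts) if c == 0
        )

    def n_components(self) -> int:
        ncomp, _ = connected_components(self.adjacency_matrix(), directed=False)
        return int(ncomp)

    def neighbors_of(self, region: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == region:
                out.append(b)
            elif b == region:
                out.append(a)
        return sorted(out)


@dataclass(frozen=True)
class StructureMatrix:
    """Symmetric PSD structure (precision-scaling) matrix with labels."""

    labels: tuple[str, ...]
    entries: np.ndarray
    rank_deficiency: int

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("structure matrix must be square")
        if m.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix dimension")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("structure matrix must be symmetric")
        object.__setattr__(self, "entries", m)

    @property
    def dim(self) -> int:
        return self.entries.shape[0]

    @property
    def rank(self) -> int:
        return self.dim - self.rank_deficiency

    def to_coo_text(self, path: str | Path) -> None:
        """Write nonzero entries as '<i> <j> <value>' coordinate text."""
        ii, jj = np.nonzero(self.entries)
        with open(path, "w") as fh:
            fh.write("i\tj\tvalue\n")
            for i, j in zip(ii, jj):
                fh.write(f"{i}\t{j}\t{self.entries[i, j]:.17g}\n")


@dataclass(frozen=True)
class MoranResult:
    statistic: float
    expected_null: float
    p_value: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# Graph construction


def adjacency_from_edges(
    edges: Iterable[tuple[str, str]],
    region_ids: Sequence[str] | None = None,
) -> AdjacencyGraph:
    """Build a graph from unordered label pairs.

    ``region_ids`` fixes the ordering (and may include regions with no
    edges, which are flagged as islands); when omitted the ordering is the
    sorted set of labels appearing in the edge list.
    """
    norm = set()
    seen: list[str] = []
    for a, b in edges:
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-edge on region {a!r}")
        norm.add((min(a, b), max(a, b)))
        seen += [a, b]
    if region_ids is None:
        region_ids = sorted(set(seen))
    return AdjacencyGraph(tuple(str(r) for r in region_ids), frozenset(norm))


def adjacency_from_polygons(
    geometries: Mapping[str, object],
) -> AdjacencyGraph:
    """Queen-contiguity adjacency: neighbors share >= 1 boundary point.

    ``geometries`` maps region id -> shapely geometry.
    """
    from shapely import STRtree
    from shapely.validation import explain_validity

    ids = list(geometries.keys())
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids in polygon collection")
    geoms = []
    for rid in ids:
        g = geometries[rid]
        if not g.is_valid:
            raise ValueError(
                f"invalid geometry for region {rid!r}: {explain_validity(g)}"
            )
        geoms.append(g)
    tree = STRtree(geoms)
    edges: set[tuple[str, str]] = set()
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            edges.add((min(ids[i], ids[j]), max(ids[i], ids[j])))
    return AdjacencyGraph(tuple(ids), frozenset(edges))


def build_adjacency_graph(source) -> AdjacencyGraph:
    """Dispatch on source: iterable of pairs, mapping of geometries, or a
    GeoJSON FeatureCollection dict (region id read from each feature's
    properties; see :func:`read_geojson_regions`)."""
    if isinstance(source, Mapping) and source.get("type") == "FeatureCollection":
        return adjacency_from_polygons(read_geojson_regions(source))
    if isinstance(source, Mapping):
        return adjacency_from_polygons(source)
    source = list(source)
    if not source:
        raise ValueError("empty adjacency source")
    return adjacency_from_edges(source)


def read_geojson_regions(
    collection: Mapping | str | Path, id_property: str = "region_id"
) -> dict[str, object]:
    """Parse a GeoJSON FeatureCollection into {region_id: shapely geometry}."""
    from shapely.geometry import shape

    if not isinstance(collection, Mapping):
        with open(collection) as fh:
            collection = json.load(fh)
    out: dict[str, object] = {}
    for feat in collection["features"]:
        rid = str(feat["properties"][id_property])
        if rid in out:
            raise ValueError(f"duplicate region id {rid!r} in GeoJSON")
        out[rid] = shape(feat["geometry"])
    return out


def read_edge_list(path: str | Path, delimiter: str = "\t") -> AdjacencyGraph:
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs two columns (region_id_1, region_id_2)")
    pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return adjacency_from_edges(pairs)


def write_edge_list(
    graph: AdjacencyGraph, path: str | Path, delimiter: str = "\t"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"region_id_1{delimiter}region_id_2\n")
        for a, b in sorted(graph.edges):
            fh.write(f"{a}{delimiter}{b}\n")


# ---------------------------------------------------------------------------
# Structure matrices


def icar_structure_matrix(graph: AdjacencyGraph) -> StructureMatrix:
    """ICAR precision structure K = D - A (neighbor counts minus adjacency).

    Rows sum to zero; the rank deficiency equals the number of connected
    components of the graph. Islands are rejected because the conditional
    distribution is undefined for a region with no neighbors.
    """
    if graph.islands:
        raise IslandRegionError(
            f"ICAR structure undefined for island regions {sorted(graph.islands)}"
        )
    A = graph.adjacency_matrix().toarray()
    K = np.diag(A.sum(axis=1)) - A
    return StructureMatrix(
        labels=graph.region_ids,
        entries=K,
        rank_deficiency=graph.n_components(),
    )


def rw1_structure_matrix(T: int, labels: Sequence[str] | None = None) -> StructureMatrix:
    """First-difference (random-walk-1) penalty matrix of dimension T."""
    if T < 2:
        raise ValueError(f"RW1 structure requires T >= 2, got {T}")
    K = np.zeros((T, T))
    idx = np.arange(T - 1)
    K[idx, idx] += 1.0
    K[idx + 1, idx + 1] += 1.0
    K[idx, idx + 1] -= 1.0
    K[idx + 1, idx] -= 1.0
    if labels is None:
        labels = tuple(str(t) for t in range(T))
    return StructureMatrix(tuple(labels), K, rank_deficiency=1)


def interaction_structure_matrix(
    K_space: StructureMatrix, K_time: StructureMatrix
) -> StructureMatrix:
    """Kronecker-product structure for a space-time interaction field.

    Ordering is region-major: label (i, t) sits at position i * T + t, so the
    matrix is ``K_space (x) K_time``.
    """
    K = np.kron(K_space.entries, K_time.entries)
    labels = tuple(
        f"{s}:{t}" for s in K_space.labels for t in K_time.labels
    )
    rank = K_space.rank * K_time.rank
    return StructureMatrix(labels, K, rank_deficiency=K.shape[0] - rank)


def sample_intrinsic_gmrf(
    structure: StructureMatrix,
    sigma2: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw constrained samples from the intrinsic GMRF with precision
    ``structure / sigma2``.

    Sampling is done in the eigenbasis of the structure matrix: coordinates
    along null eigenvectors are fixed at zero, giving the proper Gaussian on
    the constrained subspace with covariance ``sigma2 * K^+`` (Moore-Penrose
    pseudo-inverse). Returns an array of shape (size, dim).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    if sigma2 == 0:
        return np.zeros((size, structure.dim))
    evals, evecs = np.linalg.eigh(structure.entries)
    tol = max(structure.dim, 10) * np.finfo(float).eps * max(evals.max(), 1.0)
    pos = evals > tol
    z = rng.standard_normal((size, int(pos.sum())))
    coords = z * np.sqrt(sigma2 / evals[pos])
    return coords @ evecs[:, pos].T


# ---------------------------------------------------------------------------
# Moran's I


def _morans_i_statistic(z: np.ndarray, A: csr_matrix, w_sum: float) -> float:
    n = z.size
    return float(n / w_sum * (z @ (A @ z)) / (z @ z))


def morans_i_test(
    values: Sequence[float],
    graph: AdjacencyGraph,
    n_permutations: int = 9999,
    seed: int = 0,
) -> MoranResult:
    """Two-sided permutation test of Moran's I with binary contiguity weights.

    The p-value is ``(1 + #{|I_perm - E[I]| >= |I_obs - E[I]|}) /
    (n_permutations + 1)`` with the analytic null mean ``E[I] = -1/(N-1)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size != graph.n_regions:
        raise ValueError(
            f"got {x.size} values for {graph.n_regions} regions"
        )
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for constant values (zero variance)")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    A = graph.adjacency_matrix()
    w_sum = float(A.sum())
    if w_sum == 0:
        raise ValueError("graph has no edges")
    z = x - x.mean()
    i_obs = _morans_i_statistic(z, A, w_sum)
    e_null = -1.0 / (x.size - 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        i_perm = _morans_i_statistic(zp, A, w_sum)
        if abs(i_perm - e_null) >= abs(i_obs - e_null):
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return MoranResult(
        statistic=i_obs,
        expected_null=e_null,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )
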