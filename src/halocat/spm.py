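"""Shortest-path-map (SPM) residue-communication analysis.

From a coordinate ensemble (MD frames or a statistical stand-in) the
analysis computes the dynamic cross-correlation matrix (DCCM) of residue
fluctuations and the inter-residue mean-distance matrix, connects spatially
proximal residue pairs (mean distance below a cutoff, 6 A by default) with
edges weighted by d_ij = -ln|C_ij|, and scores every edge by how many
all-pairs shortest paths traverse it.  Highly used, short edges trace the
correlated-motion pathways of the enzyme.

The log base only rescales all weights uniformly and cannot change which
path is shortest; natural log is used.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateResidueError, InvalidParameterError

__all__ = [
    "CoordinateEnsemble",
    "SPMGraph",
    "dccm",
    "mean_distance_matrix",
    "build_spm_graph",
    "shortest_path_map",
    "read_ensemble_table",
    "write_ensemble_table",
    "read_ensemble_pdb",
    "write_edge_csv",
]


@dataclass
class CoordinateEnsemble:
    """n_frames x n_residues x 3 coordinates (A) with one label per residue."""

    frames: np.ndarray
    residue_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InvalidParameterError("frames must have shape (n_frames, n_residues, 3)")
        if self.frames.shape[0] < 2:
            raise InvalidParameterError("need at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("coordinates must be finite")
        if not self.residue_labels:
            self.residue_labels = [str(i) for i in range(self.frames.shape[1])]
        if len(self.residue_labels) != self.frames.shape[1]:
            raise InvalidParameterError("one label per residue required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]


@dataclass
class SPMGraph:
    """Weighted residue graph with per-edge shortest-path usage scores.

    ``graph`` is an undirected networkx graph on residue indices with edge
    attributes ``weight`` (-ln|C|) and, after :func:`shortest_path_map`,
    ``usage`` (number of source-target pairs whose shortest path contains
    the edge).  ``map_edges`` holds the high-usage edges forming the map.
    """

    graph: nx.Graph
    residue_labels: list[str]
    map_edges: set[tuple[int, int]] = field(default_factory=set)

    def edges_table(self) -> pd.DataFrame:
        rows = []
        for i, j, attrs in self.graph.edges(data=True):
            a, b = (i, j) if i < j else (j, i)
            rows.append(
                {
                    "res_i": self.residue_labels[a],
                    "res_j": self.residue_labels[b],
                    "weight": attrs["weight"],
                    "usage": attrs.get("usage", 0),
                    "in_map": (a, b) in self.map_edges,
                }
            )
        return pd.DataFrame(rows).sort_values(["res_i", "res_j"]).reset_index(drop=True)

    def node_usage(self) -> pd.DataFrame:
        """Per-residue total usage, for coloring structures."""
        totals = dict.fromkeys(self.graph.nodes, 0)
        for i, j, attrs in self.graph.edges(data=True):
            u = attrs.get("usage", 0)
            totals[i] += u
            totals[j] += u
        return pd.DataFrame(
            {"residue": [self.residue_labels[i] for i in totals], "usage": list(totals.values())}
        )


def dccm(ensemble: CoordinateEnsemble) -> np.ndarray:
    """Dynamic cross-correlation matrix of residue displacement vectors.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>), displacements taken
    from each residue's mean position over the frames.  The diagonal is
    exactly 1; a residue with zero total fluctuation is reported by name.
    """
    disp = ensemble.frames - ensemble.frames.mean(axis=0, keepdims=True)
    # inner products summed over frames and xyz
    inner = np.einsum("fik,fjk->ij", disp, disp)
    var = np.diag(inner)
    zero = np.flatnonzero(var == 0.0)
    if zero.size:
        names = ", ".join(ensemble.residue_labels[i] for i in zero)
        raise DegenerateResidueError(f"zero positional fluctuation for residue(s): {names}")
    c = inner / np.sqrt(np.outer(var, var))
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def mean_distance_matrix(ensemble: CoordinateEnsemble) -> np.ndarray:
    """Frame-averaged Euclidean distance between residue reference points."""
    diff = ensemble.frames[:, :, None, :] - ensemble.frames[:, None, :, :]
    return np.linalg.norm(diff, axis=-1).mean(axis=0)


def build_spm_graph(
    m: np.ndarray,
    c: np.ndarray,
    residue_labels: list[str] | None = None,
    distance_cutoff: float = 6.0,
    min_abs_corr: float = 0.01,
) -> SPMGraph:
    """Thresholded correlation graph: edge iff mean distance < cutoff and
    |C_ij| >= min_abs_corr, weighted d_ij = -ln|C_ij| >= 0."""
    m = np.asarray(m, dtype=float)
    c = np.asarray(c, dtype=float)
    if m.shape != c.shape or m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidParameterError(
            f"distance and correlation matrices must be square and equal-shaped, "
            f"got {m.shape} vs {c.shape}"
        )
    n = m.shape[0]
    labels = residue_labels or [str(i) for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if m[i, j] >= distance_cutoff:
                continue
            ac = abs(c[i, j])
            if ac < min_abs_corr or ac == 0.0:
                continue  # weight would diverge; treat as disconnected
            g.add_edge(i, j, weight=float(-np.log(min(ac, 1.0))))
    return SPMGraph(graph=g, residue_labels=list(labels))


def _dijkstra_predecessors(
    g: nx.Graph, source: int, rel_tol: float = 1e-12
) -> tuple[dict[int, float], dict[int, int]]:
    """Single-source Dijkstra returning one deterministic predecessor per node.

    Among equal-length alternatives (within relative tolerance) the
    lowest-index predecessor wins, making path extraction reproducible.
    """
    dist: dict[int, float] = {source: 0.0}
    pred: dict[int, int] = {}
    done: set[int] = set()
    heap: list[tuple[float, int]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, attrs in g.adj[u].items():
            nd = d + attrs["weight"]
            cur = dist.get(v)
            if cur is None or nd < cur * (1.0 - rel_tol) - rel_tol:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif abs(nd - cur) <= rel_tol * max(1.0, abs(cur)) and u < pred.get(v, u + 1):
                pred[v] = u  # tie: prefer the lowest-index predecessor
    return dist, pred


def shortest_path_lengths(spm_graph: SPMGraph) -> dict[int, dict[int, float]]:
    """All-pairs shortest-path lengths (per connected component)."""
    return {s: _dijkstra_predecessors(spm_graph.graph, s)[0] for s in spm_graph.graph.nodes}


def shortest_path_map(spm_graph: SPMGraph, usage_quantile: float = 0.8) -> SPMGraph:
    """Score every edge by shortest-path usage and extract the map edges.

    For each unordered residue pair in the same component, the deterministic
    shortest path is traced and each of its edges credited once.  Map edges
    are those whose usage reaches the ``usage_quantile`` quantile of the
    positive usages.  Disconnected components are handled independently.
    """
    g = spm_graph.graph
    if g.number_of_edges() == 0:
        raise InvalidParameterError("graph has no edges; nothing to map")
    if not 0.0 <= usage_quantile <= 1.0:
        raise InvalidParameterError("usage_quantile must lie in [0, 1]")
    usage = dict.fromkeys(g.edges, 0)

    def ekey(a: int, b: int) -> tuple[int, int]:
        return (a, b) if (a, b) in usage else (b, a)

    nodes = sorted(g.nodes)
    for s in nodes:
        _, pred = _dijkstra_predecessors(g, s)
        for t in nodes:
            if t <= s or t not in pred:
                continue
            node = t
            while node != s:
                p = pred[node]
                usage[ekey(p, node)] += 1
                node = p
    nx.set_edge_attributes(g, {e: u for e, u in usage.items()}, "usage")
    positive = np.array([u for u in usage.values() if u > 0])
    map_edges: set[tuple[int, int]] = set()
    if positive.size:
        threshold = float(np.quantile(positive, usage_quantile))
        map_edges = {
            tuple(sorted(e)) for e, u in usage.items() if u > 0 and u >= threshold
        }
    return SPMGraph(graph=g, residue_labels=spm_graph.residue_labels, map_edges=map_edges)


def read_ensemble_table(path, n_residues: int | None = None) -> CoordinateEnsemble:
    """Read a whitespace-separated frames x (residues*3) numeric table."""
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] % 3 != 0:
        raise InvalidParameterError("ensemble table must have 3 columns per residue")
    nres = data.shape[1] // 3
    if n_residues is not None and nres != n_residues:
        raise InvalidParameterError(f"expected {n_residues} residues, found {nres}")
    return CoordinateEnsemble(frames=data.reshape(data.shape[0], nres, 3))


def write_ensemble_table(path, ensemble: CoordinateEnsemble) -> None:
    n_frames = ensemble.n_frames
    np.savetxt(path, ensemble.frames.reshape(n_frames, -1), fmt="%.6f")


def read_ensemble_pdb(path) -> CoordinateEnsemble:
    """Extract a C-alpha ensemble from a multi-model PDB file."""
    from Bio.PDB import PDBParser  # deferred: only needed for structure input

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ensemble", path)
    frames = []
    labels: list[str] = []
    for model in structure:
        coords = []
        model_labels = []
        for chain in model:
            for residue in chain:
                atom = residue["CA"] if "CA" in residue else None
                if atom is None:
                    atoms = list(residue.get_atoms())
                    coord = np.mean([a.coord for a in atoms], axis=0)
                else:
                    coord = atom.coord
                coords.append(coord)
                model_labels.append(f"{chain.id}:{residue.get_resname()}{residue.id[1]}")
        frames.append(coords)
        if not labels:
            labels = model_labels
    return CoordinateEnsemble(frames=np.array(frames, dtype=float), residue_labels=labels)


def write_edge_csv(path, spm_graph: SPMGraph) -> None:
    spm_graph.edges_table().to_csv(path, index=False)
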