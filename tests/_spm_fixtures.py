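"""Shared constructions for the residue-network tests.

``planted_chain_ensemble`` builds a two-row residue lattice (4 A spacing)
whose first row carries a strong common motion (pairwise correlation 0.9)
on top of a weak global background (0.09), so shortest paths between distant
residues funnel through the first-row chain.
"""

import numpy as np

from halocat.spm import CoordinateEnsemble
from halocat.synthetic_data import EnsembleSpec, simulate_ensemble

N_CHAIN = 6
CHAIN_EDGES = frozenset((i, i + 1) for i in range(N_CHAIN - 1))


def planted_chain_ensemble(seed: int, n_frames: int = 2000) -> CoordinateEnsemble:
    n = 2 * N_CHAIN
    mean = np.zeros((n, 3))
    for i in range(N_CHAIN):
        mean[i] = [4.0 * i, 0.0, 0.0]
        mean[N_CHAIN + i] = [4.0 * i, 4.0, 0.0]
    corr = np.full((n, n), 0.09)
    corr[:N_CHAIN, :N_CHAIN] = 0.9
    np.fill_diagonal(corr, 1.0)
    spec = EnsembleSpec(
        mean_coordinates=mean,
        correlation_targets=corr,
        fluctuation_scale=0.5,
        n_frames=n_frames,
        seed=seed,
    )
    return simulate_ensemble(spec)


def brute_force_shortest_lengths(graph) -> dict[tuple[int, int], float]:
    """All-pairs shortest-path lengths by exhaustive simple-path enumeration."""
    import itertools

    import networkx as nx

    lengths: dict[tuple[int, int], float] = {}
    nodes = sorted(graph.nodes)
    for s, t in itertools.combinations(nodes, 2):
        best = None
        for path in nx.all_simple_paths(graph, s, t):
            total = sum(graph[u][v]["weight"] for u, v in zip(path, path[1:]))
            if best is None or total < best:
                best = total
        if best is not None:
            lengths[(s, t)] = best
    return lengths
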