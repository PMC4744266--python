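"""Seeded on-disk fixture bundle: tiny deterministic instances used by the
test suite and for smoke-testing the command-line interface."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io
from ._rng import substream
from .datatypes import ComplexSet, MultiNetwork, Partition

__all__ = ["make_fixtures", "two_clique_network"]


def two_clique_network(clique_size: int = 3, T: int = 1) -> tuple[MultiNetwork, Partition]:
    """Two disjoint cliques replicated across ``T`` identical networks."""
    n = 2 * clique_size
    A = np.zeros((n, n))
    for base in (0, clique_size):
        for i in range(base, base + clique_size):
            for j in range(base, base + clique_size):
                if i != j:
                    A[i, j] = 1.0
    ids = [f"v{i:03d}" for i in range(n)]
    labels = np.array([0] * clique_size + [1] * clique_size)
    return MultiNetwork([A.copy() for _ in range(T)], ids), Partition(labels)


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture bundle; byte-stable for a fixed seed.

    Contents: two-clique edge lists (T=2), an N=4/K=2/T=2 instance small
    enough for exact enumeration, the size-8/overlap-4 complex pair, a
    4-point ranking example, and a small contingency table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    net, truth = two_clique_network(clique_size=3, T=2)
    paths["universe"] = out / "universe.txt"
    io.write_vertex_universe(paths["universe"], net.vertex_ids)
    for t in range(2):
        p = out / f"two_clique_{t}.tsv"
        io.write_edge_list(p, net.adjacency[t], net.vertex_ids)
        paths[f"two_clique_{t}"] = p
    paths["two_clique_truth"] = out / "two_clique_truth.tsv"
    io.write_partition(paths["two_clique_truth"], truth, net.vertex_ids)

    rng = substream(seed, "fixtures")
    n4 = 4
    ids4 = [f"u{i}" for i in range(n4)]
    adj = []
    for _ in range(2):
        A = np.zeros((n4, n4))
        iu, ju = np.triu_indices(n4, k=1)
        bits = rng.random(iu.size) < 0.5
        A[iu[bits], ju[bits]] = 1.0
        A += A.T
        adj.append(A)
    paths["n4_universe"] = out / "n4_universe.txt"
    io.write_vertex_universe(paths["n4_universe"], ids4)
    for t in range(2):
        p = out / f"n4_net_{t}.tsv"
        io.write_edge_list(p, adj[t], ids4)
        paths[f"n4_net_{t}"] = p

    omega_pair = ComplexSet(
        [frozenset(f"p{i}" for i in range(8))], name="reference"
    )
    omega_pred = ComplexSet(
        [frozenset(f"p{i}" for i in range(4, 12))], name="predicted"
    )
    paths["omega_reference"] = out / "omega_reference.tsv"
    paths["omega_predicted"] = out / "omega_predicted.tsv"
    io.write_complexes(paths["omega_reference"], omega_pair)
    io.write_complexes(paths["omega_predicted"], omega_pred)

    auc_example = {
        "labels": [0, 0, 1, 1],
        "scores": [0.1, 0.4, 0.35, 0.8],
    }
    paths["auc_example"] = out / "auc_example.json"
    paths["auc_example"].write_text(json.dumps(auc_example, indent=1) + "\n")

    table = rng.integers(0, 5, size=(3, 4))
    paths["contingency"] = out / "contingency.tsv"
    io.write_matrix(paths["contingency"], table.astype(float))
    return paths
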