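"""Text I/O: edge lists, vertex universes, partitions, complex sets, matrices.

All formats are plain whitespace/tab-separated text.  Module labels are
1-based on disk and 0-based in memory; conversion happens here only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datatypes import ComplexSet, MultiNetwork, Partition

__all__ = [
    "read_vertex_universe",
    "write_vertex_universe",
    "read_edge_list",
    "write_edge_list",
    "load_multinetwork",
    "read_partition",
    "write_partition",
    "read_complexes",
    "write_complexes",
    "write_matrix",
]


def read_vertex_universe(path: str | Path) -> list[str]:
    """One vertex id per line; fixes N and the vertex ordering."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate vertex ids")
    if not ids:
        raise ValueError(f"{path}: empty vertex universe")
    return ids


def write_vertex_universe(path: str | Path, vertex_ids: list[str]) -> None:
    Path(path).write_text("".join(f"{v}\n" for v in vertex_ids))


def read_edge_list(path: str | Path, vertex_ids: list[str]) -> np.ndarray:
    """Read an undirected edge list into a symmetric binary adjacency matrix.

    Each non-empty line holds two whitespace-separated vertex ids.  Self
    edges, duplicate edges (either orientation) and ids absent from
    ``vertex_ids`` are rejected.  Vertices without edges stay isolated.
    """
    index = {v: i for i, v in enumerate(vertex_ids)}
    N = len(vertex_ids)
    A = np.zeros((N, N))
    seen: set[tuple[int, int]] = set()
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        u, v = parts
        if u == v:
            raise ValueError(f"{path}:{lineno}: self edge {u!r}")
        try:
            i, j = index[u], index[v]
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: unknown vertex {exc.args[0]!r}") from None
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"{path}:{lineno}: duplicate edge {u!r}-{v!r}")
        seen.add(key)
        A[i, j] = A[j, i] = 1.0
    return A


def write_edge_list(path: str | Path, A: np.ndarray, vertex_ids: list[str]) -> None:
    iu, ju = np.nonzero(np.triu(A, k=1))
    with open(path, "w") as fh:
        for i, j in zip(iu, ju):
            fh.write(f"{vertex_ids[i]}\t{vertex_ids[j]}\n")


def load_multinetwork(
    edge_paths: list[str | Path], universe_path: str | Path
) -> MultiNetwork:
    """Read one edge-list file per network against a shared vertex universe."""
    ids = read_vertex_universe(universe_path)
    adjacency = [read_edge_list(p, ids) for p in edge_paths]
    return MultiNetwork(adjacency, ids)


def read_partition(path: str | Path, vertex_ids: list[str]) -> Partition:
    """Two tab-separated columns: vertex_id, 1-based module label."""
    index = {v: i for i, v in enumerate(vertex_ids)}
    labels = np.full(len(vertex_ids), -1, dtype=np.int64)
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        v, lab = parts
        if v not in index:
            raise ValueError(f"{path}:{lineno}: unknown vertex {v!r}")
        lab_i = int(lab)
        if lab_i < 1:
            raise ValueError(f"{path}:{lineno}: labels are 1-based, got {lab_i}")
        labels[index[v]] = lab_i - 1
    if (labels < 0).any():
        missing = [v for v, i in index.items() if labels[i] < 0]
        raise ValueError(f"{path}: no label for vertices {missing[:5]}")
    return Partition(labels)


def write_partition(path: str | Path, p: Partition, vertex_ids: list[str]) -> None:
    with open(path, "w") as fh:
        for v, lab in zip(vertex_ids, p.labels):
            fh.write(f"{v}\t{lab + 1}\n")


def read_complexes(path: str | Path, name: str = "") -> ComplexSet:
    """One complex per line, tab-separated vertex ids."""
    complexes = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        members = ln.split("\t") if "\t" in ln else ln.split()
        complexes.append(frozenset(members))
    return ComplexSet(complexes, name=name or Path(path).stem)


def write_complexes(path: str | Path, cs: ComplexSet) -> None:
    with open(path, "w") as fh:
        for c in cs.complexes:
            fh.write("\t".join(sorted(c)) + "\n")


def write_matrix(path: str | Path, M: np.ndarray, row_ids: list[str] | None = None) -> None:
    """Tab-separated matrix, optionally with a leading row-id column."""
    with open(path, "w") as fh:
        for i, row in enumerate(np.atleast_2d(M)):
            cells = "\t".join(f"{x:.10g}" for x in row)
            if row_ids is not None:
                fh.write(f"{row_ids[i]}\t{cells}\n")
            else:
                fh.write(cells + "\n")
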