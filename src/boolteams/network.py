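"""Signed regulatory network container and topo-format IO.

A regulatory network is a signed directed graph: nodes are transcription
factors or microRNAs, edges are activations (+1) or inhibitions (-1).
Networks are stored as an N x N integer adjacency matrix with entry
``adjacency[i, j]`` describing the edge FROM node ``i`` TO node ``j``.

The on-disk format is the whitespace-delimited "topo" edge list used by
published gene-circuit collections: a header line ``Source Target Type``
followed by one edge per row, with Type 1 = activation, 2 = inhibition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RegulatoryNetwork",
    "TopoFormatError",
    "read_topo",
    "write_topo",
    "classify_nodes",
]

TOPO_HEADER = ("Source", "Target", "Type")


class TopoFormatError(ValueError):
    """Raised when a topo file violates the format contract."""


@dataclass
class RegulatoryNetwork:
    """A signed directed regulatory network.

    Parameters
    ----------
    node_names
        Node identifiers in a fixed order; all matrices and state vectors
        produced by this package are aligned to this order.
    adjacency
        N x N integer matrix with entries in {-1, 0, +1}; ``adjacency[i, j]``
        is the sign of the edge from node ``i`` to node ``j``.
    node_classes
        Map node name -> "signal" | "output" | "core". Computed from degrees
        if not supplied: signal nodes have no incoming edges, output nodes no
        outgoing edges, every other node is core.
    """

    node_names: list[str]
    adjacency: np.ndarray
    node_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        self.node_names = list(self.node_names)
        n = len(self.node_names)
        if n < 2:
            raise ValueError("a regulatory network needs at least 2 nodes")
        if len(set(self.node_names)) != n:
            raise ValueError("node names must be unique")
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match {n} nodes"
            )
        if not np.isin(self.adjacency, (-1, 0, 1)).all():
            raise ValueError("adjacency entries must be in {-1, 0, +1}")
        if not self.node_classes:
            self.node_classes = classify_nodes(self)

    # -- basic descriptors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    @property
    def density(self) -> float:
        """Edge density E / N^2."""
        return self.n_edges / self.n_nodes**2

    def node_index(self, name: str) -> int:
        return self.node_names.index(name)

    def indices_of(self, node_class: str) -> np.ndarray:
        """Indices of nodes in a class ('signal', 'output' or 'core')."""
        return np.array(
            [i for i, nm in enumerate(self.node_names) if self.node_classes[nm] == node_class],
            dtype=np.intp,
        )

    @property
    def core(self) -> np.ndarray:
        return self.indices_of("core")

    @property
    def signals(self) -> np.ndarray:
        return self.indices_of("signal")

    @property
    def outputs(self) -> np.ndarray:
        return self.indices_of("output")

    def edge_list(self) -> list[tuple[str, str, int]]:
        """Edges as (source, target, sign) triples in row-major order."""
        src, dst = np.nonzero(self.adjacency)
        return [
            (self.node_names[i], self.node_names[j], int(self.adjacency[i, j]))
            for i, j in zip(src, dst)
        ]

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(
            list(self.node_names), self.adjacency.copy(), dict(self.node_classes)
        )


def classify_nodes(net: RegulatoryNetwork) -> dict[str, str]:
    """Classify every node as signal, output or core from its degrees.

    Signal nodes have in-degree 0 (no regulator, so they hold whatever value
    they are given); output nodes have out-degree 0 (they regulate nothing);
    all remaining nodes are core. A fully isolated node (in = out = 0) is
    classified as signal — like a signal it can never revert once flipped —
    and a warning is emitted.
    """
    adj = net.adjacency
    in_deg = np.count_nonzero(adj, axis=0)
    out_deg = np.count_nonzero(adj, axis=1)
    classes: dict[str, str] = {}
    for i, name in enumerate(net.node_names):
        if in_deg[i] == 0 and out_deg[i] == 0:
            warnings.warn(f"node {name!r} is isolated; classified as signal")
            classes[name] = "signal"
        elif in_deg[i] == 0:
            classes[name] = "signal"
        elif out_deg[i] == 0:
            classes[name] = "output"
        else:
            classes[name] = "core"
    return classes


def read_topo(path: str | Path, annotations: str | Path | None = None) -> RegulatoryNetwork:
    """Read a signed network from a topo edge-list file.

    The first non-blank line must be the header ``Source Target Type``;
    each following non-blank line is ``source target type`` with type 1
    (activation) or 2 (inhibition). Node order is first-appearance order.
    Duplicate identical edges collapse to one (with a warning); the same
    ordered pair listed with both signs is an error.

    ``annotations`` optionally names a CSV sidecar (``node,class`` with an
    optional third column) whose class column — signal/output/core —
    overrides the degree-based auto-classification for the listed nodes.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise TopoFormatError(f"{path}: empty topo file")
    header = tuple(lines[0].split())
    if header != TOPO_HEADER:
        raise TopoFormatError(
            f"{path}: expected header 'Source Target Type', got {lines[0]!r}"
        )

    names: list[str] = []
    index: dict[str, int] = {}
    edges: dict[tuple[int, int], int] = {}

    def _idx(name: str) -> int:
        if name not in index:
            index[name] = len(names)
            names.append(name)
        return index[name]

    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != 3:
            raise TopoFormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        src, dst, typ = parts
        if typ not in ("1", "2"):
            raise ValueError(f"{path}:{lineno}: Type must be 1 or 2, got {typ!r}")
        sign = 1 if typ == "1" else -1
        key = (_idx(src), _idx(dst))
        if key in edges:
            if edges[key] != sign:
                raise ValueError(
                    f"{path}:{lineno}: contradictory duplicate edge {src}->{dst}"
                )
            warnings.warn(f"{path}:{lineno}: duplicate edge {src}->{dst} collapsed")
            continue
        edges[key] = sign

    n = len(names)
    adj = np.zeros((n, n), dtype=np.int8)
    for (i, j), sign in edges.items():
        adj[i, j] = sign
    net = RegulatoryNetwork(names, adj)
    if annotations is not None:
        overrides = _read_annotations(annotations)
        unknown = set(overrides) - set(names)
        if unknown:
            raise ValueError(f"annotation sidecar names unknown nodes: {sorted(unknown)}")
        net.node_classes.update(overrides)
    return net


def _read_annotations(path: str | Path) -> dict[str, str]:
    """Parse a ``node,class[,team_hint]`` CSV sidecar into a class map."""
    valid = {"signal", "output", "core"}
    overrides: dict[str, str] = {}
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    for lineno, ln in enumerate(lines, start=1):
        parts = [p.strip() for p in ln.split(",")]
        if lineno == 1 and parts[0].lower() == "node":
            continue
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'node,class' columns")
        node, cls = parts[0], parts[1].lower()
        if cls not in valid:
            raise ValueError(f"{path}:{lineno}: class must be one of {sorted(valid)}")
        overrides[node] = cls
    return overrides


def write_topo(net: RegulatoryNetwork, path: str | Path) -> Path:
    """Write a network as a topo edge-list file (round-trips with read_topo)."""
    path = Path(path)
    rows = ["Source Target Type"]
    for src, dst, sign in net.edge_list():
        rows.append(f"{src} {dst} {1 if sign > 0 else 2}")
    path.write_text("\n".join(rows) + "\n")
    return path
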