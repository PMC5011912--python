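"""Simple node-labelled networks and set-level degree/link accounting.

The enrichment test operates on a *simple* graph (no self-loops, no
parallel edges) that is directed, undirected, or mixed (partially
directed).  A mixed network is analysed through its directed expansion,
in which every undirected edge {v, w} stands for the pair of arrows
(v, w) and (w, v).

Node labels are opaque, case-sensitive strings: gene identifiers are
case-significant in some nomenclatures, so no normalisation is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MODES = ("directed", "undirected", "mixed")

__all__ = [
    "MODES",
    "NetworkError",
    "Network",
    "NodeSet",
    "DegreeTable",
    "SetDegrees",
    "build_network",
    "expand_mixed",
    "degree_table",
    "set_degrees",
    "count_links",
]


class NetworkError(ValueError):
    """Invalid network, node set, or parameterisation."""


@dataclass(frozen=True)
class NodeSet:
    """A named collection of distinct node labels (target or functional set)."""

    name: str
    members: tuple[str, ...]

    def __init__(self, name: str, members: Iterable[str]):
        labels = [str(m) for m in members]
        seen: dict[str, None] = dict.fromkeys(labels)
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "members", tuple(seen))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


class Network:
    """A simple graph with string node labels and a directedness mode.

    Do not call the constructor with raw index arrays from user code;
    :func:`build_network` performs label coercion, canonicalisation and
    validation.
    """

    __slots__ = ("nodes", "mode", "_index", "_arcs", "_edges")

    def __init__(
        self,
        nodes: Sequence[str],
        arcs: np.ndarray,
        edges: np.ndarray,
        mode: str,
    ):
        if mode not in MODES:
            raise NetworkError(f"unknown mode {mode!r}; expected one of {MODES}")
        self.nodes: tuple[str, ...] = tuple(nodes)
        self.mode = mode
        self._index = {v: i for i, v in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise NetworkError("duplicate node labels")
        # arcs: (D, 2) int array of directed links; edges: (U, 2) with row[0] < row[1]
        self._arcs = np.asarray(arcs, dtype=np.int64).reshape(-1, 2)
        self._edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Total number of links (arcs plus undirected edges)."""
        return len(self._arcs) + len(self._edges)

    @property
    def arcs(self) -> np.ndarray:
        """Directed links as an (n, 2) index array (read-only view)."""
        return self._arcs

    @property
    def undirected_edges(self) -> np.ndarray:
        """Undirected links as an (n, 2) index array with row[0] < row[1]."""
        return self._edges

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        """Map labels to node indices, raising on unknown labels."""
        labels = [str(v) for v in labels]
        missing = [v for v in labels if v not in self._index]
        if missing:
            raise NetworkError(
                "node labels not in network: " + ", ".join(sorted(missing))
            )
        return np.fromiter((self._index[v] for v in labels), dtype=np.int64,
                           count=len(labels))

    def __contains__(self, label: str) -> bool:
        return str(label) in self._index

    def edge_records(self) -> list[tuple]:
        """Edges as label tuples; mixed mode includes the direction flag."""
        recs: list[tuple] = []
        for u, v in self._arcs:
            rec = (self.nodes[u], self.nodes[v])
            recs.append(rec + ("directed",) if self.mode == "mixed" else rec)
        for u, v in self._edges:
            rec = (self.nodes[u], self.nodes[v])
            recs.append(rec + ("undirected",) if self.mode == "mixed" else rec)
        return recs

    def adjacency(self, dense: bool = False):
        """Adjacency matrix of the analysed image of the network.

        Directed / mixed: entry (i, j) = 1 iff there is an arrow i -> j in
        the directed expansion.  Undirected: symmetric 0/1 matrix.
        """
        n = self.n_nodes
        if self.mode == "undirected":
            rows = np.concatenate([self._edges[:, 0], self._edges[:, 1]])
            cols = np.concatenate([self._edges[:, 1], self._edges[:, 0]])
        else:
            net = expand_mixed(self) if self.mode == "mixed" else self
            rows, cols = net._arcs[:, 0], net._arcs[:, 1]
        data = np.ones(len(rows), dtype=np.int64)
        mat = sp.csr_array((data, (rows, cols)), shape=(n, n))
        return mat.toarray() if dense else mat

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Network mode={self.mode!r} nodes={self.n_nodes} "
            f"edges={self.n_edges}>"
        )


def build_network(
    edge_records: Iterable[Sequence],
    mode: str,
    nodes: Optional[Sequence[str]] = None,
) -> Network:
    """Build a canonical simple :class:`Network` from edge records.

    Parameters
    ----------
    edge_records
        Iterable of ``(u, v)`` pairs; in mixed mode each record must carry
        a third element, the direction flag ``"directed"`` or
        ``"undirected"``.
    mode
        ``"directed"``, ``"undirected"`` or ``"mixed"``.
    nodes
        Optional explicit node list (needed to declare isolated nodes).
        When omitted, nodes are inferred from the records in order of
        first appearance.

    Duplicate edges are collapsed with a logged warning; self-loops raise
    :class:`NetworkError` (their degree contribution is ambiguous in the
    stub-sampling model behind the test).
    """
    if mode not in MODES:
        raise NetworkError(f"unknown mode {mode!r}; expected one of {MODES}")

    parsed: list[tuple[str, str, bool]] = []  # (u, v, is_directed)
    order: dict[str, None] = {}
    for rec in edge_records:
        rec = tuple(rec)
        if len(rec) < 2:
            raise NetworkError(f"edge record too short: {rec!r}")
        u, v = str(rec[0]), str(rec[1])
        if not u or not v:
            raise NetworkError(f"empty node label in edge record {rec!r}")
        if u == v:
            raise NetworkError(f"self-loop at node {u!r} is not allowed")
        if mode == "mixed":
            if len(rec) < 3:
                raise NetworkError(
                    f"mixed-mode edge record {rec!r} lacks a direction flag"
                )
            flag = str(rec[2]).lower()
            if flag not in ("directed", "undirected"):
                raise NetworkError(f"unknown direction flag {rec[2]!r}")
            directed = flag == "directed"
        else:
            directed = mode == "directed"
        parsed.append((u, v, directed))
        order.setdefault(u)
        order.setdefault(v)

    if nodes is None:
        node_list = list(order)
    else:
        node_list = [str(v) for v in nodes]
        index = set(node_list)
        unknown = sorted({u for u, v, _ in parsed if u not in index}
                         | {v for u, v, _ in parsed if v not in index})
        if unknown:
            raise NetworkError(
                "edge endpoints not in declared node list: " + ", ".join(unknown)
            )
    index = {v: i for i, v in enumerate(node_list)}
    if len(index) != len(node_list):
        raise NetworkError("duplicate node labels")

    arc_set: dict[tuple[int, int], None] = {}
    edge_set: dict[tuple[int, int], None] = {}
    dupes = 0
    for u, v, directed in parsed:
        i, j = index[u], index[v]
        if directed:
            key = (i, j)
            target = arc_set
        else:
            key = (min(i, j), max(i, j))
            target = edge_set
        if key in target:
            dupes += 1
        else:
            target[key] = None
    if dupes:
        logger.warning("collapsed %d duplicate edge(s) during canonicalization", dupes)

    arcs = np.array(list(arc_set), dtype=np.int64).reshape(-1, 2)
    edges = np.array(list(edge_set), dtype=np.int64).reshape(-1, 2)
    return Network(node_list, arcs, edges, mode)


def expand_mixed(net: Network) -> Network:
    """Directed expansion of a mixed network.

    Every undirected edge {v, w} is replaced by the pair of arrows
    (v, w) and (w, v); directed edges are kept.  An arc coinciding with
    one orientation of an undirected edge is collapsed with a warning.
    """
    if net.mode != "mixed":
        raise NetworkError(f"expand_mixed expects a mixed network, got {net.mode!r}")
    fwd = net._edges
    rev = net._edges[:, ::-1]
    all_arcs = np.concatenate([net._arcs, fwd, rev], axis=0)
    keys = set()
    keep = []
    for row in all_arcs:
        key = (int(row[0]), int(row[1]))
        if key in keys:
            continue
        keys.add(key)
        keep.append(key)
    if len(keep) < len(all_arcs):
        logger.warning(
            "collapsed %d arc(s) duplicated by undirected expansion",
            len(all_arcs) - len(keep),
        )
    arcs = np.array(keep, dtype=np.int64).reshape(-1, 2)
    return Network(net.nodes, arcs, np.empty((0, 2)), "directed")


@dataclass(frozen=True)
class DegreeTable:
    """Per-node degrees and network totals.

    Directed (and mixed, via the directed expansion): ``indegree`` and
    ``outdegree`` per node; ``total_indegree`` (i_V) equals the number of
    arrows.  Undirected: ``degree`` per node; ``total_degree`` (d_V)
    equals twice the number of edges.
    """

    nodes: tuple[str, ...]
    indegree: Optional[np.ndarray] = None
    outdegree: Optional[np.ndarray] = None
    degree: Optional[np.ndarray] = None
    total_indegree: Optional[int] = None
    total_degree: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        if self.outdegree is not None:
            cols["outdegree"] = self.outdegree
            cols["indegree"] = self.indegree
        if self.degree is not None:
            cols["degree"] = self.degree
        return pd.DataFrame(cols, index=list(self.nodes))


@dataclass(frozen=True)
class SetDegrees:
    """Degrees of a node set: (o_S, i_S) in directed mode, d_S otherwise."""

    out_degree: Optional[int] = None
    in_degree: Optional[int] = None
    degree: Optional[int] = None


def degree_table(net: Network) -> DegreeTable:
    """Per-node and total degrees; mixed networks use the directed expansion."""
    n = net.n_nodes
    if net.mode == "undirected":
        deg = np.zeros(n, dtype=np.int64)
        np.add.at(deg, net._edges[:, 0], 1)
        np.add.at(deg, net._edges[:, 1], 1)
        return DegreeTable(net.nodes, degree=deg, total_degree=int(deg.sum()))
    image = expand_mixed(net) if net.mode == "mixed" else net
    out = np.zeros(n, dtype=np.int64)
    ind = np.zeros(n, dtype=np.int64)
    np.add.at(out, image._arcs[:, 0], 1)
    np.add.at(ind, image._arcs[:, 1], 1)
    return DegreeTable(
        net.nodes, indegree=ind, outdegree=out, total_indegree=int(ind.sum())
    )


def set_degrees(net: Network, S: NodeSet) -> SetDegrees:
    """Sum of the relevant per-node degrees over the members of ``S``."""
    idx = net.indices(S.members)
    table = degree_table(net)
    if net.mode == "undirected":
        return SetDegrees(degree=int(table.degree[idx].sum()))
    return SetDegrees(
        out_degree=int(table.outdegree[idx].sum()),
        in_degree=int(table.indegree[idx].sum()),
    )


def count_links(net: Network, A: NodeSet, B: NodeSet) -> int:
    """Observed links n_AB between two node sets.

    Directed / mixed: the number of arrows (u, v) with u in A and v in B
    in the directed expansion (ordered count A -> B).  Undirected: the
    adjacency-submatrix sum over A x B; an edge with both endpoints in
    A intersect B therefore counts twice, once per orientation, which is
    the convention consistent with the stub-sampling null (both stubs of
    such an edge fall in the d_A sample and both opposite endpoints lie
    in B).
    """
    a_idx = net.indices(A.members)
    b_idx = net.indices(B.members)
    n = net.n_nodes
    in_a = np.zeros(n, dtype=bool)
    in_b = np.zeros(n, dtype=bool)
    in_a[a_idx] = True
    in_b[b_idx] = True
    if net.mode == "undirected":
        e = net._edges
        fwd = in_a[e[:, 0]] & in_b[e[:, 1]]
        rev = in_a[e[:, 1]] & in_b[e[:, 0]]
        return int(fwd.sum() + rev.sum())
    image = expand_mixed(net) if net.mode == "mixed" else net
    arcs = image._arcs
    return int((in_a[arcs[:, 0]] & in_b[arcs[:, 1]]).sum())
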