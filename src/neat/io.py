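"""Readers and writers for the plain-text formats the tool touches.

Networks come in as two-column edge-list TSVs (optional third column with
the per-edge direction flag for mixed networks) or as square labelled
adjacency matrices; gene sets come in as GMT or whitespace-separated
list files; results go out as a deterministic TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .graph_core import Network, NetworkError, NodeSet, build_network
from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "read_adjacency",
    "read_gene_sets",
    "write_results",
    "results_to_frame",
]

PathLike = Union[str, Path]

RESULT_COLUMNS = (
    "set_A", "set_B", "direction", "n_AB",
    "expected_n_AB", "p_value", "conclusion",
)


def read_edge_list(path: PathLike, mode: str) -> Network:
    """Read an edge-list TSV into a :class:`Network`.

    Columns are ``from`` and ``to`` (header optional, auto-detected),
    plus an optional third ``direction`` column taking values
    ``directed``/``undirected`` for mixed networks.  Lines starting with
    ``#`` are ignored; fields may be separated by tabs or spaces.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields]
            if len(fields) < 2:
                raise NetworkError(
                    f"{path}:{lineno}: expected at least two columns, got {line!r}"
                )
            if (
                not records
                and fields[0].lower() == "from"
                and fields[1].lower() == "to"
            ):
                continue  # header line
            records.append(tuple(fields[:3]) if mode == "mixed" else tuple(fields[:2]))
    if not records:
        raise NetworkError(f"no edges found in {path}")
    return build_network(records, mode)


def read_adjacency(path: PathLike, mode: Optional[str] = None) -> Network:
    """Read a square labelled adjacency matrix (TSV; entry > 0 means edge).

    Node labels must appear as both the first row and the first column.
    When ``mode`` is omitted, a symmetric matrix is read as undirected
    and an asymmetric one as directed.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    if list(frame.index) != list(frame.columns):
        raise NetworkError(
            f"{path}: adjacency matrix row and column labels differ"
        )
    mat = frame.to_numpy() > 0
    symmetric = bool((mat == mat.T).all())
    if mode is None:
        mode = "undirected" if symmetric else "directed"
    if mode == "undirected" and not symmetric:
        raise NetworkError(f"{path}: asymmetric matrix cannot be undirected")
    labels = list(frame.index)
    if mode == "undirected":
        rows, cols = np.nonzero(np.triu(mat, k=0))
    else:
        rows, cols = np.nonzero(mat)
    records = [(labels[i], labels[j]) for i, j in zip(rows, cols)]
    if not records:
        raise NetworkError(f"no edges found in {path}")
    return build_network(records, mode, nodes=labels)


def read_gene_sets(path: PathLike, fmt: str = "auto") -> list[NodeSet]:
    """Read named gene sets from a GMT or whitespace-list file.

    GMT lines are ``name<TAB>description<TAB>member...``; list lines are
    ``name member member ...``.  With ``fmt="auto"`` the ``.gmt``
    extension selects GMT.  Duplicate members within a set are removed
    with a warning; an empty set or a duplicate set name is an error.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "list"
    if fmt not in ("gmt", "list"):
        raise NetworkError(f"unknown gene-set format {fmt!r}")

    sets: list[NodeSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if fmt == "gmt":
                fields = line.split("\t")
                if len(fields) < 3:
                    raise NetworkError(
                        f"{path}:{lineno}: GMT line needs name, description "
                        "and at least one member"
                    )
                name, members = fields[0], [f for f in fields[2:] if f.strip()]
            else:
                fields = line.split()
                name, members = fields[0], fields[1:]
            if not members:
                raise NetworkError(f"{path}:{lineno}: set {name!r} is empty")
            if name in names:
                raise NetworkError(f"{path}:{lineno}: duplicate set name {name!r}")
            names.add(name)
            node_set = NodeSet(name, members)
            if len(node_set) < len(members):
                logger.warning(
                    "set %s: removed %d duplicate member(s)",
                    name, len(members) - len(node_set),
                )
            sets.append(node_set)
    if not sets:
        raise NetworkError(f"no gene sets found in {path}")
    return sets


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Results as a DataFrame with the standard column order."""
    rows = {
        "set_A": [r.set_a for r in results],
        "set_B": [r.set_b for r in results],
        "direction": [r.direction for r in results],
        "n_AB": [r.nab for r in results],
        "expected_n_AB": [r.expected for r in results],
        "p_value": [r.pvalue for r in results],
    }
    if results and results[0].adjusted_p is not None:
        rows["adjusted_p"] = [r.adjusted_p for r in results]
    rows["conclusion"] = [r.conclusion for r in results]
    return pd.DataFrame(rows)


def write_results(results: Sequence[EnrichmentResult], path: PathLike) -> None:
    """Write results as a TSV (p-values with 6 significant digits)."""
    if not results:
        raise NetworkError("no results to write")
    frame = results_to_frame(results)
    for col in ("expected_n_AB", "p_value", "adjusted_p"):
        if col in frame:
            frame[col] = frame[col].map(lambda x: format(float(x), ".6g"))
    frame.to_csv(path, sep="\t", index=False)


def read_results(path: PathLike) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
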