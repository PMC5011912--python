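"""Model / results interface for network enrichment analysis.

`NEAT` is the user-facing model object: it binds a network to two
collections of node sets, validates memberships, and its :meth:`NEAT.fit`
returns a :class:`NEATResults` carrying the per-pair estimates (observed
links, null expectation, p-value, verdict) with a ``summary()`` table.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import pandas as pd

from . import io as _io
from .enrichment import EnrichmentResult, neat
from .graph_core import Network, NetworkError, NodeSet

logger = logging.getLogger(__name__)

__all__ = ["NEAT", "NEATResults"]


class NEAT:
    """Network enrichment analysis test for a network and two set collections.

    Parameters
    ----------
    network
        A :class:`~neat.graph_core.Network` (directed, undirected or mixed).
    targets
        Target node sets (e.g. differentially expressed genes).
    functionals
        Functional node sets (e.g. GO categories).  When omitted, the
        targets are tested against themselves.
    missing
        Policy for set members absent from the network: ``"drop"``
        removes them with a logged warning (real gene sets routinely
        contain genes outside curated networks), ``"error"`` raises.
    """

    def __init__(
        self,
        network: Network,
        targets: Sequence[NodeSet],
        functionals: Optional[Sequence[NodeSet]] = None,
        missing: str = "drop",
    ):
        if missing not in ("drop", "error"):
            raise NetworkError(f"unknown missing-member policy {missing!r}")
        self.network = network
        self.targets = [self._validate(s, missing) for s in targets]
        if functionals is None:
            self.functionals = self.targets
        else:
            self.functionals = [self._validate(s, missing) for s in functionals]
        if not self.targets or not self.functionals:
            raise NetworkError("empty set list")

    def _validate(self, s: NodeSet, missing: str) -> NodeSet:
        absent = [m for m in s.members if m not in self.network]
        if not absent:
            return s
        if missing == "error":
            raise NetworkError(
                f"set {s.name!r} has members absent from the network: "
                + ", ".join(absent)
            )
        logger.warning(
            "set %s: dropped %d member(s) absent from the network",
            s.name, len(absent),
        )
        kept = [m for m in s.members if m in self.network]
        if not kept:
            raise NetworkError(
                f"set {s.name!r} has no members left after dropping "
                "those absent from the network"
            )
        return NodeSet(s.name, kept)

    @classmethod
    def from_files(
        cls,
        network_path: str,
        sets_a_path: str,
        sets_b_path: Optional[str] = None,
        network_format: str = "edgelist",
        mode: str = "undirected",
        missing: str = "drop",
    ) -> "NEAT":
        """Build the model from an edge-list/adjacency file and GMT set files."""
        if network_format == "edgelist":
            net = _io.read_edge_list(network_path, mode)
        elif network_format == "adjacency":
            net = _io.read_adjacency(network_path, mode)
        else:
            raise NetworkError(f"unknown network format {network_format!r}")
        targets = _io.read_gene_sets(sets_a_path)
        functionals = _io.read_gene_sets(sets_b_path) if sets_b_path else None
        return cls(net, targets, functionals, missing=missing)

    def fit(self, alpha: float = 0.05, adjust: Optional[str] = None) -> "NEATResults":
        """Run the enrichment test over every pair of sets.

        ``adjust="bh"`` adds a Benjamini-Hochberg adjusted p-value column;
        the enrichment verdicts themselves use the raw p-values at the
        given level, which is how the test is calibrated.
        """
        results = neat(
            self.network, self.targets, self.functionals,
            alpha=alpha, adjust=adjust,
        )
        return NEATResults(self, results, alpha=alpha, adjust=adjust)


class NEATResults:
    """Fitted enrichment results: one row per tested pair of sets."""

    def __init__(
        self,
        model: NEAT,
        results: list[EnrichmentResult],
        alpha: float,
        adjust: Optional[str],
    ):
        self.model = model
        self.results = results
        self.alpha = alpha
        self.adjust = adjust
        self.frame = _io.results_to_frame(results)

    @property
    def pvalues(self) -> pd.Series:
        return self.frame["p_value"]

    @property
    def n_significant(self) -> int:
        return int((self.frame["p_value"] < self.alpha).sum())

    def to_tsv(self, path) -> None:
        """Write the results table (deterministic, tab-separated)."""
        _io.write_results(self.results, path)

    def summary(self) -> str:
        """Plain-text summary: model dimensions and the full results table."""
        net = self.model.network
        calls = self.frame["conclusion"].value_counts()
        head = [
            "Network Enrichment Analysis Test",
            "=" * 64,
            f"network mode:      {net.mode}",
            f"nodes / edges:     {net.n_nodes} / {net.n_edges}",
            f"target sets:       {len(self.model.targets)}",
            f"functional sets:   {len(self.model.functionals)}",
            f"tests:             {len(self.results)}",
            f"alpha:             {self.alpha:g}"
            + (f"   (adjust: {self.adjust})" if self.adjust else ""),
            f"enrichments found: {self.n_significant}"
            + f" ({calls.get('over-enriched', 0)} over, "
            + f"{calls.get('under-enriched', 0)} under)",
            "-" * 64,
        ]
        table = self.frame.copy()
        table["expected_n_AB"] = table["expected_n_AB"].map(lambda x: f"{x:.2f}")
        table["p_value"] = table["p_value"].map(lambda x: f"{x:.4g}")
        if "adjusted_p" in table:
            table["adjusted_p"] = table["adjusted_p"].map(lambda x: f"{x:.4g}")
        return "\n".join(head) + "\n" + table.to_string(index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<NEATResults tests={len(self.results)} "
            f"significant={self.n_significant} alpha={self.alpha:g}>"
        )
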