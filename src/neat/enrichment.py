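"""The network enrichment test: hypergeometric null and two-sided p-value.

Under no enrichment the number of links N_AB between node sets A and B
follows a hypergeometric law: the o_A arrows leaving A (directed case)
are a sample without replacement from the i_V arrows of the network, of
which the i_B arrows entering B are "successes",

    N_AB ~ hypergeom(n = o_A, K = i_B, N = i_V),

and in the undirected case the total degrees (d_A, d_B, d_V) play the
same roles.  The two-sided p-value of the observed count t is

    p = 2 min[ P0(T < t), P0(T > t) ] + P0(T = t),

which, unlike the doubled one-tailed p-value, always lies in [0, 1] for
a discrete statistic.  Tail probabilities are obtained by summing the
probability mass of the smaller tail directly in log space, never as
one minus the other tail, so extreme counts on large networks do not
suffer catastrophic cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .graph_core import Network, NetworkError, NodeSet, degree_table, expand_mixed

__all__ = [
    "NullParams",
    "EnrichmentResult",
    "hypergeom_pmf",
    "two_sided_pvalue",
    "null_params",
    "neat",
    "test_pairs",
    "OVER", "UNDER", "NO_EVIDENCE",
]

OVER = "over-enriched"
UNDER = "under-enriched"
NO_EVIDENCE = "no evidence"


@dataclass(frozen=True)
class NullParams:
    """Hypergeometric null parameterisation for one pair of node sets.

    ``n`` is the sample size (o_A directed, d_A undirected), ``K`` the
    number of successes in the population (i_B / d_B) and ``N`` the
    population size (i_V / d_V).
    """

    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (0 <= self.n <= self.N and 0 <= self.K <= self.N):
            raise NetworkError(
                f"invalid hypergeometric parameters n={self.n}, K={self.K}, N={self.N}"
            )

    @property
    def mu0(self) -> float:
        """Null expectation of the link count, n*K/N."""
        return self.n * self.K / self.N

    @property
    def support(self) -> tuple[int, int]:
        return max(0, self.n + self.K - self.N), min(self.n, self.K)

    @property
    def degenerate(self) -> bool:
        """True when the null is a point mass (the test returns p = 1)."""
        lo, hi = self.support
        return lo == hi


@dataclass(frozen=True)
class EnrichmentResult:
    """One row of output: a tested pair of sets and its verdict."""

    set_a: str
    set_b: str
    direction: str  # "A->B" style arrow, or "A--B" for undirected pairs
    nab: int
    expected: float  # mu0
    pvalue: float
    conclusion: str
    alpha: float
    adjusted_p: Optional[float] = None


def _lchoose(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def _log_support(params: NullParams) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = params.support
    k = np.arange(lo, hi + 1)
    lp = (
        _lchoose(params.K, k)
        + _lchoose(params.N - params.K, params.n - k)
        - _lchoose(params.N, params.n)
    )
    return k, lp


def hypergeom_pmf(k: int, params: NullParams) -> float:
    """P(T = k) under the null; 0 outside the support."""
    lo, hi = params.support
    if k < lo or k > hi:
        return 0.0
    lp = (
        _lchoose(params.K, k)
        + _lchoose(params.N - params.K, params.n - k)
        - _lchoose(params.N, params.n)
    )
    return float(np.exp(lp))


def two_sided_pvalue(t: int, params: NullParams) -> float:
    """Two-sided p-value 2*min[P0(T<t), P0(T>t)] + P0(T=t), in [0, 1]."""
    t = int(t)
    lo, hi = params.support
    if t < lo or t > hi:
        # observed value outside the support: the point mass is zero and
        # one strict tail is empty, so the formula evaluates to zero
        return 0.0
    k, lp = _log_support(params)
    below = lp[k < t]
    above = lp[k > t]
    lower = float(np.exp(logsumexp(below))) if below.size else 0.0
    upper = float(np.exp(logsumexp(above))) if above.size else 0.0
    point = float(np.exp(lp[t - lo]))
    p = 2.0 * min(lower, upper) + point
    return float(min(1.0, max(0.0, p)))


def _double_tail_pvalue(t: int, params: NullParams) -> float:
    """Doubled one-tailed p-value 2*min[P0(T<=t), P0(T>=t)] (may exceed 1).

    Internal only: it differs from the reported p-value by exactly
    P0(T=t), an identity asserted in the test suite; it is not exposed
    because it is not a probability.
    """
    lo, hi = params.support
    if t < lo or t > hi:
        return 0.0
    k, lp = _log_support(params)
    le = float(np.exp(logsumexp(lp[k <= t])))
    ge = float(np.exp(logsumexp(lp[k >= t])))
    return 2.0 * min(le, ge)


def null_params(net: Network, A: NodeSet, B: NodeSet) -> NullParams:
    """Null parameterisation for the pair (A, B) on the given network.

    Directed and mixed networks use (o_A, i_B, i_V) on the directed
    expansion; undirected networks use the total degrees (d_A, d_B, d_V).
    Raises :class:`NetworkError` on an edgeless network.
    """
    table = degree_table(net)
    a_idx = net.indices(A.members)
    b_idx = net.indices(B.members)
    if net.mode == "undirected":
        total = table.total_degree
        if total == 0:
            raise NetworkError("no links in network")
        return NullParams(
            n=int(table.degree[a_idx].sum()),
            K=int(table.degree[b_idx].sum()),
            N=int(total),
        )
    total = table.total_indegree
    if total == 0:
        raise NetworkError("no links in network")
    return NullParams(
        n=int(table.outdegree[a_idx].sum()),
        K=int(table.indegree[b_idx].sum()),
        N=int(total),
    )


# ---------------------------------------------------------------------------
# batch testing


def _membership(net: Network, sets: Sequence[NodeSet]) -> sp.csr_array:
    rows, cols = [], []
    for i, s in enumerate(sets):
        idx = net.indices(s.members)
        rows.extend([i] * len(idx))
        cols.extend(idx.tolist())
    data = np.ones(len(rows), dtype=np.int64)
    return sp.csr_array((data, (rows, cols)), shape=(len(sets), net.n_nodes))


def test_pairs(
    net: Network,
    sets: Sequence[NodeSet],
    pairs: Sequence[tuple[int, int]],
    alpha: float = 0.05,
    adjust: Optional[str] = None,
) -> list[EnrichmentResult]:
    """Run the enrichment test for the listed (index) pairs of sets.

    ``pairs`` are ``(i, j)`` indices into ``sets``; directed/mixed
    networks test the ordered pair sets[i] -> sets[j], undirected
    networks the unordered pair.  This is the vectorised core behind
    :func:`neat` and the simulation harness.
    """
    if not 0.0 < alpha < 1.0:
        raise NetworkError(f"alpha must lie in (0, 1), got {alpha}")
    if adjust not in (None, "none", "bh"):
        raise NetworkError(f"unknown adjustment method {adjust!r}")
    if not pairs:
        raise NetworkError("no set pairs to test")

    table = degree_table(net)
    memb = _membership(net, sets)
    adj = net.adjacency()
    counts = (memb @ adj @ memb.T).toarray()
    undirected = net.mode == "undirected"
    if undirected:
        if table.total_degree == 0:
            raise NetworkError("no links in network")
        deg = memb @ table.degree
        n_arr, k_arr = deg, deg
        total = int(table.total_degree)
        arrow = "--"
    else:
        if table.total_indegree == 0:
            raise NetworkError("no links in network")
        n_arr = memb @ table.outdegree
        k_arr = memb @ table.indegree
        total = int(table.total_indegree)
        arrow = "->"

    results = []
    pvals = np.empty(len(pairs))
    for r, (i, j) in enumerate(pairs):
        params = NullParams(n=int(n_arr[i]), K=int(k_arr[j]), N=total)
        t = int(counts[i, j])
        pvals[r] = two_sided_pvalue(t, params)
    adj_p = false_discovery_control(pvals, method="bh") if adjust == "bh" else None

    for r, (i, j) in enumerate(pairs):
        mu0 = int(n_arr[i]) * int(k_arr[j]) / total
        t = int(counts[i, j])
        p = float(pvals[r])
        if p < alpha and t > mu0:
            concl = OVER
        elif p < alpha and t < mu0:
            concl = UNDER
        else:
            concl = NO_EVIDENCE
        results.append(
            EnrichmentResult(
                set_a=sets[i].name,
                set_b=sets[j].name,
                direction=arrow,
                nab=t,
                expected=mu0,
                pvalue=p,
                conclusion=concl,
                alpha=alpha,
                adjusted_p=float(adj_p[r]) if adj_p is not None else None,
            )
        )
    return results


def neat(
    net: Network,
    targets: Sequence[NodeSet],
    functionals: Sequence[NodeSet],
    alpha: float = 0.05,
    adjust: Optional[str] = None,
) -> list[EnrichmentResult]:
    """Test every target set against every functional set.

    Directed and mixed networks test each ordered pair target -> functional;
    undirected networks test each unordered pair exactly once, reported
    with set names in lexicographic order.  Rows are ordered targets
    outer, functionals inner.
    """
    targets = list(targets)
    functionals = list(functionals)
    if not targets or not functionals:
        raise NetworkError("empty set list")

    sets: list[NodeSet] = []
    index: dict[int, int] = {}
    for s in list(targets) + list(functionals):
        if id(s) not in index:
            index[id(s)] = len(sets)
            sets.append(s)

    undirected = net.mode == "undirected"
    pairs: list[tuple[int, int]] = []
    seen: set[frozenset] = set()
    for a in targets:
        for b in functionals:
            i, j = index[id(a)], index[id(b)]
            if undirected:
                key = frozenset((sets[i].name, sets[j].name))
                if key in seen:
                    continue
                seen.add(key)
                if sets[j].name < sets[i].name:
                    i, j = j, i
            pairs.append((i, j))
    return test_pairs(net, sets, pairs, alpha=alpha, adjust=adjust)
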