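"""Benchmark harness: calibration and power of the enrichment test.

Five stock designs (S1-S5) generate fixed-degree-sequence random
networks with 1000 nodes, draw 50 node sets of size 50-100, plant
enrichments by adding or removing cross links, run the test on every
pair of sets, and score the outcome:

=========  ==========  ====================================  ==================
design     mode        degree model                          planted effects
=========  ==========  ====================================  ==================
S1         directed    power law (exponent 4, min 20)        200 of 2450 pairs
S2         directed    Poisson mixture (40/100, 99%/1%)      200 of 2450 pairs
S3         directed    Poisson mixture (overlap study)       +35 arrows per H1
S4         undirected  power law (exponent 4, min 20)        100 of 1225 pairs
S5         undirected  Poisson mixture (40/100, 99%/1%)      100 of 1225 pairs
=========  ==========  ====================================  ==================

Effect sizes in S1/S2/S4/S5 change n_AB by a proportion drawn uniformly
from [0.10, 0.50], with addition or removal decided by a fair coin.
S3 fixes |A| = |B| = 50 and sweeps the overlap |A intersect B| over
{0, 5, ..., 50}, running 2000 tests per level (1000 true nulls, 1000
with 35 added arrows).

Graphs realise their degree sequences exactly: stubs are matched at
random and the resulting multigraph is simplified by degree-preserving
edge swaps until no self-loops or parallel links remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import kstest, rankdata

from .enrichment import NullParams, test_pairs, two_sided_pvalue
from .graph_core import Network, NetworkError, NodeSet

__all__ = [
    "PowerLawDegrees",
    "PoissonMixtureDegrees",
    "SimulationDesign",
    "EvaluationReport",
    "DESIGNS",
    "sample_degree_sequence",
    "generate_fixed_degree_graph",
    "plant_enrichment",
    "run_design",
    "overlap_study",
]


# ---------------------------------------------------------------------------
# degree models


@dataclass(frozen=True)
class PowerLawDegrees:
    """Discrete power-law degrees: P(k) ~ k**-exponent for k >= min_degree."""

    exponent: float = 4.0
    min_degree: int = 20

    def sample(self, n: int, rng: np.random.Generator, max_degree: int) -> np.ndarray:
        ks = np.arange(self.min_degree, max_degree + 1, dtype=np.float64)
        weights = ks ** (-self.exponent)
        probs = weights / weights.sum()
        return rng.choice(ks.astype(np.int64), size=n, p=probs)


@dataclass(frozen=True)
class PoissonMixtureDegrees:
    """Two-component Poisson mixture: w1*Pois(lam1) + (1-w1)*Pois(lam2)."""

    lam1: float = 40.0
    lam2: float = 100.0
    w1: float = 0.99

    @property
    def mean(self) -> float:
        return self.w1 * self.lam1 + (1.0 - self.w1) * self.lam2

    def sample(self, n: int, rng: np.random.Generator, max_degree: int) -> np.ndarray:
        lam = np.where(rng.random(n) < self.w1, self.lam1, self.lam2)
        degs = rng.poisson(lam)
        return np.minimum(degs, max_degree).astype(np.int64)


DegreeModel = Union[PowerLawDegrees, PoissonMixtureDegrees]


def sample_degree_sequence(
    model: DegreeModel,
    n_nodes: int,
    rng: Union[int, np.random.Generator],
    mode: str = "undirected",
):
    """Sample a degree sequence (undirected) or an (out, in) pair (directed).

    Undirected sequences are forced to an even sum by resampling one
    entry; directed out/in sequences are balanced by incrementing random
    entries of the smaller-sum sequence.  All degrees stay below
    ``n_nodes``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    max_degree = n_nodes - 1
    if mode == "undirected":
        degs = model.sample(n_nodes, rng, max_degree)
        for _ in range(1000):
            if degs.sum() % 2 == 0:
                return degs
            i = rng.integers(n_nodes)
            degs[i] = model.sample(1, rng, max_degree)[0]
        raise NetworkError("could not reach an even degree sum")
    if mode == "directed":
        out = model.sample(n_nodes, rng, max_degree)
        inn = model.sample(n_nodes, rng, max_degree)
        diff = int(out.sum() - inn.sum())
        smaller = inn if diff > 0 else out
        idx = rng.integers(0, n_nodes, size=abs(diff))
        np.add.at(smaller, idx, 1)
        if smaller.max() >= n_nodes:
            raise NetworkError("degree exceeded n_nodes - 1 while balancing sums")
        return out, inn
    raise NetworkError(f"unsupported mode {mode!r} for degree sampling")


# ---------------------------------------------------------------------------
# fixed-degree random graphs


def _simplify_directed(arcs: np.ndarray, n: int, rng: np.random.Generator,
                       max_iter: int) -> np.ndarray:
    """Degree-preserving target swaps until no self-loops or parallel arcs."""
    m = len(arcs)
    arcs = arcs.copy()
    present: set[int] = set()
    bad: list[int] = []
    for e in range(m):
        u, v = int(arcs[e, 0]), int(arcs[e, 1])
        key = u * n + v
        if u == v or key in present:
            bad.append(e)
        else:
            present.add(key)
    iters = 0
    while bad:
        e1 = bad[-1]
        u, v = int(arcs[e1, 0]), int(arcs[e1, 1])
        if u != v and (u * n + v) not in present:
            # earlier swaps freed this slot
            present.add(u * n + v)
            bad.pop()
            continue
        while True:
            iters += 1
            if iters > max_iter:
                raise NetworkError(
                    "could not simplify directed multigraph within budget"
                )
            e2 = int(rng.integers(m))
            x, y = int(arcs[e2, 0]), int(arcs[e2, 1])
            if x * n + y not in present:  # defective or same arc
                continue
            if u == y or x == v:
                continue
            if (u * n + y) in present or (x * n + v) in present:
                continue
            break
        present.discard(x * n + y)
        present.add(u * n + y)
        present.add(x * n + v)
        arcs[e1, 1] = y
        arcs[e2, 1] = v
        bad.pop()
    return arcs


def _simplify_undirected(pairs: np.ndarray, n: int, rng: np.random.Generator,
                         max_iter: int) -> np.ndarray:
    """Degree-preserving double-edge swaps until the graph is simple."""
    m = len(pairs)
    pairs = pairs.copy()

    def key(a: int, b: int) -> int:
        return min(a, b) * n + max(a, b)

    present: set[int] = set()
    bad: list[int] = []
    for e in range(m):
        u, v = int(pairs[e, 0]), int(pairs[e, 1])
        if u == v or key(u, v) in present:
            bad.append(e)
        else:
            present.add(key(u, v))
    iters = 0
    while bad:
        e1 = bad[-1]
        u, v = int(pairs[e1, 0]), int(pairs[e1, 1])
        if u != v and key(u, v) not in present:
            # earlier swaps freed this slot
            present.add(key(u, v))
            bad.pop()
            continue
        while True:
            iters += 1
            if iters > max_iter:
                raise NetworkError(
                    "could not simplify undirected multigraph within budget"
                )
            e2 = int(rng.integers(m))
            x, y = int(pairs[e2, 0]), int(pairs[e2, 1])
            if key(x, y) not in present:
                continue
            if rng.random() < 0.5:
                x, y = y, x
            # propose {u, x} and {v, y}
            if u == x or v == y:
                continue
            k1, k2 = key(u, x), key(v, y)
            if k1 == k2 or k1 in present or k2 in present:
                continue
            break
        present.discard(key(x, y))
        present.add(k1)
        present.add(k2)
        pairs[e1] = (u, x)
        pairs[e2] = (v, y)
        bad.pop()
    return pairs


def generate_fixed_degree_graph(
    degrees,
    mode: str,
    rng: Union[int, np.random.Generator],
    max_iter_factor: int = 200,
) -> Network:
    """Random simple graph realising the degree sequence exactly.

    ``degrees`` is a single sequence for undirected graphs or an
    ``(out, in)`` pair for directed graphs.  Stub matching produces a
    random multigraph; degree-preserving swaps then remove self-loops
    and parallel links, so the realised degrees equal the request.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    attempts = 50
    if mode == "directed":
        out, inn = (np.asarray(d, dtype=np.int64) for d in degrees)
        if out.sum() != inn.sum():
            raise NetworkError("out- and indegree sums differ")
        n = len(out)
        out_stubs = np.repeat(np.arange(n), out)
        in_stubs = np.repeat(np.arange(n), inn)
        for _ in range(attempts):
            shuffled = in_stubs.copy()
            rng.shuffle(shuffled)
            arcs = np.column_stack([out_stubs, shuffled])
            try:
                arcs = _simplify_directed(arcs, n, rng, max_iter_factor * len(arcs))
            except NetworkError:
                continue  # rare deadlock: restart from a fresh matching
            labels = [str(i) for i in range(n)]
            return Network(labels, arcs, np.empty((0, 2), dtype=np.int64),
                           "directed")
        raise NetworkError("could not realize the directed degree sequence")
    if mode == "undirected":
        degs = np.asarray(degrees, dtype=np.int64)
        if degs.sum() % 2:
            raise NetworkError("odd degree sum is not graphical")
        n = len(degs)
        stubs = np.repeat(np.arange(n), degs)
        for _ in range(attempts):
            shuffled = stubs.copy()
            rng.shuffle(shuffled)
            pairs = shuffled.reshape(-1, 2)
            try:
                pairs = _simplify_undirected(pairs, n, rng,
                                             max_iter_factor * len(pairs))
            except NetworkError:
                continue
            edges = np.sort(pairs, axis=1)
            labels = [str(i) for i in range(n)]
            return Network(labels, np.empty((0, 2), dtype=np.int64), edges,
                           "undirected")
        raise NetworkError("could not realize the undirected degree sequence")
    raise NetworkError(f"unsupported mode {mode!r} for graph generation")


# ---------------------------------------------------------------------------
# planted enrichments


def _cross_mask(net: Network, in_a: np.ndarray, in_b: np.ndarray) -> np.ndarray:
    if net.mode == "undirected":
        e = net.undirected_edges
        one = in_a[e[:, 0]] & in_b[e[:, 1]]
        two = in_a[e[:, 1]] & in_b[e[:, 0]]
        return one | two
    arcs = net.arcs
    return in_a[arcs[:, 0]] & in_b[arcs[:, 1]]


def plant_enrichment(
    net: Network,
    A: NodeSet,
    B: NodeSet,
    delta: Union[int, float],
    rng: Union[int, np.random.Generator],
) -> tuple[Network, int]:
    """Change n_AB by adding or removing random cross links.

    ``delta`` is either a signed integer (the exact change requested) or
    a signed proportion in (-1, 1), realised as
    ``sign * max(1, round(|delta| * n_AB))``.  Returns the modified
    network and the realised signed change of n_AB; links elsewhere are
    untouched.  Candidate links are chosen so each contributes exactly
    one to n_AB (in undirected networks, edges inside A intersect B
    would count twice and are excluded), hence the change is exact.
    """
    if net.mode == "mixed":
        raise NetworkError("plant_enrichment expects a directed or undirected network")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a_idx = net.indices(A.members)
    b_idx = net.indices(B.members)
    n = net.n_nodes
    in_a = np.zeros(n, dtype=bool)
    in_b = np.zeros(n, dtype=bool)
    in_a[a_idx] = True
    in_b[b_idx] = True

    mask = _cross_mask(net, in_a, in_b)
    if net.mode == "undirected":
        both = (in_a & in_b)
        e = net.undirected_edges
        nab = int((in_a[e[:, 0]] & in_b[e[:, 1]]).sum()
                  + (in_a[e[:, 1]] & in_b[e[:, 0]]).sum())
    else:
        nab = int(mask.sum())

    if isinstance(delta, float) and not float(delta).is_integer():
        magnitude = max(1, round(abs(delta) * nab))
        sign = 1 if delta > 0 else -1
    else:
        magnitude = abs(int(delta))
        sign = 1 if delta >= 0 else -1
    if magnitude == 0:
        return net, 0

    directed = net.mode == "directed"
    edges = net.arcs if directed else net.undirected_edges

    if sign > 0:
        # candidate new links, each adding exactly 1 to n_AB
        aa, bb = np.meshgrid(a_idx, b_idx, indexing="ij")
        cand = np.column_stack([aa.ravel(), bb.ravel()])
        cand = cand[cand[:, 0] != cand[:, 1]]
        if not directed:
            # exclude pairs with both endpoints in A intersect B (would add 2)
            in_both0 = in_a[cand[:, 0]] & in_b[cand[:, 0]]
            in_both1 = in_a[cand[:, 1]] & in_b[cand[:, 1]]
            cand = cand[~(in_both0 & in_both1)]
            cand = np.sort(cand, axis=1)
        keys = cand[:, 0] * n + cand[:, 1]
        existing = set((edges[:, 0] * n + edges[:, 1]).tolist())
        fresh = np.array([k not in existing for k in keys.tolist()])
        cand = cand[fresh]
        cand = np.unique(cand, axis=0)
        if len(cand) < magnitude:
            raise NetworkError(
                f"cannot add {magnitude} links between {A.name!r} and {B.name!r}: "
                f"only {len(cand)} free cross pairs"
            )
        pick = rng.choice(len(cand), size=magnitude, replace=False)
        new_edges = np.concatenate([edges, cand[pick]], axis=0)
        realized = magnitude
    else:
        removable = np.flatnonzero(mask)
        if not directed:
            e = net.undirected_edges
            twice = in_a[e[:, 0]] & in_b[e[:, 0]] & in_a[e[:, 1]] & in_b[e[:, 1]]
            removable = np.flatnonzero(mask & ~twice)
        if len(removable) < magnitude:
            raise NetworkError(
                f"cannot remove {magnitude} links between {A.name!r} and "
                f"{B.name!r}: only {len(removable)} removable"
            )
        pick = rng.choice(removable, size=magnitude, replace=False)
        keep = np.ones(len(edges), dtype=bool)
        keep[pick] = False
        new_edges = edges[keep]
        realized = -magnitude

    if directed:
        out = Network(net.nodes, new_edges, np.empty((0, 2), dtype=np.int64),
                      "directed")
    else:
        out = Network(net.nodes, np.empty((0, 2), dtype=np.int64), new_edges,
                      "undirected")
    return out, realized


# ---------------------------------------------------------------------------
# designs


@dataclass(frozen=True)
class SimulationDesign:
    """Full parameterisation of one benchmark design."""

    design_id: str
    mode: str
    degree_model: DegreeModel
    n_nodes: int = 1000
    n_sets: int = 50
    set_size: tuple[int, int] = (50, 100)
    n_planted: int = 200
    effect_range: tuple[float, float] = (0.10, 0.50)
    # S3-style overlap study parameters
    overlap_grid: Optional[tuple[int, ...]] = None
    overlap_set_size: int = 50
    n_h0: int = 1000
    n_h1: int = 1000
    added_links: int = 35

    def __post_init__(self):
        if self.overlap_grid is None:
            n_pairs = self.n_sets * (self.n_sets - 1)
            if self.mode == "undirected":
                n_pairs //= 2
            if not self.n_planted < n_pairs:
                raise NetworkError("planted-enrichment count must be < total pairs")
        lo, hi = self.effect_range
        if not (0.0 < lo <= hi <= 1.0):
            raise NetworkError("effect-size bounds must lie within (0, 1]")


DESIGNS: dict[str, SimulationDesign] = {
    "S1": SimulationDesign("S1", "directed", PowerLawDegrees(), n_planted=200),
    "S2": SimulationDesign("S2", "directed", PoissonMixtureDegrees(), n_planted=200),
    "S3": SimulationDesign(
        "S3", "directed", PoissonMixtureDegrees(),
        overlap_grid=tuple(range(0, 55, 5)),
    ),
    "S4": SimulationDesign("S4", "undirected", PowerLawDegrees(), n_planted=100),
    "S5": SimulationDesign("S5", "undirected", PoissonMixtureDegrees(), n_planted=100),
}


@dataclass(frozen=True)
class EvaluationReport:
    """Scored outcome of one benchmark replicate."""

    design_id: str
    seed: int
    alpha: float
    sensitivity: float
    specificity: float
    auc: float
    r1: float
    r5: float
    ks_pvalue: float
    table: pd.DataFrame = field(repr=False, compare=False)

    def metrics(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "R1": self.r1,
            "R5": self.r5,
            "ks_pvalue": self.ks_pvalue,
        }

    def summary(self) -> str:
        lines = [
            f"design {self.design_id} (seed {self.seed}, alpha {self.alpha:g}, "
            f"{len(self.table)} tests, {int(self.table['planted'].sum())} planted)",
        ]
        for k, v in self.metrics().items():
            lines.append(f"  {k:12s} {v:.3f}")
        return "\n".join(lines)


def _sample_sets(
    rng: np.random.Generator,
    nodes: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int],
) -> list[NodeSet]:
    lo, hi = size_range
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(nodes), size=size, replace=False)
        sets.append(NodeSet(f"set{i + 1:02d}", [nodes[j] for j in members]))
    return sets


def _auc_from_pvalues(pvals: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUC (mid-ranks for ties); score is 1 - p."""
    npos = int(truth.sum())
    nneg = int((~truth).sum())
    if npos == 0 or nneg == 0:
        return float("nan")
    ranks = rankdata(pvals)  # ascending: small p-value = strong evidence
    u_pos = ranks[truth].sum() - npos * (npos + 1) / 2.0
    return 1.0 - u_pos / (npos * nneg)


def evaluate(
    table: pd.DataFrame, design_id: str, seed: int, alpha: float
) -> EvaluationReport:
    """Score a truth-annotated results table (columns p_value, planted)."""
    pvals = table["p_value"].to_numpy()
    truth = table["planted"].to_numpy(dtype=bool)
    h0 = pvals[~truth]
    h1 = pvals[truth]
    sensitivity = float((h1 < alpha).mean()) if len(h1) else float("nan")
    specificity = float((h0 >= alpha).mean()) if len(h0) else float("nan")
    r1 = float((h0 < 0.01).mean() / 0.01) if len(h0) else float("nan")
    r5 = float((h0 < 0.05).mean() / 0.05) if len(h0) else float("nan")
    ks_p = float(kstest(h0, "uniform").pvalue) if len(h0) else float("nan")
    auc = _auc_from_pvalues(pvals, truth) if len(h1) else float("nan")
    return EvaluationReport(
        design_id=design_id, seed=seed, alpha=alpha,
        sensitivity=sensitivity, specificity=specificity, auc=auc,
        r1=r1, r5=r5, ks_pvalue=ks_p, table=table,
    )


def run_design(
    design: Union[str, SimulationDesign],
    seed: int,
    alpha: float = 0.05,
) -> EvaluationReport:
    """Run one replicate of a planted-enrichment benchmark design.

    Generates the network and sets, plants the enrichments, tests every
    ordered (directed) or unordered (undirected) pair of distinct sets,
    and scores sensitivity/specificity at ``alpha``, rank-based AUC,
    the R1/R5 rejection ratios and the Kolmogorov-Smirnov uniformity
    p-value of the true-null p-values.  Fully reproducible from ``seed``.
    """
    if isinstance(design, str):
        design = DESIGNS[design]
    if design.overlap_grid is not None:
        raise NetworkError(
            f"design {design.design_id} is an overlap study; use overlap_study()"
        )
    rng = np.random.default_rng(seed)
    directed = design.mode == "directed"
    degrees = sample_degree_sequence(
        design.degree_model, design.n_nodes, rng, mode=design.mode
    )
    net = generate_fixed_degree_graph(degrees, design.mode, rng)
    sets = _sample_sets(rng, net.nodes, design.n_sets, design.set_size)

    if directed:
        pairs = [(i, j) for i in range(len(sets)) for j in range(len(sets)) if i != j]
    else:
        pairs = [(i, j) for i in range(len(sets)) for j in range(i + 1, len(sets))]
    planted_rows = rng.choice(len(pairs), size=design.n_planted, replace=False)
    planted_set = set(int(r) for r in planted_rows)

    lo, hi = design.effect_range
    realized: dict[int, int] = {}
    for row in sorted(planted_set):
        i, j = pairs[row]
        u = rng.uniform(lo, hi)
        sign = 1 if rng.random() < 0.5 else -1
        try:
            net, d = plant_enrichment(net, sets[i], sets[j], sign * u, rng)
        except NetworkError:
            # infeasible direction (e.g. nothing to remove): flip the coin
            net, d = plant_enrichment(net, sets[i], sets[j], -sign * u, rng)
        realized[row] = d

    results = test_pairs(net, sets, pairs, alpha=alpha)
    table = pd.DataFrame(
        {
            "set_A": [r.set_a for r in results],
            "set_B": [r.set_b for r in results],
            "n_AB": [r.nab for r in results],
            "expected_n_AB": [r.expected for r in results],
            "p_value": [r.pvalue for r in results],
            "conclusion": [r.conclusion for r in results],
            "planted": [row in planted_set for row in range(len(pairs))],
            "realized_delta": [realized.get(row, 0) for row in range(len(pairs))],
        }
    )
    return evaluate(table, design.design_id, seed, alpha)


def overlap_study(
    design: Union[str, SimulationDesign],
    seed: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sensitivity/specificity of the test as set overlap grows.

    For each overlap level o in the design's grid, draws pairs of sets
    with |A| = |B| = 50 and |A intersect B| = o from a single
    fixed-degree network, and runs ``n_h0`` unmodified tests plus
    ``n_h1`` tests in which 35 extra arrows run from A to B.  The
    35-arrow modification is applied through the exact count update
    (n_AB, o_A, i_B and i_V each grow by 35), which is equivalent to
    materialising 35 new distinct cross arcs.  Returns one row per
    level with the Jaccard index, sensitivity and specificity.
    """
    if isinstance(design, str):
        design = DESIGNS[design]
    if design.overlap_grid is None:
        raise NetworkError(f"design {design.design_id} has no overlap grid")
    rng = np.random.default_rng(seed)
    out_deg, in_deg = sample_degree_sequence(
        design.degree_model, design.n_nodes, rng, mode="directed"
    )
    net = generate_fixed_degree_graph((out_deg, in_deg), "directed", rng)
    adj = net.adjacency(dense=True).astype(bool)
    outdeg = adj.sum(axis=1)
    indeg = adj.sum(axis=0)
    i_v = int(indeg.sum())
    n_nodes = net.n_nodes
    size = design.overlap_set_size
    extra = design.added_links

    rows = []
    for o in design.overlap_grid:
        pvals_h0 = np.empty(design.n_h0)
        pvals_h1 = np.empty(design.n_h1)
        for rep in range(design.n_h0 + design.n_h1):
            chosen = rng.choice(n_nodes, size=2 * size - o, replace=False)
            a_idx = chosen[:size]
            b_idx = np.concatenate([chosen[:o], chosen[size:]])
            o_a = int(outdeg[a_idx].sum())
            i_b = int(indeg[b_idx].sum())
            nab = int(adj[np.ix_(a_idx, b_idx)].sum())
            if rep < design.n_h0:
                params = NullParams(n=o_a, K=i_b, N=i_v)
                pvals_h0[rep] = two_sided_pvalue(nab, params)
            else:
                params = NullParams(n=o_a + extra, K=i_b + extra, N=i_v + extra)
                pvals_h1[rep - design.n_h0] = two_sided_pvalue(nab + extra, params)
        rows.append(
            {
                "overlap": int(o),
                "jaccard": o / (2 * size - o),
                "sensitivity": float((pvals_h1 < alpha).mean()),
                "specificity": float((pvals_h0 >= alpha).mean()),
                "n_tests": design.n_h0 + design.n_h1,
            }
        )
    return pd.DataFrame(rows)
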