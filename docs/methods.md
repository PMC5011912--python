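# Methods

## The null model

The test treats the links of a fixed network as exchangeable stubs.
In a directed network the o_A arrows leaving set A are viewed as a
sample without replacement from the i_V arrows of the network; an arrow
is a "success" when it enters set B (i_B of them do).  Absent any
preferential connection between A and B, the cross-count N_AB is then
hypergeometric with parameters (n = o_A, K = i_B, N = i_V) and null
mean mu0 = o_A i_B / i_V.  The undirected version replaces arrow
counts by total degrees: (n = d_A, K = d_B, N = d_V), where d_S sums
node degrees over S and d_V is twice the edge count.  A partially
directed network is always analysed through its directed expansion
(each undirected edge becomes two opposite arrows); no separate mixed
statistic exists, and on an all-undirected network the expanded
directed test coincides exactly with the undirected test (asserted in
the suite).

Assumptions worth keeping in mind: the network is simple (self-loops
are rejected rather than dropped, because their stub contribution is
ambiguous; parallel edges are collapsed with a warning), unweighted,
and taken as ground truth — the test conditions on the degree
sequence but not on any other topology.  The null is exact for stub
sampling, and an approximation to the configuration-model conditional
law of N_AB; in practice the difference is small (the simulation
harness measures it).

### Overlapping sets

When A and B intersect in an undirected network, n_AB is defined as the
adjacency-submatrix sum over A x B, so an edge with both endpoints in
A ∩ B counts twice (once per orientation).  This is the only convention
consistent with the stub-sampling story: both stubs of such an edge lie
in the d_A sample and both opposite endpoints lie in B.  Self-pairs
(A = B) are legal and measure within-set connectivity.

## The two-sided p-value

For a discrete statistic, doubling the smaller closed tail,
p1 = 2 min[P0(T ≤ t), P0(T ≥ t)], can exceed 1.  The reported p-value
subtracts the point mass once:

    p = 2 min[ P0(T < t), P0(T > t) ] + P0(T = t),

which is p1 − P0(T = t) and always lies in [0, 1] (an identity the
suite asserts numerically; the p1 variant is kept private).  Ties
between the two strict tails need no tie-break — the formula is
symmetric in that case.  Degenerate parameterisations (o_A = 0,
i_B = 0, or B absorbing every arrow) make the null a point mass and
the formula returns p = 1; batch runs therefore never abort on such
pairs, they simply report "no evidence".

Numerics: log-binomial coefficients via `gammaln`, tails summed over
the support with `logsumexp`, and the *smaller* tail summed directly —
never obtained as one minus the other tail — so far-tail p-values on
large networks (supports of thousands) do not suffer cancellation.
The implementation agrees with exact rational-arithmetic enumeration
to < 1e-10 over the full parameter grid with population N ≤ 30, and
with `scipy.stats.hypergeom` on random parameters.  Below roughly
1e-300 the p-value underflows to 0, which is inconsequential at any
usable significance level.

## Batch testing and multiplicity

Directed/mixed networks test each ordered pair (target → functional);
undirected networks test each unordered pair once, reported with set
names in lexicographic order; rows are deterministic (targets outer,
functionals inner).  Verdicts use raw p-values at the chosen level
alpha (default 0.05), which is how the test's calibration is defined;
a Benjamini–Hochberg adjusted column (`scipy.stats.false_discovery_control`)
is available behind `adjust="bh"` as a reporting convenience and does
not change the verdict column.  Set members absent from the network are
dropped with a warning by default (curated networks rarely cover whole
gene catalogues); an `error` policy is available.

## The simulation harness

The harness emulates enrichment studies on synthetic networks whose
degree structure mimics gene networks; it does not emulate curated
networks' community structure, edge noise or annotation bias, so
passing benchmarks demonstrate calibration and power under the stated
generative conditions, not performance on any particular biological
network.

Degree models (1000 nodes unless overridden):

* power law, P(k) ∝ k^-4 for k ≥ 20 (mean ≈ 30; graph density ≈ 3%);
* Poisson mixture, 0.99·Pois(40) + 0.01·Pois(100) (mean 40.6,
  density ≈ 4%) — a homogeneous network with a 1% fringe of hubs.

Undirected sequences are forced even by resampling one entry; directed
out/in sequences are balanced by incrementing random entries of the
smaller-sum side.  Graphs realise the sequences *exactly*: stubs are
matched uniformly at random and the resulting multigraph is simplified
by degree-preserving swaps (target swaps for arcs, double-edge swaps
for edges) until no self-loop or parallel link remains; if a matching
deadlocks (possible only for degenerate tiny sequences), generation
restarts from a fresh shuffle, up to 50 attempts.

Fifty sets are drawn independently, sizes uniform on {50, …, 100},
members uniform without replacement; overlap between sets arises only
by chance (≈ 4% mean Jaccard at these sizes).  Planted effects change
n_AB for 200 ordered pairs (directed designs) or 100 unordered pairs
(undirected) by delta = max(1, round(u·n_AB)) with u ~ U(0.10, 0.50),
addition vs removal by a fair coin per pair (re-flipped if infeasible,
e.g. nothing to remove); added links are drawn uniformly among free
cross pairs that each contribute exactly +1 to n_AB, so the realised
delta — recorded as ground truth — is exact.  Planting one pair can
incidentally touch other pairs that share nodes; this contamination is
inherent to the design and is visible as null-rejection ratios R1/R5
slightly above 1.

The overlap study (S3) fixes |A| = |B| = 50 and sweeps
|A ∩ B| ∈ {0, 5, …, 50} on one Poisson-mixture directed network,
running 1000 true-null and 1000 alternative tests per level; the
alternative adds 35 arrows from A to B, applied through the exact
count update (t, n, K, N each +35), which is equivalent to
materialising 35 distinct new cross arcs and is cross-checked against
the graph-mutating path in the unit suite.

Scoring: sensitivity and specificity at alpha; rank-based AUC with
mid-ranks for tied p-values (Mann–Whitney convention), scoring by
1 − p; R1 and R5, the ratios of observed to nominal rejections among
true-null tests at 1% and 5%; and the asymptotic one-sample
Kolmogorov–Smirnov p-value for uniformity of the true-null p-values
(applied directly despite the mild discreteness of the statistic,
which is negligible at these support sizes).  Everything is
reproducible from a single integer seed.

## Problem sizes and expected figures

All benchmark checks run the designs at full scale (1000 nodes, 50
sets, 2450 or 1225 tests) and average three replicate seeds; one
replicate takes a few seconds on one CPU.  Typical figures: S1
sensitivity ≈ 0.73, specificity ≈ 0.95, AUC ≈ 0.91; S2 ≈ 0.80 / 0.94 /
0.94; S4 ≈ 0.75 / 0.95 / 0.91; S5 ≈ 0.79 / 0.94 / 0.91; S3 specificity
stays within ±0.02 of 0.95 at every overlap level (pooled over three
sweeps) while sensitivity decays mildly with overlap.  Sensitivity
estimates carry binomial noise of 0.03–0.05 per replicate (100–200
planted pairs), so single-replicate figures scatter accordingly.

## Known limitations

* Weighted networks, multigraphs and hypergraphs are out of scope; edge
  weights are thresholded to presence/absence by the adjacency reader.
* The stub-sampling null conditions only on degrees; strong community
  structure unrelated to the tested sets can inflate cross-counts and
  is read as enrichment, by design.
* The swap-based generator targets the uniform distribution over simple
  graphs with the given degrees but, like all repair-based samplers, is
  not exactly uniform; residual bias is far below the noise floor of
  the reported metrics.
* p-values below ≈ 1e-300 underflow to zero rather than being reported
  in log space.
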