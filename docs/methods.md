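# Methods

`grnbench` benchmarks statistical reverse-engineering of transcriptional
regulatory networks in *S. cerevisiae*-style settings. This note records
the models, conventions and numerical choices behind each stage, and what
the synthetic tests do and do not establish about real data.

## Gold-standard construction

Direct regulatory interactions are defined as the intersection of two
independent lines of evidence for each TF→gene pair:

* **Regulatory evidence** — the gene responds when the TF is deleted.
  The input is a per-mutant table of differential-expression p-values
  with response signs. Benjamini–Hochberg step-up is applied *within
  each mutant profile* at a 5% FDR (each deletion experiment is its own
  family of hypotheses); survivors become signed mutant→gene edges. The
  sign convention follows the deletion logic: a target that goes down
  when its regulator is removed is recorded as excitatory.
* **Binding evidence** — the TF physically binds the gene's promoter.
  The input is a TF→gene score table with a binding p-value and an
  evolutionary-conservation count (0–2 related *Saccharomyces* species).
  Three nested stringency levels are standard: p ≤ 0.001 with
  conservation in 2 species (conservative), p ≤ 0.005 with conservation
  in 1 (intermediate), p ≤ 0.005 unconditionally (liberal).

Either line alone is insufficient — knockout responses can be indirect,
binding can be non-functional — so the gold standard keeps a pair only
when both agree, taking the sign from the regulatory side.

Overlap significance is an upper-tail hypergeometric test: population =
candidate TF→gene pairs, successes = regulatory edges, draws = binding
edges, observed = intersection size, with the tail summed in log space.
The candidate-pair universe is not canonical; we default to
(TFs shared by both sources) × (shared genes − 1) and expose it as an
explicit argument, since the choice changes the p-value and published
analyses rarely state it.

## Statistical inference approaches

Eighteen approaches are benchmarked (`STANDARD_APPROACHES`): two
association tests × (bivariate analysis with three thresholding rules, or
GLL with conditioning up to 1, 2 or 3 genes × AND/OR assembly). All
output *undirected* networks; orientation is out of scope.

**Fisher's Z.** The partial correlation r of genes i, j given a set S is
read off the inverse of the sample correlation matrix of {i, j} ∪ S;
z = ½·ln((1+r)/(1−r)) and √(n−|S|−3)·|z| is referred to the standard
normal, two-sided. r is clamped to ±(1−10⁻⁷) so perfectly correlated
replicate pairs stay finite; a numerically singular submatrix yields an
unreliable result with p = 1.

**G².** Expression is first discretized per gene: standardize to mean 0
and sd 1 (n−1 denominator; constant genes map entirely to the middle
category) and cut at ±1 into low/mid/high, with the boundary values
±1 inclusive in the middle category. The statistic is 2·Σ O·ln(O/E)
over the 3×3 table within each joint stratum of the conditioning genes;
zero observed cells contribute nothing; df is fixed at 4 per non-empty
stratum with no adjustment for zero margins, a deliberate convention that
keeps edge counts bit-for-bit reproducible (margin-adjusted df is a
defensible alternative that shifts results slightly). A G² result is
*unreliable* when n < 5 × (9 × non-empty strata) — fewer than five
samples per cell on average — and unreliable tests are never allowed to
declare independence, the conservative retention rule from the local
causal-discovery literature. With ternary data and k conditioning genes
this means conditional elimination effectively requires n ≥ 135·3^(k−1).

**Bivariate screening** computes all pairwise tests once. The alpha rule
keeps pairs with p ≤ 0.05 (symmetric, no assembly needed). The FDR rule
runs Benjamini–Hochberg within each gene's row of m−1 p-values, which is
asymmetric, and therefore requires AND (mutual) or OR (either)
symmetrization.

**GLL neighborhood search** (`gll_neighbors`) is an interleaved
inclusion/elimination local search in the HITON-PC style: candidates
enter in descending order of unconditional association strength (ties
broken by gene identifier, fixing determinism); after each admission
every current member X is re-examined and removed on the first reliable
test of independence given any subset of the other members with size
≤ max_k, the empty set included. "Conditioning on k genes" is read as
subsets *up to* size k, the GLL convention. Per-gene searches are
independent, so any execution order yields the same network; assembly
uses the AND or OR rule.

## Accuracy evaluation

The candidate universe for confusion counting defaults to
gold regulators × gold universe (minus self-pairs) and is injectable,
because the negative space is the least standardized part of published
network evaluations. An inferred unordered pair {a, b} predicts every
directed candidate it is compatible with — both directions when both
genes are regulators. Core metrics with a 0/0 denominator are carried as
NaN with an explicit `undefined` flag, never imputed to zero.

Combined metrics are Euclidean distances from the ideal point for an
antagonistic pair — √((1−m1)² + (1−m2)²) for sensitivity/specificity,
PPV/NPV and recall/precision — ranging 0 (optimal) to √2 (worst).
Table summaries average the per-cell distances without intermediate
rounding and round the averages to 2 decimals. When the inputs are
metric pairs already printed at 2 decimals, averages computed this way
can differ by 0.01 from averages of the printed per-cell distances; the
bundled reference tables reproduce all benchmark averages this package
asserts under either convention.

Network-level significance is the upper-tail hypergeometric probability
of recovering ≥ tp gold edges among tp+fp predictions, Benjamini–Hochberg
adjusted across the whole benchmarking grid (gold standards × approaches
× datasets share one adjustment). A cloud of (sensitivity, specificity)
results is summarized by the ROC staircase through its Pareto-optimal
points, anchored at (0,0) and (1,1), with AUROC by the trapezoid rule and
a one-sided p-value for AUROC > 0.5 from the Hanley–McNeil normal
approximation given caller-supplied effective positive/negative counts
(published analyses report AUROC p-values without stating a method;
Hanley–McNeil is our choice).

## TF connectivity vs sub-network accuracy

Per-TF sub-network metrics restrict the confusion universe to candidates
with that TF as regulator. The hypothesis that hub TFs are easier to
reconstruct is tested with Spearman correlation between TF connectivity
(degree in the gold or inferred network) and the combined-distance
metric, against an exact permutation null: gene identifiers of the
selected network are relabeled uniformly at random with topology fixed
(TFs are not independent observations, so a parametric null would be
invalid). By default connectivity *and* per-TF metrics are recomputed
after each relabeling; a documented switch permutes only the
connectivity vector. The recompute null is conservative when relabeling
leaves few TFs with defined metrics, because small-support correlations
of ±1 then occur often in the null. The p-value is add-one smoothed,
(1 + hits)/(n_perm + 1), two-sided on |rho| — so its floor is
1/(n_perm + 1) and p = 0 is impossible.

## Synthetic data generator

The generator defines the conditions under which the pipeline is tested.

* **Ground truth**: a directed acyclic TF→gene network with exactly
  round(n_tfs · mean_out_degree) edges placed by preferential attachment
  on both endpoints, giving the hub-heavy degree profile of real
  transcription networks. TF→TF edges respect a fixed ordering, so the
  graph is acyclic and gene identifiers sort topologically. Signs are
  fair coins; |weights| are uniform on [0.5, 1.5].
* **Expression**: linear-Gaussian structural equations evaluated in
  topological order, x_g = Σ w·x_parent + ε_g. Exogenous roots receive
  unit-variance innovations (so the scale is "standardized" and signal
  propagates); regulated genes receive ε ~ N(0, noise_sd²), default
  noise_sd 0.3. Knockouts clamp the deleted gene to −3 on this scale
  rather than deleting the row, as in real mutant arrays.
* **Designs**: `replicates` (i.i.d. draws), `environment_time` (a
  random-phase sinusoidal condition signal feeds half the TFs),
  `compendium` (each sample clamps one random gene — a semi-perturbation
  mixture), `perturbation` (samples cycle through TF knockouts). The
  perturbed gene is recorded in sample annotations but never shown to
  the inference methods.
* **Knockout DE calls**: Welch t-tests of n_mut knockout vs n_wt
  wild-type replicates per gene (defaults 20/20, comparable power to a
  moderated test at these sample sizes); degenerate variance ⇒ p = 1.
* **Binding calls**: the liberal set keeps true edges with probability
  1−fnr and adds false TF→gene pairs with probability fpr; the
  intermediate and conservative sets thin it with survival probabilities
  0.95 (true) / 0.5 (false) per step, so stringency preferentially prunes
  spurious calls and the three sets are nested by construction.

Every operation is a pure function of its arguments and seed.

What the generator deliberately omits: microarray noise structure (dye
bias, probe effects, batch), feedback loops, time-course dynamics beyond
the smooth latent signal, and indirect-effect cascades of real deletion
compendia. Passing tests therefore demonstrate correctness of the
statistical machinery under a faithful linear-Gaussian world, not
expected accuracy on real expression data, where published benchmarks
find whole-network reconstruction much harder.

## Calibration tests and problem sizes

The test suite checks, at sizes chosen to keep the default run fast on a
single CPU: type-I error of both association tests near α on 1,000 null
simulations (n = 200 continuous / 300 ternary); agreement of GLL with an
exhaustive d-separation oracle over 100 seeded 8-node worlds at n = 10⁴,
measured over pairwise adjacency decisions (≥95% required; exact
whole-skeleton equality has an irreducible failure rate at α = 0.05,
since each admitted non-adjacent sibling pair is retained with
probability ≈ α by a single effective separator test shared by both
assembly directions). These oracle trials use unit innovation variance
throughout — the canonical SEM of the constraint-based literature —
because sub-unit child noise creates near-deterministic sibling
relations that mask true edges from any conditional-independence method,
a known limitation rather than a tunable. Further checks: hypergeometric
p-values against brute-force enumeration (universes ≤ 30), Pareto
staircase invariants, permutation-test floor and null calibration
(50 exchangeable instances, n_perm = 99), and end-to-end recovery on a
low-noise 50-gene, 5-TF world (noiseless binding, 25+25 knockout
replicates, 250 perturbation samples) with sensitivity > 0.8 against the
true skeleton. The suite also runs the full benchmark grid once at its
default size (30 genes, 5 TFs, 4 designs, all 18 approaches, 3 gold
standards, n_perm = 50 — under a minute on one CPU) and asserts
byte-identical reruns on a reduced grid (15 genes, 3 approaches,
n_perm = 20).

## Known limitations

* G² df and reliability conventions are one defensible choice among
  several; alternatives shift edge counts at small n.
* The hypergeometric universe and the AUROC p-value method are package
  choices where published practice is unstated; both are injectable or
  documented above.
* Near-deterministic regulatory relations (child noise ≪ parent signal)
  degrade conditional-independence tests; the generator can produce such
  regimes at small noise_sd.
* The permutation null with full metric recomputation is conservative on
  sparse networks (see above); the vector-permutation variant is
  available where a sharper null on the observed configuration is wanted.
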