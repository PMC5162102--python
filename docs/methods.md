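# Methods

## Null model

The unit of data is a binary alteration matrix `X ∈ {0,1}^{n×m}` (genes ×
tumors). All tests in the package are exact tail tests against a null
model of independent Bernoulli alterations with tumor-specific
probabilities `p_ij`, estimated from the margins of `X`.

Two estimators are provided.

**Homogeneous (binomial).** `p_ij = x_i· / m` for every tumor. This is
the maximum-likelihood estimate under the constraint that per-gene
expected counts match observed counts; per-tumor counts are ignored. It
is kept as the comparator whose failure motivates the package: on
cohorts with dispersed tumor loads it is strongly anti-conservative for
co-occurrence and conservative for exclusivity.

**Heterogeneous (maximum entropy).** Maximize
`H(p) = −Σ p log p + (1−p) log(1−p)` subject to `Σ_j p_ij = x_i·` and
`Σ_i p_ij = x_·j`. Entropy rather than likelihood is maximized because
the n·m-parameter likelihood would simply reproduce `X` itself. The
optimum has the logistic form `p_ij = 1/(1 + e^{μ_i + λ_j})`; genes with
equal row sums share a `μ`, tumors with equal column sums share a `λ`,
so the effective dimension is the number of *distinct* margin values.

The fit minimizes the convex dual
`F(μ,λ) = Σ_ij log(1 + e^{−(μ_i+λ_j)}) + Σ_i μ_i x_i· + Σ_j λ_j x_·j`,
whose gradient components are exactly the marginal residuals.
Implementation details:

- all-zero / all-one rows and columns are peeled off iteratively before
  the fit (their dual parameters diverge) and assigned exact 0/1
  probabilities, with the remaining margins decremented accordingly;
- L-BFGS from the deterministic start `μ_i = −logit(x_i·/m)`, `λ_j = 0`
  does most of the work; because the dual has a flat gauge direction
  (`μ+c, λ−c`), L-BFGS can stall with residuals just above tolerance on
  large matrices, so the fit finishes with damped alternating Newton
  sweeps — with one side fixed, each shared parameter solves an
  independent monotone 1-D margin equation;
- convergence is declared when the largest absolute marginal residual is
  below `tol` (default 1e-4, in units of expected alteration counts); a
  fit that cannot reach it raises with the residual achieved;
- stratified estimation fits each tumor subgroup separately and
  concatenates the per-stratum probability matrices, so margins are
  matched within every subgroup. The tests consume the concatenated
  matrix unchanged — stratification needs no logic downstream.

## Test statistics

For an independent gene pair the overlap count is Poisson-binomial with
per-tumor parameters `p_1j p_2j`. The pmf is computed by the O(n·k)
dynamic-programming convolution (fold in one Bernoulli at a time) in
double precision; no approximation is used at any cohort size shipped
here, and tails include the observed point (the conservative discrete
convention). Group statistics use per-tumor event probabilities:
coverage `1 − Π(1−p_ij)`, exclusivity `Σ_i p_ij Π_{k≠i}(1−p_kj)`,
impurity = coverage − exclusivity (exactly `p_1j p_2j` for pairs).
Coverage and exclusivity are upper-tail tests, impurity lower-tail;
impurity is the default group statistic.

## Multiple testing

Poisson-binomial p-values are discrete: each test attains only the
values `{tail(k) : k = 0..n}`, and pooled null p-values skew towards 1,
making plain Benjamini-Hochberg needlessly conservative. The discrete
variant implemented here replaces the BH null-mass estimate `count·t` at
threshold `t` by `Σ_i max{s ∈ support_i : s ≤ t}` — the exact null
probability that test *i* rejects at `t` — and runs the usual step-up
minimization over the observed p-values as candidate thresholds. Because
each term is at most `t`, the resulting q-values are bounded above by the
BH q-values (tested element-wise), while tests that can never reach a
threshold contribute nothing. The proportion of true nulls is not
re-estimated. Supports are grouped before summation since margin
parameter sharing makes many tests share a support.

## Synthetic cohorts

The generator reproduces the two marginal features that break i.i.d.
tests, without any dependence between genes:

- **gene frequencies**: truncated power law with density `∝ f^−1.8` on
  [0.01, 0.5] — few frequent drivers, many rare passengers;
- **tumor loads**: log-normal with coefficient of variation 0.8 —
  strongly over-dispersed, as in real exomes; loads are scaled and
  largest-remainder-rounded so both degree sequences share one total.

Defaults are 600 genes × 800 tumors, sized so that roughly 120 genes
pass the convention of testing only genes with ≥ 50 alterations (rarer
genes still inform the background fit). A matrix with *exactly* these
margins is realized as a bipartite configuration model: random stub
pairing followed by checkerboard swaps that repair duplicate edges in
O(1) each while preserving both margins; rejection is declared after
`10^4·|E|` failed swap attempts. Explicit degree sequences are accepted
for users who have real cohort margins.

Planted positives are calibrated against the null itself: linear
pinball-loss quantile regression of a pair statistic on pair coverage
(impurity proportion for exclusive pairs, overlap count for co-occurring
ones), with binned empirical quantiles as fallback. Planted exclusive
pairs must fall below the 1st-percentile impurity prediction at their
coverage; co-occurring pairs above the 99th-percentile overlap. Gene
sets are planted by sampling a coverage fraction from a truncated normal
(mean 0.4, sd 0.2, on [0.2, 0.8]), drawing per-gene counts from the
empirical frequency distribution of testable genes until they sum to the
coverage (resampling until the set size lands in [3, 6]; the last count
is truncated to fit), laying the genes over disjoint tumor blocks, and
then adding impure alterations — extra hits in already covered tumors,
targeted proportionally to tumor load — until a prescribed fraction
{0.02, 0.05, 0.08} of covered tumors is impure.

**Where planted alterations go matters.** Covered tumors are selected by
systematic probability-proportional-to-size sampling with inclusion
probabilities given by the logistic tumor profile of a hypothetical null
gene of equal frequency (`null_gene_profile`: solve the 1-D margin
equation against the fitted `λ_j`). Naive weighted sampling without
replacement flattens the load bias for large samples, which makes a
planted gene marginally *distinguishable* from a null gene of the same
frequency — and the refitted background then reports phantom
exclusivities between planted and null genes. Matching the placement to
the model's own profile removes that artifact while keeping the planted
sets genuinely exclusive.

What the generator does **not** emulate: genomic segment structure
(neighboring genes with correlated copy-number calls), alteration-type
composition (mutation vs amplification vs deletion), subtype strata, or
measurement noise. Passing tests on these cohorts therefore demonstrate
correct behavior under margin heterogeneity — the failure mode the
method targets — not robustness to correlated calls or calling errors.

## Benchmark design

`run_benchmark` plants positive gene sets in seeded null cohorts, picks
negative sets of independent genes frequency-matched within ±10%
(band doubled on failure), estimates the background on the complete
matrix including planted genes, and reports false/true positive rates
over a significance grid for both background models, averaged over
replicates. The shipped scale is 3 data sets × 30 positive + 30 negative
groups; the full 10 × 100 + 100 design is available behind a flag. With
90 negative groups a perfectly calibrated test still rejects
`Binomial(90, α)` negatives, so calibration assertions allow two
binomial standard errors above `α`.

## De novo gene-set detection

1. **Graph**: pairwise exclusivity results are corrected with the
   discrete FDR and genes joined by an edge at q ≤ 0.10 — permissive on
   purpose, so borderline pairs are not lost before grouping.
2. **Weights**: each edge gets
   `w_uv = s_uv · (1 − √(d_u d_v) / (2|E|))`, floored at 0.01, where `d`
   are degrees in the exclusivity graph and
   `s_uv = min(1, −log10 q_uv / 3)`. The degree factor discounts edges
   that random graphs with the same degree sequence would produce anyway
   (edges of promiscuously exclusive genes say little about set
   membership). The geometric mean is used deliberately: a raw degree
   product can exceed `2|E|` in small graphs and would zero out exactly
   the edges inside densely connected groups. The strength factor keeps
   barely-significant edges from outranking firmly established ones.
3. **Clustering**: overlapping correlation clustering by seeded local
   search over must-link atoms (user-declared groups — e.g. genes on one
   copy-number segment, or the mutation and copy-number events of one
   gene — move as units). The objective is Jaccard-scaled agreement:
   a pair of atoms contributes its summed similarity (edge weight, or a
   non-edge penalty of −0.5) multiplied by the Jaccard overlap of their
   cluster-label sets. The Jaccard scaling is what keeps overlap honest —
   with plain shared-label agreement, assigning every node to one cluster
   per incident edge collects all edge weight penalty-free. Moves are
   single-atom reassignments plus secondary memberships (up to 2) and
   whole-cluster merges; the objective never decreases, and the best of
   5 randomized restarts is kept. Output records the algorithm tag so
   results are never conflated with other clustering procedures.
4. **Validation**: every candidate is tested with the groupwise impurity
   statistic under discrete FDR at q ≤ 0.01; only validated sets are
   reported.

A generic label-shuffling permutation test for the edge overlap of two
gene graphs (e.g. exclusivity graph vs a functional-interaction network)
uses the add-one estimator `(1 + #{perm ≥ obs})/(n_perm + 1)`, so p-values
are never zero.

The end-to-end recovery experiment plants three generator-drawn gene
sets among 6000 background genes × 2000 tumors and runs the pipeline on
50 tested null genes plus the planted ones. The background gene count is
deliberately large: the planted sets cover up to 80% of tumors each, and
against a small background their mass visibly shifts the fitted tumor
parameters, miscalibrating unrelated pairs; a genome-scale background
absorbs it. Known limitation, visible at any scale: a planted set whose
coverage is small and whose frequency draw is dominated by one gene can
be pairwise-invisible (its pairwise impurity stays within the FDR-10%
band) and is then never proposed as a candidate, even though the
groupwise test would validate it if asked directly. This is a property
of the graph-then-validate design, not of the group test.

## Numerical conventions

- Poisson-binomial tails are exact sums of the DP pmf; the upper tail is
  accumulated from the far end for accuracy; values are clipped to [0,1].
- p-values are floored at the smallest positive double; tails of
  attainable outcomes are mathematically positive, so this guards only
  against underflow.
- Probabilities entering products are used as stored; the entropy fit
  stores exact 0/1 only for degenerate margins.
- All stochastic operations take an explicit integer seed and are pure
  functions of (inputs, seed); nothing reads global random state.
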