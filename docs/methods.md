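# Methods

## Diffusion model

`netprio` scores each gene of an undirected association network as a
candidate drug target by one or more applications of the self-retaining
neighborhood-averaging operator

    s⁽ᵗ⁺¹⁾ = α s⁽ᵗ⁾ + (1 − α) P s⁽ᵗ⁾,    s⁽⁰⁾ = x,

where P = D⁻¹W is the confidence-row-normalized adjacency (W holds edge
confidences in (0, 1], D the diagonal of row sums; isolated nodes get an
identity row so their signal stays put).  Each row of αI + (1 − α)P is a
convex combination, so scores always stay within [min x, max x], constant
signals are fixed points, and the output is equivariant under node
relabeling.  The kernel was chosen as the smallest operator that realizes
"signal flows to neighbors proportionally to association confidence":
one free continuous parameter (α, the self-retention weight, default 0.5)
and one discrete one (`steps`, default 1).  Other propagation kernels
(random walk with restart, heat kernels) are reachable by iterating, but a
single step already expresses the core assumption — a target is flagged by
a responding *neighborhood*, not by its own transcription.

**Signal.** x_j = min(−log10 p_j, cap) by default, with cap = 16 so p = 0
does not produce infinities; |log2 FC| and |moderated t| are offered for
signatures without useful P-values.  Genes measured but absent from the
network are ignored (logged); network genes without measurements carry
zero signal rather than being removed — this is deliberate, since a hub
adjacent to responding genes must be able to rank highly even when
unmeasured or unresponsive itself.

**Permutation null.** The observed signal values are reassigned uniformly
at random over all network nodes; this preserves the signal distribution
exactly and destroys only its relation to network position, so the null is
exact by construction for an exchangeable signal.  The add-one estimator
p = (1 + #{permuted ≥ observed}) / (B + 1) guarantees p ≥ 1/(B + 1) > 0,
a valid input to BH.  The b-th permutation is generated from the seed pair
(seed, b), so any subset of permutations can be reproduced independently.
B defaults to 1000.  Ranks order by score (desc), then permutation P
(asc), then gene symbol — fully deterministic output files.

**Attribution.** Each gene's top contributors are its neighbors ordered by
(1 − α)·w_ij·x_j, the exact one-step decomposition of the neighbor term;
at most ten are reported and exported as a neighbor-graph document with
per-node fold change (color) and significance statistic (size).

## Moderated t differential expression

For two groups with n_t, n_c ≥ 2 replicates, gene-level residual variances
s_g² (d = n_t + n_c − 2 df) are shrunk toward a prior via the hierarchical
model s_g² | σ_g² ~ σ_g²·χ²_d/d, σ_g² ~ s₀²·d₀/χ²_{d₀}.  The posterior
variance s̃_g² = (d₀s₀² + d·s_g²)/(d₀ + d) yields
t̃ = Δ/(s̃·√(1/n_t + 1/n_c)) with d₀ + d df (capped at the pooled residual
df).  Hyperparameters come from the method of moments on log s_g²: with
e_g = log s_g² − ψ(d/2) + log(d/2), solving ψ′(d₀/2) = Var(e) − ψ′(d/2)
by Newton inversion of the trigamma function and
s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)).  Agreement with the Bioconductor
reference implementation is verified in the test suite to ~1e−9 on a
heterogeneous-variance fixture.

Degenerate branch: when the moment equation has no positive solution
(observed variances more homogeneous than any finite-d₀ prior predicts),
d₀ is set to +∞ with s₀² equal to the df-weighted pooled variance.  This
makes moderation an exact no-op on perfectly homogeneous variances — the
natural limit for this estimator, though reference implementations differ
in this (rarely hit) branch by using the bias-corrected geometric mean
instead.  A single gene disables moderation (ordinary t, with a warning);
an all-zero-variance matrix is rejected.

BH adjustment is the standard step-up adj_(i) = min(1, min_{j≥i} p_(j)n/j);
it is implemented directly (it is load-bearing for three modules) and
cross-checked against statsmodels in the tests.

## Enrichment

One-sided hypergeometric over-representation (P(X ≥ k)) of the genes with
adjusted P ≤ threshold (default 0.01) against each gene set, BH-corrected
per collection — pathways and phenotypes are separate collections and are
corrected separately.  The universe defaults to measured ∩ annotated
genes, avoiding the inflation produced by counting genes that can never
overlap any set; `universe="all-measured"` overrides.  Sets with no
annotated measured genes are not tested.  Depletion is not tested.  HPO
annotations are taken as given; no propagation up the ontology graph is
performed.

## Evaluation

Per-experiment performance is the Mann–Whitney AUC of the known targets'
positions in the full ranking.  Pooling across experiments uses normalized
ranks — each gene becomes an instance scored 1 − (rank − 0.5)/n_e — the
scale-free choice that makes rankings over different gene universes
commensurable; the pooled ROC is swept over these instances.  This pooling
rule materially affects pooled AUC values and is therefore stated
prominently.  Targets absent from a ranking are dropped from that
experiment with a logged count.

## Synthetic benchmark

The generator emulates the method's premise with known ground truth:

- **Network**: Barabási–Albert preferential attachment (default 500 genes,
  m = 3), because protein association networks are heavy-tailed; edge
  confidences ~ Beta(4, 2) rescaled to (0.15, 0.999], right-skewed like
  STRING confidence scores.  An Erdős–Rényi topology is available for
  null-calibration work.
- **Signature**: per-gene z ~ N(0, 1) background; 80% of the target's
  neighbors get |z| inflated by effect_mu = 2.5 (clear but unsaturated
  signal on the two-sided normal-tail P scale); the target itself stays at
  background level by default — exactly the regime where diffusion must
  beat the raw ranking.  log2 ratios are z/2.
- **Suite**: 20 experiments with distinct random targets on one shared
  network, plus per experiment one "true" gene set (perturbed neighborhood
  ∪ target) among 30 size-matched random decoys.

Everything is a pure function of the config seed; written files are
byte-identical across reruns.  What the generator does **not** emulate:
probe-level microarray artifacts, normalization residue, batch effects,
correlated background expression, multi-target compounds, or the
incompleteness and ascertainment bias of real association networks.
Passing benchmarks therefore demonstrate correctness of the machinery and
the qualitative diffusion-vs-raw contrast, not field performance on real
treatment data.

In the benchmark tests the enrichment DE cutoff is 0.2 rather than the
pipeline default 0.01: a single-z evidence model under BH across 500 genes
rarely clears stringent genome-wide thresholds, and the hypergeometric
test needs nonempty overlaps to discriminate; the value was fixed once
from oracle runs of the generator and is not a recommendation for real
data.

## Problem sizes and numerical choices

The shipped benchmark scripts use 10 replicate suites × 20 experiments on
500-gene networks with B = 999 permutations for calibration runs — sizes
at which every reported quantity is stable to well within its tolerance
while the whole recomputation stays in the tens of seconds.  Permutation
comparisons use plain `>=` (no epsilon): permuting a constant vector
reproduces bit-identical scores, so degenerate ties are exact.  Confidence
scales are auto-detected per file (any value > 1 ⇒ STRING 0–999 integers,
divided by 1000; values > 1000 rejected as ambiguous).  Duplicate
signature records keep the smallest P (then larger |log2 FC|, then first
occurrence); duplicate matrix rows keep the highest mean; duplicate edges
keep the maximum confidence.  Gene symbols are upper-cased; no alias or
ID-mapping service is consulted, so upstream mapping to a single symbol
namespace is the caller's responsibility.

## Known limitations

- Two-group designs only; no multi-factor contrasts, time series, array
  weights, or trend/robust variance options.
- The diffusion kernel is one fixed family (self-retention + row-stochastic
  neighbor averaging); no comparison across kernels is built in.
- Permutation P-values are exchangeable-null P-values; they do not model
  hub bias under alternative nulls (degree-preserving signal nulls are not
  implemented).
- The enrichment universe choice (annotated vs all-measured) can change
  results materially; both are exposed, neither is inferred.
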