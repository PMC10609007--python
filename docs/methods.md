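# Methods

## The estimation problem

Sequencing counts are closed: per sample, taxon counts are a multinomial
draw of fixed depth from relative abundances, which are themselves the
closure of latent absolute ("basis") abundances. Correlations computed
naively on fractions confound biology with closure — in particular, closure
and shared-denominator effects push apparent correlations *negative*. The
quantity of interest is the correlation ρ_ij of log basis abundances.

SparCC's sufficient statistic is the log-ratio variance
t_ij = Var[log(x_i/x_j)], which is closure-invariant (the sample total
cancels inside the ratio). With basis log-variances ω and correlations ρ,

    t_ij = ω_i + ω_j − 2 ρ_ij √(ω_i ω_j).

This is one equation per pair for D + D(D−1)/2 unknowns; the sparsity
approximation (ρ_ij ≈ 0 for most pairs) closes the system: summing over
active partners of taxon i gives the linear system

    |A_i| ω_i + Σ_{j ∈ A_i} ω_j = Σ_{j ∈ A_i} t_ij,

which with all pairs active is ((D−2)·I + J)·ω = rowsum(t). Basis
correlations then follow from the displayed identity, clipped to [−1, 1]
(the clip count is recorded — heavy clipping is a sparsity-violation
symptom). The system is solvable only for D ≥ 4.

## Pair exclusion: what it is for and how it is done here

Strongly correlated pairs violate the sparsity assumption and bias every ω
downward (their t_ij is far below ω_i + ω_j). The classic refinement
iteratively removes the most strongly correlated pair from the variance
system and re-solves.

Two behaviors of the classic |ρ̂|-greedy matter on densely correlated data
(measured on a two-block world, D = 30, half of all pairs at ρ = 0.8,
n = 200):

1. Under-estimated variances make all *null* pairs appear strongly
   *negative* (≈ −0.6 here), numerically inseparable from the planted pairs
   by magnitude (|ρ̂| 0.50–0.69 vs 0.54–0.76). The greedy burns its
   exclusion budget on these artifacts and converges to a visibly biased
   estimate (mean absolute error ≈ 0.26–0.37 regardless of budget).
2. Mid-refinement, partially corrected variances transiently overshoot,
   creating spurious *positive* candidates as well.

The sign carries the missing information: compositional artifacts of both
kinds appear negative in the initial estimate, planted structure positive.
The default rule here, `exclusion_rule="gated_positive"`, therefore excludes
the pair maximizing min(ρ̂_current, ρ̂_initial) — a pair must look strongly
positive both before and after refinement. On the same world this removes
exactly the planted pairs and reaches MAE ≈ 0.06 while leaving null data
calibrated (95th percentile |ρ̂| ≈ 0.20 at D = 30–50, n ≥ 100). The classic
rule remains available as `exclusion_rule="abs"`. The cost of the gate: a
world dominated by strong *negative* basis correlations would not be
repaired by it (such pairs are never excluded); magnitude thresholding of
the final estimate is unaffected.

Exclusion runs until no candidate exceeds the threshold (0.1), capped at the
degeneracy limit D(D−3)/2; a taxon is never reduced below 3 active pairs,
else the linear system turns singular (the analogue of the classic d−3
component cutoff). Non-positive ω solutions are floored at 1e-6 and flagged
rather than failed: they occur legitimately at small n.

Count uncertainty: each of `n_resamples` (default 20) passes draws per-sample
fractions from Dirichlet(counts + 1) — proper even for all-zero columns —
and the per-pass ρ̂ are aggregated entrywise (median by default). A
deterministic mode (`fraction_mode="ml"`, pseudocount 0.5) exists for exact
reproducibility checks. Seeded, so identical seeds give identical estimates.

## Network, centrality, keystones

Edges keep pairs with |ρ̂| > threshold (default 0.3, the common gut-network
choice); `mode="positive"` restricts to positive correlations. Isolated
taxa stay in the node set.

Betweenness is Brandes on the **unweighted** graph, unnormalized, unordered
pairs. Correlation weights are similarities; a shortest-path routine fed
them as distances would treat strong edges as long — the classic igraph
pitfall — so the weighted variant offered is `distance_mode="one_minus_abs"`
(cost 1 − |ρ̂|). Betweenness is standardized within the network,
z_i = (b_i − mean b)/sd(b) with sample sd (n−1, recorded in output
metadata); constant betweenness maps to z = 0. Keystones are taxa with
z > 2, strict.

Louvain (two-phase greedy modularity) is seed-dependent, so the partition
returned is the best of 8 seeded restarts (seeds derived from the user
seed; ties to the earliest restart) — deterministic given the seed, and on
small graphs it attains the exhaustive-search optimum in the test suite.
Default is unweighted to match the betweenness convention;
`weight_mode="abs_weight"` maximizes modularity on |ρ̂|. An edgeless graph
yields singleton communities with Q defined as 0.

## Cross-group comparison

Keystone match percent between keystones a and b: both taxa are removed from
both neighbor sets, then 100·|N(a)∩N(b)|/|N(a)∪N(b)| (Jaccard; the overlap
coefficient, denominator min(|N(a)|,|N(b)|), is the selectable variant —
the source study never defines its "matched by" formula, so both readings
are available and neither is privileged). Two empty sets give 0% with a
flag.

Group feature vectors concatenate the node feature (z-value by default, raw
betweenness as variant) over the shared taxon universe with the signed edge
correlation over all universe pairs in a fixed order; absent taxa and edges
contribute 0 (absence is the natural zero of correlation). Dendrograms are
plain agglomerative clustering (average/UPGMA default, complete available)
on Euclidean distances, written here in ~50 lines instead of calling
scipy.cluster because deterministic lexicographic tie-breaking on group
labels is part of the output contract (scipy does not expose its
tie-breaking); on tie-free inputs it matches scipy's average-linkage merge
heights exactly, and the tests assert that. Trees are emitted as Newick
with branch lengths equal to merge-height differences.

Community counts are reported for two scopes: all nodes, and the
"displayed" subset (keystones plus the top-k most abundant taxa, k = 4 by
default) mirroring how such networks are typically drawn; which scope a
published count refers to is often ambiguous, so both are always written.

## The synthetic generator: what it emulates and what it does not

The generator produces the world under which SparCC is consistent:
block-structured correlation (modules of co-occurring taxa) with optional
hub taxa tied at |ρ| = hub_rho to every taxon outside their own module,
log-variances uniform on [0.5, 2]; per sample, log basis abundances are
multivariate normal, exponentiated, closed to fractions, and read out as a
multinomial of fixed depth. Group-specific structure comes from rewiring a
fraction of the strong correlations to previously-null pairs (PSD repair
re-applied). Defaults mirror the motivating study design: 5 groups × 5
samples, 55 genus-level taxa, depth 3×10⁴, 3 modules, 2 hubs, within-module
ρ = 0.7, hub ρ = 0.6, rewire fraction 0.4. Taxonomy labels are drawn from a
fixed pool of real mouse-gut families/genera with phylum prefixes so that
rank parsing, phylum aggregation and ratio utilities exercise realistic
strings.

Block+hub correlation targets can be indefinite; repair clips eigenvalues at
1e-8 and renormalizes the diagonal. The object therefore carries both the
exact pre-repair design (`planted_correlation`) and the repaired correlation
actually sampled from (`correlation`); recovery tests compare against the
latter, since it is the true generative correlation.

Not emulated: read-level error, chimeras, ASV calling, taxon-specific
sequencing bias, zero inflation beyond multinomial sampling, or
mechanistic diet effects on abundances. A green recovery test therefore
establishes correctness of the estimator under its own generative
assumptions — not robustness to real 16S artifacts.

Sample size: the motivating design (n = 5 per group) is far below what
SparCC needs for stable correlations; the pipeline runs it but emits an
explicit warning below n = 20 and the warning is recorded in the manifest.
Recovery-quality claims in the tests use n ≥ 100.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng` seeds; per-group
  SparCC streams derive as seed + 101·group_index. Identical config + seed
  reproduce count tables bit-for-bit and floating outputs byte-for-byte
  (formatted at 10 significant digits).
- Log-ratio variances are computed from the covariance of log fractions
  (t_ij = V_ii + V_jj − 2 C_ij), symmetrized and floored at 0; sample
  variance convention ddof = 1 throughout.
- Multinomial sampling exponentiates shifted logs (z − max z); closure makes
  the shift exact, not approximate.
- Degenerate inputs: zero-total samples are rejected by name; a zero-sd
  betweenness vector maps to all-zero z; an edgeless graph yields singleton
  communities with Q = 0; a zero pooled denominator makes the abundance
  ratio NaN rather than infinity.
- Serum utilities are the two closed-form clinical indices used alongside
  such studies: Friedewald LDL-c = T-Cho − HDL-c − TG/5 (mg/dL) and
  HOMA-IR = glucose × insulin / 405 (mg/dL × µU/mL).

## Known limitations

- The gated-positive exclusion rule assumes dominant dense structure is
  positive; predominantly negative true correlation structure falls back to
  the behavior of the classic rule.
- SparCC point estimates only; no bootstrap p-values (edges are thresholded
  on magnitude, matching the pipeline this package reimplements).
- Dendrograms carry no topology-significance testing.
- BIOM support is read-only JSON (v1.0); HDF5 BIOM (v2) is out of scope.
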