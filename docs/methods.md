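# Methods

## Model

An intra-chromosomal contact map at resolution `r` (default 100 kb) is a
symmetric nonnegative matrix `A` over genomic bins; `A_ij` is the
(balanced) contact count between bins `i` and `j`. Self-contacts are
dropped on load and the total weight is `m = (1/2) Σ_{i≠j} A_ij`, so that
`Σ_{i≠j} A_ij = 2m`.

Communities are scored by the parametric modularity

    Q = (1/2m) Σ_{i≠j} (A_ij − γ P⁰_ij) δ(C_i, C_j)

with the distance-decay null model

    P⁰_ij = 2m k_i k_j |i−j|^(−α) / Σ_{i'≠j'} k_i' k_j' |i'−j'|^(−α).

The power law reflects polymer physics: contact probability between two
loci of a folded chain decays with their linear separation. Separations
`|i−j|` always use *original* bin indices, so bins masked out before
balancing (centromeres, unmappable regions) still contribute genomic
distance. The normalisation forces `Σ P⁰ = 2m`, which yields two exact
identities used throughout the tests: `Q(one community) = 1 − γ` and
`Q(all singletons) = 0`. At `α = 0` the null reduces to the
configuration (Newman–Girvan) model.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `α` | contact-decay exponent (dimensionless) | 0.75 / 1.08 | empirical short-range (~0.2–1.2 Mb) and genome-wide long-range decay in human Hi-C |
| `γ` | null-model scale (dimensionless) | 1.0 | neutral scale; swept in practice |
| `n_runs` | optimizer passes per (α, γ) | 1000 | enough samples to chart the landscape; desk-scale analyses use 20–50 |
| `d_max` | cluster radius in partition distance | 0.10 | co-clustered partitions share ≥ 90% of nodes on weighted average |
| `p` | core support fraction | 0.9 | mirrors the 10% dissimilarity allowed by `d_max` |
| min cluster size | cores only from clusters with ≥ 10% of the ensemble | 0.10 | avoids core statistics on a handful of runs |
| KR tolerance / iterations | row-sum relative deviation / cap | 1e−6 / 1000 | standard balancing practice |
| mask threshold | min fraction of nonzero entries per bin | 0.10 | drops bins that prevent balancing convergence |

## Optimization

The optimizer is a generalized Louvain scheme on `B = A − γP⁰`. Local
moves sweep nodes in an RNG-shuffled order; a node's candidate communities
are those of its nonzero-`B` neighbours plus one fresh singleton, and one
of the strictly-positive-gain moves is chosen with probability
proportional to its gain. This proportional rule (rather than greedy
argmax, available via `greedy=True`) deliberately samples the space of
feasible near-optimal partitions — the landscape — instead of funnelling
into one optimum. When a full sweep accepts no move, communities are
aggregated (block sums of `B`; within-community weight accumulates on the
diagonal, which moves ignore but quality bookkeeping retains) and the
procedure recurses until aggregation stops merging. Starting from
singletons (`Q = 0`) and accepting only positive gains guarantees
`Q ≥ 0` and monotone non-decreasing quality; aggregation exactness is
asserted by an internal debug hook exercised in the tests.

Gains within `1e−12` of zero are treated as zero to avoid cycling on
float noise. Community labels are canonicalized by first-node occurrence.
The only stochasticity is the sweep order and the proportional sampling,
both driven by a single per-run seed; ensemble seeds derive from a master
seed via `numpy.random.SeedSequence`, so any stored run is reproducible
in isolation and ensembles are byte-identical across reruns.

## Landscape analysis

Partition distance is the symmetrized weighted mean Jaccard distance
(each community of `P` matched to its best-overlapping community of `P'`,
weighted by community size, averaged over both directions). It is a
dissimilarity in `[0, 1)` with `d = 0` iff the partitions are identical;
the triangle inequality is *not* guaranteed and never used. Variation of
information is available as an optional metric but is not the default.

Ensembles are summarised by MD(d) (mean over the strict upper triangle),
Var(d), CV(Q) and Var(Q) (unbiased, ddof = 1), and classified as
consistent / dissimilar / degenerate / anomalous by two thresholds:
"high" distance variability ⇔ MD(d) > `d_max`, "high" quality
variability ⇔ CV(Q) > 1e−3. The thresholds are qualitative knobs, both
configurable; the degenerate class (high Var(d), low Var(Q)) is the
regime where no partition can be preferred on quality grounds.

Clustering follows the quality-ordered centre rule: visit partitions in
decreasing Q (ties broken by run id, stable), seed the first centre with
the best partition, make any partition at distance ≥ `d_max` from all
existing centres a new centre, then assign every remaining partition to
its nearest centre (ties to the earlier, higher-quality centre).

## Cores and fringe nodes

For a cluster centre community `C_i`, each member partition's
best-overlap community is fixed once (ties: larger community, then
smaller label), and `c(v)` is the fraction of members whose matched
community contains `v`. The core is `C'_i = {v ∈ C_i : c(v) ≥ p}`. The
centre run itself never counts toward support (a one-member cluster has
`c ≡ 1` by convention), but distinct members that happen to equal the
centre do. Finding the literally largest subset co-clustered in a
fraction `p` of members is combinatorial; this one-pass matched-community
rule is deterministic, satisfies the support guarantee node-wise, and an
optional iterative mode re-matches against the shrinking core until a
fixpoint. The fringe score is `1 − c`; nodes with `1 − c > 1 − p` are
fringe nodes.

## Effective size and annotation comparison

`ŝ = n / 2^H(P)` with `H` the Shannon entropy (bits) of the community
size distribution; the perplexity `2^H` is the effective number of
communities, insensitive to spurious singletons (an optional size filter
drops communities under a given bin count first, e.g. sub-5-bin TADs).
The `ŝ(γ)` curve is measured on the best partition per γ (not the
ensemble mean) and inverted by log–log interpolation, falling back to the
closest grid point with a warning when non-monotonic.

Annotation tracks rasterize at bin resolution — a bin takes the label of
the first-listed interval covering ≥ 50% of it; uncovered bins stay
unassigned — and become partitions in two modes: `segments` (each maximal
same-label run of consecutive bins is a community, the natural reading of
TAD intervals) or `classes` (all bins of one label form one delocalized
community, optionally merging sub-compartments to A/B). Agreement is
adjusted mutual information over the bins assigned in *both* partitions,
with arithmetic-mean normalisation and the hypergeometric expected-MI
correction (scikit-learn's default).

## Synthetic data

The generator draws `A_ij ~ Poisson(μ (1 + ε·[same block]) |i−j|^(−α))`
for `i < j` and mirrors: power-law decay with planted contiguous blocks
(optionally two distant blocks merged into one delocalized community) and
Poisson count noise. Defaults — 6 blocks of 50 bins (5 Mb at 100 kb),
`α = 0.75`, `μ = 50`, `ε = 5` — give a strong, cleanly recoverable
signal; the log–log regression of mean count vs separation recovers `α`
within ±0.05 at 400 bins. What it does **not** emulate: balancing biases,
overdispersion beyond Poisson, nested/hierarchical domains, unmappable
gaps, or the semi-nested deviations of real chromosomes — so passing
recovery tests shows the machinery is correct, not that real Hi-C
landscapes are benign. `perturbed_ensemble` builds ensembles with exactly
known flip arithmetic (each node moved to a random other community with
probability `f`), giving closed-form expectations for `c`, cores, and
fringe counts without running the optimizer. Note that the expected
member–centre Jaccard distance under flips is ≈ `2f/(1+f)`, so `f` must
stay well below `d_max/2` for such an ensemble to form a single cluster.

## Problem sizes

Dense `O(n²)` storage for `A`, `P⁰` and `B` is deliberate: a human
chromosome at 100 kb is ~1–2.5 k bins, well within memory, and dense
numpy operations dominate hand-rolled sparsity at these sizes. Tests and
the acceptance script use 120–400-bin instances with 20-run ensembles —
the recovery statistics there are already saturated (AMI = 1 across
seeds), so larger ensembles would only add runtime, not information;
1000-run production ensembles use identical code paths.

## Known limitations

- The power-law null is a modelling choice; blended decay forms
  (loop-extrusion plus phase separation) are out of scope.
- The one-pass core rule can under-fill cores relative to the (NP-hard)
  maximal subset; the iterative mode mitigates but does not solve this.
- Cluster assignment uses distance-to-centre only, not average linkage.
- `.hic`/`.mcool` binary formats are not parsed; convert to triplet text
  or dense matrices first. Inter-chromosomal contacts are out of scope.
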