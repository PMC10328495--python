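# Methods

This note records the statistical conventions, numerical choices and known
limitations of the package, in the order a user meets them.

## Topological hypotheses and posterior model odds

A hypothesis is a predicate over trees: monophyly of a taxon set, a sister
grouping of two sets (each set monophyletic and their union monophyletic),
or the negation of monophyly. On rooted trees monophyly means some node's
leaf set equals the query; on unrooted trees it means the corresponding
bipartition exists. Singletons and the full taxon set are monophyletic by
convention.

Posterior model odds are estimated by filtering an MCMC tree sample:
`odds = n_consistent / n_inconsistent` estimates P(M0|X)/P(M1|X) because
the two counts are proportional to the posterior masses of the two
(complementary) topology classes. Published tables of this quantity are not
always consistent about the denominator — some rows match
n_consistent/n_total instead — so the result object carries both
(`odds` and `odds_vs_total`) with the mass ratio as the headline number.
When no tree is inconsistent the odds are +infinity, reported as such.

Burn-in discards the leading `floor(fraction * N)` trees. Sample files are
taken as-is: the package never reconstructs chain length or sampling
interval from generation counts, because producers differ in whether the
initial state is written out.

## Root-placement frequencies and MCC trees

A root placement is the equivalence class of the bipartition between the
two subtrees under a (binary) root; branch lengths are ignored. The
frequency table sorts placements by descending count, ties broken by the
lexicographically smallest member set, and its frequencies sum to one by
construction.

The MCC tree is the *sampled* tree maximizing the sum of log clade
frequencies (equivalently the product of clade credibilities), clade
frequencies estimated from the same sample; clades of size 1 and n are
excluded since their frequency is always 1. Ties go to the earliest tree in
sample order, which makes the choice deterministic. No node-height
summarization is performed.

## Information criteria

AIC = −2 logL + 2K; AICc adds 2K(K+1)/(n−K−1) and requires n > K+1 (a
domain error otherwise). The small-sample rule n/K < 40 (strict) flags when
AICc rather than AIC should be read. Akaike weights are computed as
exp(−Δ/2) normalized through a log-sum-exp, so comparisons remain exact
when Δ is in the hundreds or thousands. K and n are always caller-supplied;
the package never infers them from model names.

For fits produced by the built-in engine, K counts 2n−3 branch lengths
(shared across partitions) plus, per partition, 1 for a gamma shape, 1 for
an invariant fraction and 19 for +F frequencies. Substitution-model
exchangeabilities are fixed empirical constants and are not counted.

## Combining stepping-stone runs and Bayes factors

Replicate log marginal likelihoods v_1..v_R are combined as

    combined = ln( (1/R) Σ_r exp(v_r) )

i.e. the log of the arithmetic mean on the likelihood scale, computed
relative to max(v_r). This is *not* the arithmetic mean of the logs, and
the difference matters: for run pairs tens of log units apart the two
conventions disagree by ~10 log units, and only the log-mean-exp
convention is consistent with treating the runs as replicate estimates of
the same marginal likelihood. The combined value always lies in
[max − ln R, max] and is dominated by the best run.

The Bayes factor is exp of the difference of combined log marginals. It is
stored on the log scale and rendered as a base-10 mantissa/exponent pair,
so magnitudes like 10⁻⁹⁴ (or beyond double-precision range) serialize
exactly. Evidence is banded on the 2 ln BF scale — 0–2 negligible, 2–6
positive, 6–10 strong, >10 very strong — mirrored as "evidence against M0"
for negative values; a value exactly on a band edge takes the stronger
label.

## The likelihood engine

Amino-acid likelihoods use Felsenstein pruning over 20 states with the LG
exchangeability matrix and frequencies (bundled as a text data file in the
standard published-matrix layout; +F replaces the frequencies with observed
alignment frequencies using a 1/20 pseudo-count for absent residues).

Rate heterogeneity uses C equal-probability discrete gamma categories whose
rates are the *mean* of each quantile slice (the dominant convention in ML
tools), so the rates average to exactly 1. With an invariant class the site
likelihood is

    (1 − p_inv) (1/C) Σ_k L(r_k) + p_inv π_x [site constant]

and the variable-site rates are deliberately *not* renormalized by
1/(1 − p_inv); this matches the way p_inv and the gamma mixture are
parameterized in the producing tools. Gaps and the ambiguity codes
B, Z, J, X are missing data (all-ones partials); for the invariant class a
column counts as constant if all non-missing residues agree, and an all-gap
column has invariant likelihood 1.

Transition probabilities come from the symmetrized eigendecomposition
(similarity transform by √π), which guarantees real eigenvalues; rows are
clipped at 0 and renormalized to guard against round-off at extreme branch
lengths. Per-node rescaling by the per-pattern maximum keeps partials in
range on large trees; site patterns are compressed with counts.

Branch lengths are optimized by round-robin bounded univariate search
(Brent on [1e-9, 30]) with partials recomputed before each branch, which
guarantees the log-likelihood never decreases; sweeps stop when a full pass
improves by less than the tolerance (default 1e-6; the topology search uses
a looser 1e-4 and at most 4 sweeps, since it only needs to rank
topologies).

Constrained topology search enumerates all unrooted binary topologies
((2n−5)!! of them; capped at 8 taxa = 10,395), filters them by the
hypothesis predicate (or its negation), optimizes branch lengths on each
survivor and returns the argmax, ties resolved by enumeration order.
Partitions share topology and branch lengths (one concatenated tree);
per-partition rate multipliers are out of scope. Site ranges are 0-based
half-open internally; the partition file format uses 1-based inclusive
ranges ("name = start-end").

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* the analyses assume,
with known ground truth:

* Yule trees conditioned on n tips; the expected root height is
  Σ_{k=2..n} 1/(λk), which the tests verify. Defaults: birth rate 1.
* Alignments evolved site-by-site under the engine's own models — the exact
  inverse of the likelihood computation, so simulation + inference
  round-trips are exact in distribution.
* Posterior-like tree samples where a focal hypothesis holds independently
  with probability p: satisfying trees are built by construction
  (focal subtrees joined, then spliced into a random frame), violating
  trees by rejection sampling (capped at 10,000 draws — for realistic taxon
  counts a random tree violates a specific clade with overwhelming
  probability, so the cap is a safety valve). Branch lengths are
  exponential with mean 0.1; downstream consumers of these samples use
  topology only.
* Root samples: a fixed unrooted tree rooted on edges drawn from a given
  distribution.
* Marginal-likelihood replicates: a true value plus Gaussian noise.

These samples are i.i.d. draws; they do not emulate MCMC autocorrelation,
convergence failure, or across-tree branch-length correlation. Passing the
calibration tests therefore shows the estimators are correct for honest
samples, not that any particular real chain has converged. Random streams
are derived per operation from (seed, operation tag), so adding one
generator call does not shift the draws of the others.

The subsampler implements greedy diversity-maximizing reduction: repeatedly
find the closest leaf pair and drop one member until the target remains.
The reference tool drops a random member; here the default deterministic
rule drops the less peripheral member (smaller total distance to the rest,
ties dropping the lexicographically larger label) so runs are reproducible,
with the randomized rule available behind a seed. A fixed per-group count
is used as the stopping rule. Groups are subsampled independently on their
own trees.

## Problem sizes used in the test suite

The statistical tests run at sizes chosen to give sharp bounds while
keeping the suite quick on one CPU: estimator calibration at 5,000 trees
per clade probability and 10,000 trees for the root-frequency table
(exact 99% binomial/multinomial bounds); pruning vs brute force on all
topology shapes with ≤4 leaves over 50 random models; re-rooting invariance
on 50 random instances; the end-to-end model comparison on 20 replicates of
6-taxon, 2,000-site alignments; subsampler near-optimality on 100 ten-leaf
trees against the exhaustive C(10,5) optimum.

## Known limitations

* No heuristic large-tree search (NNI/SPR), bootstrap, model-parameter
  estimation (α, p_inv are supplied, not fitted) or dating — full-scale
  inference belongs to the external tools whose outputs this package
  consumes.
* No NeXML/PhyloXML; node annotations in tree files are stripped, not
  preserved.
* The MCC tree is selected among sampled trees only (no consensus-tree
  construction, no node-height annotation).
* Stepping-stone sampling itself is out of scope; only run-level log
  marginals are aggregated.
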