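# Methods

## Problem

A fossil taxon known only from morphology is to be positioned on a fixed
molecular backbone phylogeny of living taxa. The running example is the
extinct cycad *Dioonopsis*, scored together with the ten extant cycad
genera for a small matrix of unordered leaf-morphology and cuticle
characters, and placed on the genus-level molecular topology of the
extant genera. With the backbone fixed and a single free taxon, every
binary tree compatible with the backbone corresponds to exactly one of
its 2L−3 edges (L = number of backbone leaves), so "searching tree space
under a backbone constraint" reduces to scoring each attachment edge
exhaustively. All analyses here exploit that reduction; nothing is
heuristic.

## Data model

A character matrix cell is a non-empty *set* of integer state codes:
singleton = observed state, full set = missing ("?" or "-"),
intermediate set = polymorphism/ambiguity ("(01)" and "{01}" are treated
identically because both parsimony and likelihood consume them the same
way). Per-character state-space sizes k may differ within one matrix.
NEXUS has no per-character alphabet, so the writer embeds a
`[&statecounts=...]` comment (a legal NEXUS comment, invisible to other
programs) that the reader honours; foreign files fall back to
`len(SYMBOLS)` when declared, else max observed state + 1.

Trees are unrooted in meaning, stored with a canonical trifurcating-root
representation. Edges are identified by the bipartition of the leaf set
they induce, canonicalised as the side not containing the smallest
label; this identity is invariant under rerooting, which is what makes
"attachment edge" a stable coordinate across the whole pipeline.

## Parsimony placement and bootstrap

Fitch's set-intersection/union pass generalised to set-valued leaves
gives the minimum number of unordered changes per character; leaf
ambiguity enters the downpass directly and still yields the true
minimum (verified against exhaustive internal-labeling minimisation on
all instances up to 6 leaves and 3 states). The placement profile scores
the fossil attached at the midpoint of every backbone edge; the set of
edges attaining the minimum (`mp_edges`) is reported without
tie-breaking.

The nonparametric bootstrap resamples the characters with replacement
(default 1000 replicates) and repeats the exhaustive placement scoring on
each pseudo-matrix. The conventional tooling runs a heuristic
constrained search here; exhaustive attachment enumeration is exact and
strictly dominates it at this problem size. Tied MP placements within a replicate split that
replicate's unit weight equally, so placement support sums to one over
edges; split support aggregates all splits of each replicate's MP trees
with the same fractional weights.

## Mk(+Γ) likelihood with the variable-characters correction

The Mk model: k states, equal exchange rates, uniform stationary
frequencies, branch lengths in expected changes per character. Its
transition probabilities are closed-form, and the pruning recursion uses
the rank-one structure `P v = P_diff · Σv + e^{-krt/(k-1)} · v`, so no
transition matrices are materialised. Rate variation among characters
uses the discrete-gamma approximation: `ncat` equal-probability
categories (default 4, the convention of the standard Bayesian tool),
category rate = mean of its quantile bin, renormalised to average
exactly 1. The root is placed arbitrarily; reversibility plus uniform
root frequencies make the likelihood rooting-invariant (tested).

Because invariant morphological characters are never collected, each
character's likelihood is conditioned on being variable: divided by
`1 − Σ_s L(constant all-s)` for its own k (the "Mkv" correction).
"Variable" rather than "parsimony-informative" conditioning is
implemented, with a switch to disable the correction entirely.
Characters with different k are independent; one branch-length set and
one gamma shape α are shared by all characters (no partitioning — the
matrix is a single small block).

## Bayesian placement by Metropolis-coupled MCMC

The sampled state is (attachment edge, backbone branch lengths, pendant
branch length, α). The backbone constrains topology only; its branch
lengths are free parameters because the morphological matrix is the only
data. Priors: uniform over the 2L−3 attachment edges, iid exponential
(rate 10, i.e. mean 0.1 expected changes) on every branch length,
exponential(1) on α. Moves: (a) re-attachment to a uniformly proposed
edge, re-split at its midpoint, pendant length carried over (symmetric);
(b) a multiplier `x → x·exp(δ(u−½))` on one random branch length, and
(c) the same kernel on α, both with Hastings factor equal to the
multiplier; δ = 2·ln 1.5, fixed — reproducibility is preferred over
auto-tuned efficiency at this size. Chains are heated incrementally,
β_i = 1/(1+λ(i−1)) with λ = 0.1; the heated target is
prior × likelihood^β; one swap between a random adjacent pair is
attempted per generation; only the cold chain is recorded.

The study design — 2 independent runs × 4 chains, 10⁶ generations, 25%
burn-in — is the `SamplerConfig` default. Tests and smoke runs use a
separate test scale (10⁴ generations), named explicitly in the config
class; the methods are identical at both scales. Convergence is
summarised by the ASDSF: splits above 10% frequency in at least one run,
sample standard deviation (ddof = 1) across runs, averaged. Correctness
of the sampler is established three ways: a flat-target run is uniform
over edges within Monte-Carlo error; the placement-only sampler matches
direct enumeration `L(e)/Σ L(e')`; and each multiplier kernel alone
leaves its exponential prior stationary. Monte-Carlo standard errors in
these checks use batch means, which is conservative under
autocorrelation.

## Consensus-network splits

Bootstrap MP trees and posterior samples share one code path: each
sample's implied (L+1)-taxon tree (backbone + attached fossil) is
decomposed into non-trivial splits, frequencies are tallied with the
sample's weight, and splits at or above the cutoff are retained — the
15% cutoff of the study design, with an *inclusive* boundary (the
boundary semantics are not standardised; this convention is fixed and
tested). The retained weighted split set is written as a
SplitsTree-compatible TAXA + SPLITS NEXUS file; drawing the network is
delegated to such viewers, since the analysis content is the split set
and its weights, not the graph layout.

## Synthetic data

The generator emulates the study's data shape: a uniformly random
labelled backbone topology (sequential leaf insertion at a uniformly
chosen edge) over the ten extant cycad genera with iid exponential
(mean 0.3) edge lengths, a fossil attached at a known edge, and
characters simulated under Mk with per-character gamma rates —
*continuous* gamma by default, mirroring the usual mismatch with the
discretised inference model; a `discrete_rates` flag simulates under the
exact inference model for self-consistency tests (the simulated
constant-pattern frequency then matches the pruning machinery's analytic
value, which ties simulator and likelihood to the same model). Constant
characters are redrawn when conditioning on variability, matching the
Mkv assumption; missing cells are masked uniformly at random (no
realistic missingness structure such as taphonomic correlation); an
optional polymorphic fraction widens cells by one state. Defaults:
10 extant taxa, 15 characters alternating k = 2 and k = 3, α = 1,
5% missing.

What passing tests on these data do *not* show: robustness to correlated
characters, ordered states, non-uniform missingness, or model
misspecification beyond the continuous-vs-discrete rate mismatch.

A placement-recovery experiment (50 seeds per condition, pendant length
0.05) measures how often the true attachment edge is among the MP
placements as characters grow from 15 to 240. Raw inclusion is a
resolution-confounded statistic: at 15 characters large MP ties inflate
it, so it is not monotone in character count, and at 240 characters it
plateaus near 0.85 — the residual misses have step margins of 1–3 and
trace to short attachment edges and long-branch attraction under the
high-homoplasy mean-0.3 edge lengths, not to sampling noise (the rate is
insensitive to shrinking the pendant further). The tie-corrected credit
(1/|mp_edges| per hit) is monotone (≈0.46 → 0.52 → 0.83) and is the
statistic the unit tests assert.

## Numerical and design notes

- Problem sizes in tests and the acceptance script: 4–11-taxon trees,
  15–240 characters, 10⁴–5·10⁴ MCMC generations, 100–1000 bootstrap
  replicates; these exercise every code path of the study-scale design.
- All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds by hashing the stage name, so stages rerun in
  isolation reproduce their in-pipeline results, and whole-pipeline
  reruns are byte-identical.
- Degenerate inputs: zero-length branches are valid (transition matrix →
  identity); zero-rate categories are impossible by construction; a
  non-positive Mkv denominator raises (it cannot occur on valid input);
  matrices must cover exactly the backbone leaves plus the fossil, and
  validation reports both directions of any mismatch.
- Labels are matched after trimming whitespace and unifying underscores
  with spaces, reconciling Newick and NEXUS dialects.
- Limitations: no ordered/weighted characters, no among-character
  partitioning, no unconstrained topology search, no marginal-likelihood
  estimation, no network drawing.
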