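# Methods

## Model

A variable-length Markov chain over Σ = {A, C, G, T} is a suffix-closed
set of contexts, each holding next-symbol probabilities. For a context
*w* (written in sequence order, most recent symbol rightmost) the
estimates are

p̂(σ|w) = (N(wσ) + 1) / (Σ_c N(wc) + 4),

where N(·) are sliding-window occurrence counts of the training text.
The +1 pseudo-count is applied to each of the four extension counts
(denominator +4); this is the only reading of "add one" that guarantees
no zero probability in every position of the estimate. The denominator
uses Σ_c N(wc) rather than N(w): occurrences of *w* at a record end
(followed by the sentinel) have no observable successor and are
excluded from the conditional.

Training text is encoded with a sentinel terminating every record and
replacing every non-ACGT input character. The sentinel matches nothing,
including another sentinel, in all character comparisons, so distinct
record tails never co-extend and no k-mer window spans a break.
Lowercase (soft-masked) residues are treated as ordinary residues:
masking is annotation, not sequence content. Multi-record FASTA input
trains a single model over the concatenation — one model per genome,
not per contig.

## Counting

Support pruning keeps every k-mer with N(w) ≥ t and |w| ≤ L. The
enumeration evaluates suffix ranges lazily: a node is a contiguous
range of suffix start positions plus the string depth already matched.
Evaluation (1) computes the longest common extension of the range,
emitting one record per extension character (implicit suffix-tree nodes
are expanded to unit-length edges, since the probabilistic suffix tree
needs each length explicitly), (2) counting-sorts the range by the
character after the extension — a single stable sort that groups
A, C, G, T and puts terminal suffixes last, preserving
position-ascending order within groups — and (3) emits one child range
per non-empty group. Children are enqueued breadth-first only when
their size reaches t and their context length stays within L; since
N(uv) ≤ N(v), the early gate is lossless. The root record (empty
context, count = number of residue positions, next counts = residue
frequencies) is always retained as the scoring fallback.

Counts are stored at evaluation time in a plain map keyed by the
context string. Parent/child relations are resolved later by string
lookup, so no suffix-tree arrays and no suffix links are ever built.

## Similarity pruning

A context *cw* is compared with its parent *w* (oldest symbol dropped)
through the weighted divergence

Δ_cw = N(cw) · Σ_σ p̂(σ|cw) ln( p̂(σ|cw) / p̂(σ|w) ),

with the raw (un-pseudo-counted) N(cw) as multiplier. Contexts are
processed deepest-first; a context is removed iff it has no surviving
child (σw stored) and Δ < K (strict: a tie at K is kept). One
descending pass reaches the fixpoint because removing a context can
only unlock its strictly shorter parent. The root is never removed and
the surviving set stays suffix-closed. Natural logarithms are used
throughout (KL, likelihoods, BIC): K derives from a χ² quantity, which
lives in nats.

The default K = 3.9075 is half the χ² critical value at 3 degrees of
freedom, p = 0.05 (exactly 3.90736…; the constant keeps the value as
conventionally printed). Raising K never enlarges the surviving set.

## Scoring

total_nll = −Σ_t ln p̂(x_t | longest stored suffix of x_1…x_{t−1}),
with the history capped at L symbols before suffix matching. The first
positions of a sequence use the best available shorter context, down to
the root. Non-ACGT characters are skipped (not scored) and reset the
history, mirroring the sentinel convention at training time; splitting
a sequence at such a point and summing the parts therefore reproduces
the unsplit total. Scoring is deterministic and reported both as a
total and per scored position.

## Model selection

BIC = card(M)·ln|S| − 2·ln P_M(S), where |S| counts scored training
positions (sentinels and masked bases excluded) and
card(M) = (|Σ|−1)·L(M) with L(M) the number of leaves — contexts with
no stored child σw; internal contexts are redundant because they can
always be extended to a more specific one. The grid search counts once
per t at the largest requested depth and derives smaller-depth tables
by truncation (record contents are independent of the depth cap), then
prunes and scores each cell. Ties in BIC prefer the smaller depth, then
the larger min count. The companion statistic `rare5pct` is the count
at the 5% quantile (lower interpolation, element at floor(q·(n−1))) of
the sorted counts of the deepest stored contexts.

**Known limitation — depth overshoot on finite-order sources.** With K
fixed, each truly redundant boundary context passes the similarity test
with probability of a few percent (Δ behaves like a scaled χ²₃/2 under
the null; measured ≈ 3% per context at the default K). A lone deep
survivor converts its parent leaf into an internal node while adding
one leaf, so card(M) is unchanged while the training likelihood rises
by roughly 2Δ — BIC then strictly prefers the deeper model. On data
generated from an exactly finite-order source this pushes the selected
depth one or two levels past the true order whenever such a survivor
exists; the BIC margin against depths *below* the true order remains
decisive (tens of thousands of nats per megabase). On real genomes,
which are not finite-order, the selected depth reflects genuine
higher-order structure and the support threshold. Tests therefore
assert the one-sided property (selected depth ≥ true order, large
margin against under-fitting) rather than exact depth recovery.

## Parallel partitioning

The enumeration fans out into independent subtree tasks for
`parallel_depth` levels: level 0 is the root (expanded serially — it is
cheap relative to the subtrees), each level multiplies the surviving
ranges by up to 4, and the level-d ranges become tasks (4 at depth 1;
4+16 spawns across two levels at depth 2). Every task copies its
workspace slice and fills a private record buffer; buffers merge in
deterministic task order, so the merged table is identical to serial
enumeration for any worker count. Oversubscription is allowed: GC
skew makes subtree workloads unequal, and more tasks than workers
evens them out. Task failures propagate with the owning context prefix
named.

## Synthetic data generator

`random_generator(seed, max_order, kl_floor)` draws a full context tree
of depth `max_order` with Dirichlet(1,1,1,1) next-symbol rows; each
child row is resampled until its KL divergence from its parent reaches
`kl_floor`. The floor (default 0.2 nats in the recovery studies) keeps
the generator identifiable — a context indistinguishable from its
parent could never survive pruning. Sampling draws each symbol from the
longest matching context. Because the tree is full, only the
deepest contexts govern the process after the first few symbols; the
drawn rows at internal contexts are *not* the process conditionals
(those are stationary mixtures of the deeper rows), so distributional
accuracy of a trained model is asserted at the deepest contexts only.

What the generator does not emulate: repeats, isochores, strand
asymmetry, or any structure beyond what a context tree induces. Passing
recovery tests therefore demonstrates correctness of counting, pruning
and estimation — not that real genomes are order-k.

`brute_force_kmer_counts` is the independent oracle: a quadratic-time
sliding-window counter with identical masking/terminal conventions,
used to verify the lazy enumeration exactly (all counts, next-symbol
tallies and terminal tallies) on randomized corpora.

## Problem sizes and defaults

- Recovery studies: order-1 to order-3 generators, KL floor 0.2,
  n = 10⁶ sampled symbols, t = 100, L = order+1, K = 3.9075. At these
  sizes every true context has Δ in the thousands of nats while
  boundary contexts sit at the χ² null, giving a sharp separation.
- Oracle equivalence: dozens of random corpora up to 10 kb with 2%
  ambiguity characters, t ∈ {1, 2, 5}, L ∈ {1..8}.
- Serial/parallel identity: 100 kb random corpora, partition depths
  0–3, t = 2, L = 6.
- Grid-search study: order-2 source, n = 2–3·10⁵, t = 100, depths 1–4.
- Default grids for the CLI: t ∈ {2, 5, 10, 20, 50, 100, 200, 300,
  400, 500, 750, 1000}, L ∈ {3..18}, both overridable.

All randomness is seeded through function arguments; there is no
global random state.

## Degenerate inputs and numerical notes

- A corpus with no ACGT residue is rejected at encoding time.
- Probabilities are never zero by construction; logs are always finite.
- Δ of identical pseudo-counted distributions is exactly 0, and Δ ≥ 0
  always (Gibbs' inequality), so a threshold of 0 prunes nothing.
- Model files round-trip integer counts exactly; probabilities are
  always recomputed from counts, never stored.
- Scoring caches log-probability rows per history window only for
  L ≤ 12 to bound memory on deep models.
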