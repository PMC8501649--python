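# vlmc — variable-length Markov chains over DNA

Variable-length Markov chains (VLMCs) model a DNA sequence with
conditioning contexts whose length adapts to the data: frequent,
informative contexts are kept long, redundant ones are collapsed into
their parents. The model is a probabilistic suffix tree — each node is
a k-mer *w* with occurrence count *N(w)* and next-symbol probabilities
p̂(σ|w), and the child of *w* is σ*w* (one older symbol prepended).
VLMCs are a standard tool for alignment-free comparison of genomes:
train one model per genome, then score other sequences by negative
log-likelihood.

This package is aimed at people who work with alignment-free genome
comparison and at anyone who needs a transparent, well-tested reference
for VLMC training, scoring and order selection.

## Method

Training has two stages:

1. **Support pruning.** Enumerate every k-mer with

   N(w) ≥ t and |w| ≤ L

   by lazy evaluation of suffix ranges: each unevaluated node is a
   contiguous range of suffix start positions; evaluating it computes
   the longest common extension of the range, counting-sorts the range
   by the next character, and emits one child range per residue. A
   child is pursued only while it passes the support gate (counts are
   monotone under extension, so nothing is missed). Results go into an
   associative map keyed by context, so no suffix-tree structure or
   suffix links are ever materialised, and the enumeration can be
   partitioned into independent subtree tasks (`parallel_depth` levels
   of fan-out, 4 tasks per node on DNA) whose private buffers merge
   deterministically.

2. **Similarity pruning.** Estimate p̂(σ|w) = (N(wσ)+1)/(Σ_c N(wc)+4)
   (+1 pseudo-counts) and remove, leaf-first, every context *cw* with

   Δ_cw = N(cw) · Σ_σ p̂(σ|cw) ln( p̂(σ|cw) / p̂(σ|w) ) < K.

   The default K = 3.9075 is half the χ² critical value at
   |Σ|−1 = 3 degrees of freedom and p = 0.05.

Scoring computes −Σ_t ln p̂(x_t | longest stored suffix of the
history). Model selection evaluates BIC = card(M)·ln|S| − 2·ln P_M(S)
with card(M) = (|Σ|−1) · (number of leaf contexts) over a grid of
(t, L) and reports the minimising cell, along with the frequency of the
5% least common deepest k-mers.

## Worked example

```
$ python -c "
from vlmc import encode_corpus, train, negative_log_likelihood, leaves
corpus = encode_corpus(['CACAC'])
model, report = train(corpus, min_count=1, max_depth=2, kl_threshold=0.0)
print(sorted(model.nodes))
res = negative_log_likelihood(model, 'CAC')
print(round(res.total_nll, 4), res.positions_scored)
"
['', 'A', 'AC', 'C', 'CA']
2.1972 3
```

The unpruned depth-2 model of `CACAC` has five contexts. Scoring the
query `CAC` multiplies p̂(C|"") = 4/9, p̂(A|C) = 1/2 and p̂(C|CA) = 1/2,
giving −ln(1/9) ≈ 2.1972 nats over 3 scored positions. With the
default threshold K = 3.9075 every context in this tiny corpus is
pruned back into the root: five symbols of data cannot justify any
conditioning.

The same pipeline from the shell:

```
vlmc stats    --fasta genome.fa
vlmc train    --fasta genome.fa -t 10 -L 8 --parallel-depth 2 --out model.tsv
vlmc score    --model model.tsv --fasta queries.fa
vlmc bic      --fasta genome.fa --min-counts 2,10,100 --max-depths 3:12 --out grid.tsv
vlmc simulate --order 2 --kl-floor 0.2 --length 100000 --seed 1 --out sim.fa
```

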