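# Methods

This note describes what `kgner` computes, layer by layer, and the choices
made where the mathematics leaves freedom.

## Problem

Named entity recognition as BIO sequence labeling: given tokens
`x_1 … x_n`, predict tags `O`, `B-<cat>`, `I-<cat>`. The motivating
difficulty is surface ambiguity — the same string is sometimes an entity and
sometimes a plain word — which token context alone may not resolve, but a
knowledge graph (KG) of entity dependencies can: the presence of a KG
neighbor of the candidate entity elsewhere in the sentence is evidence that
the candidate is a genuine mention.

## Pipeline

### 1. Token encoding

A pluggable encoder maps tokens to a matrix `S ∈ R^{n×d}`. The reference
implementation is a trainable lookup table (row per vocabulary word, one
shared out-of-vocabulary row, `N(0, 0.1)` initialization). The encoder
contract (`__call__(words) -> (len(words), d)` array plus a `d` attribute)
accepts contextual/transformer encoders as drop-in plug-ins; nothing
downstream changes except the recommended learning rate (1e-2 for the
lookup table, of the order 1e-5 for fine-tuned transformers).

### 2. Entity matching and the sentence graph

Sentence tokens are matched against the KG lexicon by greedy left-to-right
longest n-gram match (default up to 6-grams), lowercased and
whitespace-normalized; matches never overlap. The matched nodes form the
vertex set of a per-sentence graph; its adjacency is the KG edge structure
restricted to those nodes, plus a forced self-loop on every node. An
`include_neighbors` option additionally pulls in first-order KG neighbors
of matched nodes; it is off by default because attention over co-mentioned
entities is exactly the signal that distinguishes a licensed mention from a
spurious dictionary hit — padding every neighborhood with the same KG
context would make the attention input independent of what else the
sentence actually mentions.

Node input vectors `V ∈ R^{m×d}` are the mean of the encoder embeddings of
the node's surface words (mean pooling keeps multi-word and single-word
surfaces on the same scale).

### 3. Graph attention

A single multi-head graph-attention layer. Per head `k` with projection
`W_k ∈ R^{d×d_h}` and attention vector `a_k ∈ R^{2 d_h}`:

    e_ij = LeakyReLU( a_k^T [ W_k v_i ‖ W_k v_j ] )
    α_ij = softmax over j ∈ N(i) of e_ij
    g_i  = LeakyReLU( Σ_{j∈N(i)} α_ij W_k v_j + r(v_i) )

Heads are concatenated: `H ∈ R^{m×K d_h}`. The residual `r` is the identity
when `d = d_h` and a learned linear projection `W_r ∈ R^{d×d_h}` otherwise
(a width-matching choice; the identity residual is recovered exactly when
widths agree). LeakyReLU slope is 0.2 everywhere. Inverted dropout
(default 0.2) is applied to the node inputs and to the attention weights
during training only.

All gradients are analytic: the backward pass works the softmax and
LeakyReLU chain rule out in closed form, and the test suite checks every
parameter against central finite differences.

### 4. Fusion

Knowledge vectors are scattered back to token positions: a token inside a
matched span receives its node's row of `H`; unmatched tokens receive
zeros, so for them the knowledge path contributes exactly nothing. Fusion
is linear:

    F = S W_1 + H_tok W_2,   W_1 ∈ R^{d×d_f}, W_2 ∈ R^{K d_h × d_f}

Freezing `W_2 = 0` therefore disables the knowledge path exactly — the
"none" ablation is implemented this way, which guarantees it is the same
model family with the knowledge term removed, not a separate code path.

### 5. CRF

Emissions `E = F W_out` (no bias: a per-label constant is absorbed by the
transition matrix, and dropping it keeps the parameterization minimal) feed
a linear-chain CRF with transitions `T ∈ R^{(L+1)×L}` (row `L` holds start
scores; no explicit stop scores). Training minimizes the exact
sentence-level negative log-likelihood; the partition function is computed
by the forward recursion in log space, and the gradient is
`marginals − one-hot` via forward–backward. Decoding is exact Viterbi;
argmax ties break to the lowest label index. Decoded sequences are passed
through a BIO repair step (`I` after `O` or after a different category
becomes `B`), so predictions are always legal.

## Training

All parameters — embedding table, GAT, fusion, CRF — are trained jointly
with Adam (β = 0.9/0.999) on mini-batch mean NLL. Model selection keeps the
epoch with the best dev entity F1. Runs are pure functions of the seed:
data order, dropout masks and initialization each use a dedicated seeded
stream, and the parameter draw order is fixed across ablations so all three
start from identical shared weights.

Ablations: `relation` (full sentence graph with KG edges), `concept`
(matched nodes with identity adjacency — node identity information without
dependencies), `none` (`W_2` frozen at zero).

## Evaluation

Entity-level scores use exact-span matching (start, end, category),
micro-aggregated. Token-level scores are one-vs-rest per BIO role. F1 is
the harmonic mean of precision and recall; zero denominators yield 0 with a
flag rather than an error. Percentages are rounded half-up to two decimals
at rendering only; aggregation across seeds uses full precision and the
sample (n−1) standard deviation.

## Synthetic benchmark

Because the real BioNER corpora and biomedical KGs cannot ship with the
package, `kgner.synth` generates a self-contained emulation:

* entities with pronounceable pseudo-word surfaces (1–3 words), disjoint
  from the distractor vocabulary, organized into three categories with
  "same as" alias edges and cross-category dependency edges;
* a fraction `p_amb` (default 0.4) of entity surfaces is ambiguous: such a
  surface occurs in sentences both as a labeled mention and as plain text,
  and the occurrence is a mention **iff** an unambiguous KG neighbor (a
  cue) is co-mentioned. Every ambiguous entity is guaranteed a cue
  neighbor. Mentions are drawn from base entities, so the operative
  ambiguity rate in the corpus equals `p_amb`;
* a fraction of multi-word surfaces shares its first word with a surface
  of a different category, so concept-level knowledge has measurable value
  even without edges;
* splits are disjoint at the token-sequence level, and generation is a
  pure function of the configuration and seed.

This construction has a known ceiling, which the tests verify: a plain
dictionary tagger is perfect when `p_amb = 0` and provably imperfect when
`p_amb > 0`, while the dictionary plus the KG cue rule is perfect always —
i.e. the dependency signal is sufficient, and the headline experiment asks
whether the trained model extracts it. At the default study conditions the
mean test F1 over three seeds orders `relation > concept > none` with a
gap of several F1 points between the full model and the knowledge-free
baseline.

**Limitations.** The generator is an idealization: cue sufficiency is
absolute rather than statistical, sentence "syntax" is a bag of distractor
words, and mention boundaries are unambiguous by construction (mentions are
always flanked by distractors). It measures whether the architecture can
route and use relational evidence — not biomedical language understanding.

## Desk-scale defaults

The benchmark model uses `d = 24`, `K = 2` heads, `d_h = 12`, 10 epochs,
batch 35, learning rate 1e-2, dropout 0.2. These sizes keep a full
3-ablation × 3-seed sweep on one CPU within a few minutes while leaving
the ablation ordering clearly resolvable; they are a deliberate scale
choice for a self-contained, reproducible experiment, not a claim about
optimal capacity.
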