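# Methods

`wheatrex` extracts structured facts — (head entity, relation, tail
entity) triples — from variety-description text in the wheat-germplasm
domain, where one variety name typically carries many unit-bearing
attribute values in a single sentence. This note documents the model, the
training procedure, the synthetic benchmark, and the numerical and design
choices the implementation makes.

## The model

### Character encoding with lexicon-word fusion

Sentences are processed per Unicode character. Characters are embedded
(learned embedding plus learned positional embedding, layer-normalised)
and passed through a stack of `L` post-norm Transformer encoder layers
(multi-head self-attention, GELU feed-forward of width `2·d_h`).

Lexicon information enters once, after layer `N` (`fusion_layer`). For a
word-vector table (word2vec text format), every character position `i` is
paired with up to `m` candidate words — the table words that occur in the
sentence as a contiguous substring covering position `i`. Candidate-word
vectors `c_ij` (width `word_dim`, linearly projected to `d_h`) are scored
against the character state `z_i` with a bilinear attention form and added
back:

    a_i  = softmax(z_i · W_attn · C_i^T)          (over the m candidates)
    c̃_i  = Σ_j a_ij · c_ij
    h̃_i  = z_i + c̃_i

The fused states pass through the remaining `L − N` layers, producing the
deep fusion representation `M1`. `N = 1` is the default (fusing early lets
the upper layers mix character and word evidence); `N = L` degenerates to
shallow "encode fully, then fuse once", an identity the test suite checks
bitwise to 1e-5.

Positions with fewer than `m` matches are padded with a designated PAD
slot carrying the all-zero vector. By default PAD slots participate in the
softmax unmasked — the interference of PAD padding at large `m` is a real
property of this fusion scheme — and a `mask_pad` switch excludes them.
Candidate sets larger than `m` keep the `m` longest words (ties: earlier
occurrence, then lexicographic), on the grounds that longer lexicon words
carry more boundary information.

Matching is sentence-occurrence based, not dictionary-wide character
containment: a word is only a candidate where it actually occurs in the
sentence, which keeps candidates context-relevant (the usual convention of
lattice-style lexicon augmentation). The scan is bounded by
`max_word_len` (default 8 characters).

### Bidirectional semantic encoding

A BiLSTM over `M1` — one forward and one backward pass of hidden size
`d_h/2` each, concatenated per position — yields `M2`. The per-direction
size is half the hidden width so that `M2` keeps width `d_h`: the subject
vector is later *added* elementwise to `M2`, so widths must agree. With
`use_bilstm: false` (ablation), `M2 := M1`.

### Cascading pointer extraction

Entity spans are tagged with the "01" pointer scheme: a sigmoid start
probability and a sigmoid end probability per character,

    p_i^start = σ(w_start · M2_i + b_start),   p_i^end = σ(w_end · M2_i + b_end),

thresholded at 0.5 (configurable; the comparison is strict, `p > t`).
Spans are reconstructed by the principle of proximity: scanning left to
right, each start marker pairs with the nearest end marker at or after it;
the span covers start through that end inclusive. Starts with no
following end are dropped; one end may serve several starts; nested or
overlapping decoded spans are all kept.

The cascade then conditions on each decoded head: the subject vector
`v_sub` is the arithmetic mean of `M2` over the head span (the minimal
span-to-vector pooling), and for every relation `r` in the schema a
relation-specific affine start/end tagger scores `M2_i + v_sub`. Each
relation's tail spans are decoded with the same proximity rule, and every
(head, r, tail) combination is emitted. Because every head is revisited
for every relation, a single head span can yield arbitrarily many triples
— the single-entity-overlap structure that flat sequence labelling cannot
express. All decoded heads are processed at inference (not only the
top-scoring one).

## Training

Supervision converts gold spans to "01" labels: head start/end sequences
pool all gold head spans of a sentence; tail labels are kept per
(gold head, relation). Each step supervises the head taggers on the full
sentence and — teacher forcing — samples one gold head uniformly and
supervises its relation-specific tail taggers, with all other relations'
labels zero.

The objective is binary cross-entropy, aggregated as the head taggers'
mean plus the tail taggers' mean (equal weight per cascade stage), with
tail positives up-weighted by the schema size `R`. Both choices address
label sparsity: a sentence of length `n` has ~2 positive head cells among
`2n` and a handful of positive tail cells among `2·n·R`; a single pooled
unweighted mean lets the negatives pin all probabilities to zero and the
taggers never leave the trivial optimum. BCE is computed from logits in
the stable `max(x,0) − x·t + log(1+e^{−|x|})` form; the probability-space
`pointer_loss` used for metrics clips at `1e-7`.

Optimisation is Adam with gradient clipping at global norm 1.0.
Mini-batches (default 4 sentences) accumulate per-sentence gradients
before each step. Training is deterministic given the seed: weight
initialisation, shuffling and subject sampling all derive from
`numpy.random.default_rng`.

Defaults: the desk-scale configuration is 2 encoder layers of width 64
(4 heads), `m = 3`, fusion after layer 1, learning rate `3e-3` — chosen
during development as the smallest setup that reliably memorises small
corpora; from-scratch tiny models need a far larger rate than the
fine-tuning regime of a pretrained 12×768 encoder, for which presets ship
(`EncoderConfig.full_scale_preset()`: 12 layers × 768, 256-character sentences,
200-dim word vectors; `TrainConfig.full_scale_preset()`: Adam, lr `1e-5`,
batch 4).

## Evaluation

Exact match: a predicted triple is correct iff head span, relation label
and tail span all equal a gold triple; spans compare by character offsets
(a `text_only` flag relaxes to surface strings). With `N_pred`,
`N_pred^right`, `N_gold` the predicted / correct / gold counts,
`P = N_pred^right / N_pred`, `R = N_pred^right / N_gold`,
`F1 = 2PR/(P+R)`; `P := 0` when nothing is predicted and `F1 := 0` when
`P + R = 0`. Scores are micro-averaged over sentences.

## The synthetic benchmark

No public corpus with this annotation exists at desk scale, so the
package ships a generator that emulates the structure of variety-approval
text: one generated variety name per sentence (romanized by default, e.g.
"Zhongmai 159"-style tokens, so fixtures stay readable while processing
remains strictly character-level; `language="zh"` emits the same structure
with Chinese templates) followed by 2–6 attribute clauses drawn
from a 23-relation schema, with unit-bearing numeric tails ("827 g/L",
"14.8%") or categorical values. Every sentence therefore exhibits
single-entity overlap by construction. A distractor clause — a number
attached to no relation — appears with probability 0.3 to exercise
false-positive control. The accompanying word-vector table contains every
unit token, relation-cue token and categorical value with unit-normalised
random vectors (dimension 200 by default), plus random filler words up to
the configured size, so candidate matching sees the same boundary cues
(e.g. "g/L") a real domain lexicon would supply.

What the generator does **not** emulate: real lexical variety and
paraphrase, annotation noise, relation-frequency imbalance, long-range
head–tail dependencies, multiple head entities per sentence, and word
vectors with genuine distributional semantics (the vectors are random
identities, informative only as boundary/identity cues). Passing the
benchmarks therefore demonstrates that the architecture learns and decodes
the overlap structure correctly at desk scale — not that it reaches any
particular accuracy on real germplasm text.

## Benchmark procedures and sizes

* **Overfit check** — 50 generated sentences, the tiny configuration,
  up to 200 epochs with early stopping once train F1 ≥ 0.92 (evaluated
  every 10 epochs), median over 3 seeds; passes at F1 ≥ 0.90.
* **Ablation check** — 500 generated sentences (400/50/50 split), the
  full model vs fusion-off vs BiLSTM-off, 6 epochs each, 3 shared seeds;
  the full model's median held-out F1 must not fall below either
  ablation's. Training is deliberately short: the ablations differ most
  in learning speed, which is where the lexicon boundary cues and the
  recurrent layer contribute.

These problem sizes were chosen so the whole suite runs in minutes on one
CPU core.

## Numerical choices and edge cases

* float64 throughout; the recurrent layer is a fused primitive with a
  hand-written backward pass, gradient-checked against central
  differences (as are all other operators).
* `σ(x) = (tanh(x/2)+1)/2` avoids overflow for any logit.
* Softmax subtracts the row maximum; fusion PAD masking uses a −1e9
  additive constant (an all-PAD position under masking degenerates to
  uniform weights over zero vectors, i.e. a zero increment).
* Empty sentences are rejected by the encoder; sentences longer than
  `max_len` are truncated (no sliding windows), and gold spans beyond the
  truncation point are excluded from supervision and evaluation.
* Spans are 0-based half-open internally; pointer labels mark the start
  position and the *inclusive* end position.
* Gold spans sharing a boundary share the same "1" — the pointer scheme is
  inherently shared — so decoding such conflicting gold is ambiguous;
  this is documented behaviour, not corrected.
* The word2vec-text loader rejects malformed headers, ragged rows,
  duplicate words and count mismatches, naming the offending line; an
  absent word is reported as a miss, never as a zero vector.

## Known limitations

* Entity types are not predicted — the model tags spans and relations
  only.
* No pretrained weights: the encoder trains from scratch, which is the
  point at desk scale but leaves paper-scale accuracy out of reach;
  `load_state_arrays` exists as a hook for external checkpoints.
* The schema size is configurable (the default ships the 23 attribute
  relations used throughout the tests).
* Per-sentence (unbatched) computation: simple and exact, but throughput
  is modest; the intended regime is corpora of hundreds to thousands of
  sentences.
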