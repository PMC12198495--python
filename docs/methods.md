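# Methods

## Problem setting

Named-entity recognition as BIO sequence labeling: given a pre-tokenized
sentence, assign each token `O`, `B-c`, or `I-c` over `M` entity classes.
The tagset has size `2M + 1` with a single `O` shared across classes —
the convention of the standard CoNLL-style corpora this package reads
(two columns, token TAB tag, blank line between sentences).  Tokenization
of raw text and IOBES/BILOU conversion are out of scope; inputs are
pre-tokenized files.

## Architecture

`emissions = h₃(FFN(MHA(BiGRU(E(x) + P))))`, then a linear-chain CRF over
the emissions.

* **Embedding.**  Tokens map to indices through a frequency-ordered
  vocabulary (descending count, lexicographic tie-break) with reserved
  PAD = 0 and UNK = 1.  PAD's embedding row is pinned to zero: zeroed at
  initialization and its gradient dropped before every optimizer step.
  Out-of-vocabulary tokens fall back to UNK.
* **Positional encoding.**  The standard sinusoidal table,
  `ω_k = 10000^(−2k/m)`.  Positional rows are added at padded positions
  too — simpler, and harmless because the CRF mask makes those positions
  inert (verified by the padding-invariance tests).
* **BiGRU.**  Per-direction hidden size is fixed at `m/2` so the
  concatenated output has width `m`, which keeps the residual connections
  downstream dimensionally consistent.  Hidden-state updates are gated by
  the mask, so the padded tail never leaks into real positions (this
  matters only for the backward direction, which visits padding first).
* **Attention.**  `h` heads with `d_q = d_k = d_v = m/h`; scores scaled by
  `1/√d_k` by default (`attention_scale="dk"` selects `1/d_k` instead).
  Masked keys receive a `−10⁹` additive bias before the softmax; in
  float64 the exponential underflows, so masked weights are exactly zero.
  The residual into the post-attention LayerNorm is the attention input
  (the BiGRU output).  `use_mha=False` removes the block entirely — the
  ablation configuration — and is recorded in checkpoints.
* **Feed-forward.**  `h₁: m→d_ff` with ReLU, `h₂: d_ff→m`, dropout (rate
  0.2 by default, training mode only), residual, LayerNorm with learnable
  gain/bias.  `h₃` is the tag-space projection.  With `n_encoders = N > 1`
  the whole BiGRU→attention→FFN block repeats with fresh parameters;
  default is one block.
* **CRF.**  Learned start and end boundary vectors plus the pairwise
  transition matrix — boundary scores are standard even where only
  pairwise transitions are described, and they are subsumed by the same
  "tag transition" role.  No hard BIO constraint is imposed during
  training; the transitions are learned freely.  An optional decode-time
  switch (`--constrain-bio`) adds a `−10⁴` penalty to transitions into
  `I-c` from anything other than `B-c`/`I-c` (and from the start).

## Training and decoding

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on the mean per-sentence CRF NLL,
learning rate 1e-3, batch size 32 by default, two epochs by default
(configurable — the toy overfitting runs use 200).  The padded length `d`
is the longest training sentence, fixed corpus-wide so the positional
table is built once; longer sentences at prediction time are an error,
never silently truncated.  One `numpy` generator seeded by the train
config drives initialization (Glorot-uniform projections, zero biases,
Gaussian embeddings), shuffling, and dropout, so runs are bit-reproducible
on a platform.  There is no development set, early stopping, or schedule.

Viterbi decoding breaks score ties toward the lowest tag index at every
argmax, making decoding deterministic.  The brute-force enumeration oracle
(`enumerate_decode`) keeps the first strictly best path in lexicographic
order; on exactly tied instances the two tie-break rules could in
principle pick different optimal paths, so tests assert exact *score*
equality always and path equality on continuous random instances, where
ties have probability zero.

The log-partition uses the forward recursion with per-step `logsumexp` in
log space; no scaling tricks.  Gradients flow through a batched
differentiable implementation whose values are tested to agree with the
single-sentence reference functions to 1e-10.

## The autodiff core

No deep-learning framework is part of the package's dependency set; the
encoder and CRF objective are built on `gruner.autograd`, a small
tape-based reverse-mode engine over float64 NumPy arrays (broadcasting
arithmetic, matmul, pointwise nonlinearities, reductions,
softmax/logsumexp, shape ops, gather/embedding, LayerNorm, dropout).
Every operation's gradient is validated against central finite differences
in the test suite, including a full gated-recurrence step and the batched
CRF NLL.  Float64 favors testability (tolerances of 1e-9 on the
positional table, 1e-6 on emissions) over speed; the models this package
targets are small enough that this is a good trade.

## Synthetic corpus generator

Emulates the structure the model assumes: a closed vocabulary split into
background tokens and per-class entity lexicons, all mutually disjoint;
sentences built position by position, starting an entity with probability
`entity_rate` (length uniform on `entity_length_range`, clipped at the
sentence end, tagged `B-c I-c …`), otherwise emitting a background token
tagged `O`.  Defaults: 100 sentences of 5–12 tokens, vocabulary 120, two
classes (Gene, Disease), entity rate 0.15, entity length 1–3 — a small
two-class corpus dense enough in entities that a narrow model can overfit
it quickly, which is what the end-to-end learnability check needs.  The
disjoint-lexicon choice makes the token→class mapping learnable without
context, so that check validates the training loop rather than the
corpus's ambiguity.  The generator does **not** reproduce real PubMed
token frequencies, class imbalance, nested or discontinuous mentions, or
annotation noise — passing the overfit test demonstrates that the
architecture, loss, gradients and decoder work, not that benchmark-level
accuracy on real corpora is attained.

The expected entity-token fraction implied by the sampling scheme has a
closed recursive form (used as an independent oracle in the tests):
`f(n) = r·E_G[min(G,n) + f(n−min(G,n))] + (1−r)·f(n−1)` entity tokens
expected among `n` remaining slots.

## Evaluation

Token-level micro metrics pool per-token TP/FP/FN over all sentences and
classes: TP when a non-`O` gold tag is predicted exactly; an entity-tag
substitution is both FP and FN, so FP = FN forces P = R.  Entity-level
metrics use exact `(start, end, class)` span matching; span extraction is
lenient — an orphan `I-c` opens a new span — so arbitrary model output has
well-defined spans.  Both modes are always available because published NER
results mix the two conventions; reports label the mode explicitly.
Zero-denominator convention: P (or R) is 0 when its denominator is 0, and
F1 is 0 when P + R = 0.

## Problem sizes

The test suite and the acceptance script run small instances by design:
CRF exactness on 200 random instances with L ≤ 5 and ≤ 5 tags (where
enumeration over all `K^L` paths is the oracle), parameter audits on
configurations with m ≤ 24, and training runs on the default 100-sentence
synthetic corpus with a narrow model (m = 32, h = 4, d_ff = 64, ≤ 200
epochs).  These sizes exercise every code path; nothing in the
implementation is specific to them.

## Known limitations

* CPU-only, float64, Python-loop recurrence: throughput is adequate for
  small corpora and tests, not for multi-million-token benchmark training.
* No pre-trained embeddings or subword modeling — by design the model
  learns only from the training corpus, so rare or unseen tokens rely on
  UNK and context.
* `device` in the train config accepts only `"cpu"`.
* Checkpoints are portable but bit-exact prediction reproducibility is
  guaranteed only on the platform that wrote them.
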