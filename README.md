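# gruner

A lightweight neural tagger for **named-entity recognition (NER)** on
CoNLL-style BIO corpora, aimed at biomedical text mining (gene, disease,
chemical and species mentions) but agnostic to the entity inventory.  It is
for practitioners who want a compact, trainable-from-scratch sequence
labeler — no pre-trained language model, no subword vocabulary — plus the
tooling around it: a corpus reader/writer, a synthetic-corpus generator for
testing, training/prediction/evaluation commands, and token- and
entity-level metrics.

## The model

A sentence is a token sequence `x = (t_1 … t_n)`; each token carries one of
`2M + 1` tags over `M` entity classes: `O`, or `B-c` / `I-c` marking the
beginning / inside of a class-`c` mention.  The tagger scores tags with an
encoder–decoder stack:

1. **Embedding + sinusoidal positions.**  Token embeddings `E(t) ∈ R^m`
   (padding embeds to the zero vector) plus the fixed positional features
   `P[t, 2k] = sin(t·ω_k)`, `P[t, 2k+1] = cos(t·ω_k)` with
   `ω_k = 10000^(−2k/m)`.  Sequences are right-padded to `d`, the longest
   training sentence.
2. **BiGRU.**  A forward and a backward gated recurrent unit, `m/2` hidden
   units each, concatenated so every position sees left and right context
   at width `m`.
3. **Multi-head self-attention** (optional, `--no-mha` ablates it):
   `h` heads of `softmax(QKᵀ/√d_k)·V` with `d_k = m/h`, concatenated,
   projected, then residual + LayerNorm.  Padded keys get exactly zero
   attention mass.
4. **Feed-forward block.**  `LayerNorm(x + dropout(W₂·ReLU(W₁x + b₁) + b₂))`
   with hidden width `d_ff`, followed by the linear tag projection `h₃`.
5. **Linear-chain CRF decoder.**  Learned start/transition/end scores over
   tags; a path is scored
   `start[y₁] + Σ_t e_t[y_t] + Σ_t A[y_t, y_{t+1}] + end[y_L]`.
   Training minimizes the exact negative log-likelihood
   `log Z − score(y*)` (forward algorithm in log space); decoding is
   Viterbi.  Padded positions contribute nothing to either.

Defaults follow the compact recipe the architecture was designed around:
`m = 256`, `h = 4` (so `d_k = 64`), `d_ff = 512`, dropout 0.2, one encoder
block, Adam at learning rate `1e-3`.  Everything runs on NumPy via a small
reverse-mode autodiff core inside the package (`gruner.autograd`).

## Worked example

Generate a synthetic two-class corpus (disjoint gene/disease lexicons),
train, and evaluate on the held-out split:

```bash
gruner generate --out-dir demo --seed 7 --n-sentences 100
# wrote 80 train / 20 test sentences to demo
gruner train --train demo/train.tsv --out demo/model.ckpt --seed 7 \
             --epochs 150 --batch-size 16
# epoch=150 mean_loss=0.000017 wall=0.57s
# trained on 80 sentences; final mean loss 0.000017; checkpoint -> demo/model.ckpt
gruner evaluate --gold demo/test.tsv --checkpoint demo/model.ckpt --metric both
```

which prints (stderr table; a JSON report goes to stdout or `--out`):

```
token-level micro metrics
                    P        R       F1     TP     FP     FN
overall        0.8462   0.8302   0.8381     44      8      9
Disease        0.8182   0.7500   0.7826     18      4      6
Gene           0.8667   0.8966   0.8814     26      4      3
entity-level micro metrics
                    P        R       F1     TP     FP     FN
overall        0.7647   0.8125   0.7879     26      8      6
```

Token-level metrics count each token: a non-`O` tag predicted correctly is
a TP; substituting one entity tag for another counts as both an FP and an
FN, which is why balanced errors give identical precision and recall.
Entity-level metrics require an exact `(start, end, class)` span match —
stricter, hence lower.  Here the model generalizes imperfectly from 80
training sentences: e.g. 6 of 24 gold disease tokens in the test split are
missed (token recall 0.75 for that class).

Other subcommands: `gruner merge` concatenates corpora (class sets are
unioned), and `gruner predict` writes a tagged corpus file.  `--no-mha`
trains the attention-free ablation; `--constrain-bio` forbids illegal BIO
transitions at decode time.

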