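# Methods

This note documents the modeling decisions, default parameters, and the
limits of what the synthetic evaluation shows.

## Problem setting

The package targets semi-automatic intraoperative report writing: a surgeon
dictates 2–4 keywords per intended sentence; the system expands each keyword
group into a report sentence, conditioning on the previously generated
sentence so consecutive sentences connect.  The supervised unit is the
*training pattern* (initial sentence, target sentence, keywords of the
target), built by pairing consecutive sentences of each report.  A report
with n sentences yields n patterns: the first sentence's "initial sentence"
is a reserved placeholder token (`<START_REPORT>`), so generation can
produce a report opening from keywords alone.  A `skip_first` flag
reproduces the stricter n−1 reading in which only true sentence pairs are
used.

## Synthetic corpus

Real operation reports are protected; the generator emulates the corpus
regime the pipeline is designed for — 48 reports, 10–45 sentences each,
~1500 sentences total, ~8 words per sentence, 150 keywords, 2–4 keywords
per sentence — in an invented pseudo-German word language (no real text, no
identifying data).  Each keyword owns one phrase template of 2–3 words
containing the keyword surface, a synonym slot (3 interchangeable
companions by default) and sometimes a fixed third word.  A sentence is
realized by concatenating its keywords' templates in lexicographic keyword
order and inserting filler words with probability `noise_word_rate` (0.15)
per slot.  Per-report sentence counts are sampled uniformly from the range
and then nudged to the target total (exactness is not forced; ±10% is
accepted — in practice the default seed lands exactly on 1500).

Two properties matter for testing:

- **Learnability.**  Sentence text is a deterministic function of the
  keyword set up to synonym choice and filler noise, so a correctly
  implemented sequence model must be able to learn the mapping; the
  overfit and before/after tests rest on this.
- **Non-saturation.**  Synonyms and fillers keep pre-training metric scores
  far from 1.0, leaving headroom for training to produce a measurable lift.

What the generator does *not* emulate: clinical vocabulary and grammar,
surgeon-to-surgeon style variation beyond synonym/filler noise, dictation
errors, or keyword annotation noise.  Passing tests therefore demonstrate
that the pipeline's machinery is correct and that training produces the
qualitative effect (significant improvement on all metrics); they do not
calibrate absolute metric levels expected on clinical text.

## Tokenizer

A byte-pair-encoding subword tokenizer with a fixed vocabulary of exactly
*s* = 500 pieces (8 special tokens + alphabet + learned merges), trained on
raw corpus sentences.  Merges are ranked by corpus frequency with
lexicographic tie-breaking, making training fully deterministic.  BPE was
chosen over unigram-LM segmentation: both satisfy every contract that
matters here (exact size, determinism, reversibility, character fallback),
and greedy merges are simpler to reason about and to serialize (plain JSON
piece/merge lists).  Characters unseen in training map to `<unk>`;
everything else round-trips exactly.  The keyword block and the sentence
share one vocabulary.

Special tokens: `<pad> <unk> <bos> <eos> <kw> <kwsep> <sep>
<START_REPORT>`.  `<kw>` opens the keyword block, `<kwsep>` delimits
keywords, and a single `<sep>` separates the block from the initial
sentence, so pattern inputs carry exactly one block marker and one block
separator.

## Model

Shared embedding table → bidirectional 2-layer LSTM encoder → single-head
content-based attention → unidirectional 2-layer LSTM decoder → output
projection over the vocabulary.  The decoder is deliberately
unidirectional: an autoregressive decoder cannot condition on future
tokens, so "bidirectional" can only apply to the encoder.  Decoder initial
states come from the encoder's final forward/backward states through a
per-layer tanh bridge.  Attention projects decoder state and latent
features to a common width (the hidden size), scores them by scaled dot
product, and the softmax-weighted latent average is concatenated with the
decoder state before the output projection.

Defaults and presets:

| parameter | default | test preset | scaled experiment |
|---|---|---|---|
| embedding size | 512 | 32 | 64 |
| hidden size (per direction) | 256 | 32 | 64 |
| encoder / decoder layers | 2 / 2 | 2 / 2 | 2 / 2 |
| max decode length (tokens) | 60 | 100 | 60 |

The 512-token embedding matches the architecture the pipeline was designed
around; the smaller presets exist because the full-size model is
unnecessary to demonstrate correctness and would waste CI time.  The test
preset's `max_decode_length` of 100 accommodates the long subword
sequences a tiny (80-piece) vocabulary produces.

All tensors are float32 (float64 available for verification; the gradient
check runs in float64).  Forward/backward passes are hand-derived numpy;
the test suite validates every parameter family against central finite
differences, and masking is validated by a padding-invariance test.

## Training

Teacher-forced token-level negative log-likelihood, Adam
(β₁ = 0.9, β₂ = 0.999), global gradient-norm clipping at 1.0, batch 32,
early stopping on validation loss (patience 5).  The learning rate default
is 1e-2: at this package's scales (a few hundred optimizer steps per fold)
1e-3 measurably undertrains — validation loss stays near its initial value
and generations are degenerate — while 1e-2 with clipping is stable and
reaches near-verbatim reconstruction; this was fixed once from a seeded
sweep.  Batches are length-bucketed to limit padding waste and reshuffled
each epoch with an epoch-derived seed, so training is bit-reproducible
given the config seed.

Cross-validation partitions *reports* (never sentences) into k balanced
folds (k = 10 default; each fold 4–5 of 48 reports).  Within the left-in
reports, patterns are shuffled and split 85:15; the split happens before
augmentation so validation loss is always computed on unaugmented gold
patterns.  Augmentation (when enabled) only rewrites initial sentences —
targets are the supervision signal and keywords the conditioning, so
mutating either would corrupt the loss.

Augmentation operator semantics (the minimal standard readings): swap =
exchange one random adjacent pair; deletion = remove one random word
(skipped on length-1 input); addition = append one word drawn from a
configured unigram lexicon; insertion = the same draw at a random interior
position; synonym = replace one random word that has a synonym-table entry.
Operators apply independently with probability 0.1 each, at most 2 per
sentence; inapplicable draws are no-ops that do not consume the budget.

## Metrics

All four metrics are sentence-level in [0, 1]; report scores are arithmetic
means over sentences, paired positionally.

- **BLEU-2**: √(p₁·p₂)·BP with clipped n-gram counts; the bigram precision
  is add-one smoothed (unsmoothed sentence-level BLEU is degenerate on
  short sentences); p₁ = 0 short-circuits to 0.  Identical sentences score
  exactly 1.
- **ROUGE**: unigram recall with clipped counts (the prose definition of
  "how many words of the original are found in the generation"); no LCS
  variant.
- **COSS**: for each candidate token, the maximum cosine over reference
  tokens of the model-embedding vectors, negatives clamped to 0, averaged
  over candidate tokens.  The best-match direction (candidate → reference)
  is an interpretive choice: it is total, asymmetric and precision-like.
  Clamping repairs the range: raw cosines live in [−1, 1] but the metric's
  contract is 0 = orthogonal, 1 = identical.  COSS is computed on subword
  ids from each arm's own embedding table — the untrained model's random
  embeddings for the before arm, the trained fold model's for the after
  arm — because the metric is defined on the model's embedding layer and
  the untrained state has no other.
- **METEOR**: exact-surface one-to-one alignment (greedy, preferring
  continuation of the previous match, which minimizes chunks on the
  fixtures that matter), F = PR/(αP+(1−α)R) with α = 0.9, penalty
  γ(chunks/matches)^β with γ = 0.5, β = 3.  No stemming or synonym
  dictionaries.  Its maximum on identical m-word sentences is
  1 − 0.5·(1/m)³.

## Before/after experiment and statistics

The "before training" system is the seed-initialized untrained model — the
only well-defined pre-training state.  The "after" arm uses, for each
report, the model of the fold that held that report out, so no report is
ever scored by a model that saw it.  Report generation is fully
autoregressive across sentences: sentence i conditions on the *generated*
sentence i−1, not the gold one.

Wilcoxon signed-rank: zero differences excluded, mid-ranks for ties, W =
sum of negative-difference ranks, Z = (W − μ)/σ with tie-corrected σ and no
continuity correction by default (the convention of common statistics
packages; a `continuity` flag enables it), two-sided normal-approximation
p.  Uniform improvement over 48 pairs gives W = 0, Z = −6.031,
p ≈ 1.6×10⁻⁹.  For small samples the normal approximation is off by up to
~0.1 in mid-range p, so `method="exact"` computes the exact null
distribution of the rank sum by dynamic programming; the oracle tests
compare it against independent exhaustive sign enumeration.

## Problem sizes used in the shipped tests

Unit tests run on miniature corpora (4–6 reports).  The two end-to-end
checks run at the sizes quoted in the README: the overfit check (5
patterns, hidden 32, 200 epochs, ~1 minute) and the scaled experiment
(48 reports, ~1500 sentences, hidden/embedding 64, k = 3, 15 epochs,
~5 minutes on one CPU).  The scaled experiment keeps the full 48-report
corpus — the Wilcoxon n is the scientifically meaningful quantity — and
shrinks only model width, fold count and epochs.

## Known limitations

- The synthetic grammar is far easier than clinical language; absolute
  metric values do not transfer.
- Greedy report-level generation compounds errors across sentences (each
  sentence conditions on the previous generation); beam search mitigates
  but does not remove this.
- The METEOR chunk count uses a greedy alignment, not the exhaustive
  minimum; on heavily repetitive sentences it can overcount chunks.
- Encoder pretraining on an external German corpus is supported only as a
  hook (`opreport pretrain` on any plain-text file); no external data is
  fetched.
- The Wilcoxon Z values reported on clinical data depend on that private
  corpus; on synthetic data only the direction and significance pattern are
  reproducible, which is what the experiment asserts.
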