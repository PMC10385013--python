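# Methods

## Task and data model

The unit of classification is the *candidate instance*: one (sentence,
drug-pair) combination.  A sentence with *n* annotated drug mentions
yields C(n,2) = n(n−1)/2 candidates, each labelled with one of five
classes — `mechanism`, `effect`, `advice`, `int`, or `negative` when the
sentence asserts no interaction for that pair.  Corpora are read and
written in the SemEval-2013 Task 9 DDI XML dialect.  Character offsets
are stored with **inclusive** end positions (`charOffset="0-11"` covers
twelve characters), matching the dialect in the wild; discontinuous
mentions (`;`-separated spans) are parsed into multiple spans whose
surface fragments join with a single space, and downstream anchoring uses
the first span.  Unknown entity types are accepted with a warning and
mapped to `drug_n`.  Files are UTF-8.

## Candidate construction

Tokenization for the CNN route is deterministic: the punctuation
characters `.,;:()"/` are split into standalone tokens, then the text is
whitespace-split; each entity span is collapsed to a single anchor token
beforehand.  The target pair becomes `DRUG1` (earlier offset) and
`DRUG2`, all other drug mentions `DRUGN`, so the model generalizes over
drug names and each instance contains exactly one candidate pair.  If the
two target spans overlap and cannot be disjointly replaced, the instance
is constructed degenerately and flagged as a same-drug candidate.

Two rules flag trivially negative candidates:

1. **same_drug** — both surfaces are identical after case-folding, or
   belong to the same group in an optional user-supplied synonym table
   (no synonym source ships with the package).
2. **coordination** — every token strictly between the two anchors is a
   comma, `and`/`or`, or another drug anchor; i.e. the pair sits inside a
   plain coordination list.  Adjacent anchors (no tokens between)
   vacuously satisfy this and are treated as coordinated.

Flagging never changes labels and is idempotent.  Only *negative* flagged
candidates are removed from training; gold positives always survive.  At
evaluation time flagged candidates are not fed to the model but are
auto-predicted `negative`, so scores remain comparable with unfiltered
runs.  Whether filtering should also apply at test time is genuinely
unsettled; both behaviours are available (`MCPCNNBatcher(for_training=)`).

Relative positions are the signed token distances to the two anchors,
clipped to ±`max_dist` (default 60).  Instances are padded to a fixed
length with a zero-embedded PAD token; longer instances are truncated to
the smallest window containing both anchors, extended symmetrically.  The
sentence-length cap is interpreted in **tokens** (default 150), since the
model operates on token sequences and padding refers to embedding
indices.

For the transformer route drug names are *not* anonymized.  Inputs take
the entity-marker form `[CLS] … $ e1 $ … # e2 # … [SEP] [PAD]…` with
distinct markers for the two entities (`$`, `#`; configurable) — distinct
markers disambiguate the entities where a single shared marker could
not.  The entity positional id sequence carries 1 on e1's wordpieces, 2
on e2's, 0 on everything else including markers and control tokens.

## Embedding channels

Each channel is an independent word-embedding table (word2vec **text**
format; binary is out of scope) sharing one dimensionality *k*.  Channels
keep separate vocabularies: a word missing from one channel takes that
channel's out-of-vocabulary vector (a shared seeded Gaussian(0, 0.01)
draw by default; a zero-vector policy is available) while other channels
use their own rows — this cross-channel compensation is the point of the
multichannel design.  Two position tables per channel set, shaped
(2·max_dist+1) × k_pos with k_pos = 10 per entity, are initialized
uniform(−0.05, 0.05) from the seed.  One embedded row is
word ⊕ pos₁ ⊕ pos₂, width k + 2·k_pos; PAD rows are entirely zero.
k_pos = 10 keeps the row width at 220 for the k = 200 setting customary
for pretrained biomedical vectors.  Word and position tables are frozen
during training; only attention, convolution and classifier parameters
are updated, which keeps the computation graph lean and suffices for the
studies here.

## MCPCNN

Channels form a depth axis (the RGB analogy): one filter of window size
*h* spans all channels, with weight layout channel-major × window row ×
embedding dimension, which is equivalent to summing per-channel
convolutions.  Defaults follow the reference setting: window sizes
[3, 5, 7, 9], 128 filters per size, tanh nonlinearity, dropout 0.45,
batch 64, Adam 3×10⁻⁴, noise σ 0.1.  Weights are seeded Glorot-uniform,
biases zero.

Anchor positions map to feature-map coordinates by window start: map
position *i* belongs to the left segment iff i ≤ p1, the middle iff
p1 < i ≤ p2, the right otherwise — non-overlapping and covering.  An
empty segment pools to 0, keeping the pooled vector a fixed
3 × 128 × 4 = 1536 wide.  With the two boundaries pushed past the end of
the map, the first segment covers everything and piecewise pooling
degenerates to the global max.

The attention mechanism is input-level additive attention:
score_i = vᵀ·tanh(W·x̄_i) on the channel-mean row x̄_i, masked softmax
over non-pad tokens, and the embedded rows scaled by α_i · n_tokens so
the uniform case is an exact identity.  v is initialized to zero, making
the initial network attention-neutral.  No canonical formula exists for
this component; this additive form is the package's documented choice.

## Gaussian-noise layer

`NoiseConfig` exposes two schemes, both additive and training-only:

- **pre_classifier** (default): plain Normal(0, σ) added to the pooled
  feature vector just before dropout/softmax.  σ defaults to 0.1 for the
  CNN and 0.3 for the relation head — the best-performing values in the
  reference sweep over {0.1, 0.2, 0.3}.
- **embedding** (`NoiseConfig.word_insertion_scheme()`): each embedded
  component is selected with probability 0.3 and perturbed by a draw from
  a truncated Normal(μ=0, σ=1) restricted to [0, 0.3]; PAD rows are never
  perturbed.  This realizes the word-insertion description of the
  augmentation; the two parameterizations in circulation (unit σ
  truncated to a narrow band vs. small σ at the classifier) are both
  exposed rather than reconciled.

With σ = 0, or in evaluation mode, the noise layer is a bit-identical
pass-through, and the whole forward pass equals the noise-free graph.

## Relation head and tiny encoder

The head pools `[CLS]` by start pooling, the entity spans by average
pooling (default, per the reference description of entity
representations), and optionally the three context segments; empty
context segments (entity at the sentence edge) pool to zero.  Each pooled
part passes an affine+tanh projection; enabled parts concatenate, and an
optional interaction block appends h_e1 ⊙ h_e2 (dot) or |h_e1 − h_e2|
(absdiff).  Context features and interactions default to off.  The
relation vector length depends only on the configuration, never on
sentence length.  Dropout is 0.1, noise σ 0.3, five output classes.

The shipped encoder is a deliberately small seeded bidirectional
self-attention encoder (2 layers, width 16, single head, tanh
feed-forward blocks, residual connections, no layer normalisation — at
this scale training is stable without it).  Entity positional embeddings
(3 rows) are added to the input embedding sum and trained end-to-end.
The encoder is an interface: genuinely pretrained biomedical weights can
be plugged in by supplying any callable with the same signature, but no
pretrained weights ship and no result here depends on them.

## Training and evaluation

Adam on cross-entropy; the validation split is 10% of sentences
(sentence-level, leakage-free, seeded).  After each epoch the validation
micro-F1 is logged; early stopping uses patience 10 (the reference names
early stopping over 100 epochs without a patience value), ties broken by
the earliest epoch, and the best-on-validation state is restored.  An
optional convergence target stops training once reached.  A non-finite
loss aborts with diagnostics.  Runs are exactly reproducible given the
seed (shuffling, dropout masks and noise draws all derive from it).

Micro P/R/F1 pool TP/FP/FN over the four positive classes only, the DDI
detection-and-classification convention; an all-class micro variant is
reported alongside, since published F1 figures do not always state which
pooling they use.  The 5×5 confusion matrix is reported as counts and
row-normalized proportions; 0/0 ratios are 0.  The scorer is backed by
scikit-learn and cross-checked in the tests against an independent
hand-count oracle.

## Synthetic corpus generator

The generator emulates the annotated-corpus and embedding-channel inputs.
Each positive sentence embeds exactly one class-specific trigger phrase
around its target pair, drawn from a small template lexicon per class
(dosing recommendations for `advice`, outcome wording for `effect`,
pharmacokinetic wording for `mechanism`, underspecified interaction
statements for `int`); negatives use distractor templates with no
trigger.  With probability `p_coordination` a negative sentence becomes a
pure comma/conjunction drug list (rule-2 fodder; default 0.3), and with
`p_duplicate_name` a second mention with an identical surface is inserted
(rule-1 fodder; default 0.05, kept low as such duplicates are rare in
real abstracts).  Extra drugs beyond the target pair appear in a trailing
coordination clause.  Class proportions default to uniform (0.2 each) so
every class, including the small `int` class, is well exercised; drug
names are pronounceable CV-syllable strings drawn from a 400-name pool;
2–4 drug mentions per sentence (the worked three-drug example sits in
the middle of this range).  A JSON ledger records every draw — label,
template, target pair, and all filter-eligible pairs — and serves as
ground truth for the stochastic tests.

Synthetic embedding channels draw base rows from Gaussian(0, 1/√k); words
in a class's trigger lexicon additionally receive that class's unit
offset direction scaled by a per-channel factor, making trigger rows
linearly separable by construction.  The classification task is therefore
learnable by design: parameter-recovery runs demonstrate that the
implementation can extract a signal the generator provably planted, not
that the models reach any particular accuracy on real biomedical text.
Real corpora differ in ways the generator does not emulate: heavily
skewed class balance, long complex sentences, nested and discontinuous
mentions, lexical ambiguity between classes, and annotation noise.

## Problem sizes and numerical choices

The recovery studies use a 2000-sentence synthetic corpus (250 documents
× 8 sentences) for the CNN with 2 embedding channels of dimensionality
64 and pad length 48 — synthetic sentences are short, and the planted
signal does not require high-dimensional channels — and a 200-sentence
separable toy (one pair per sentence) for the relation head with the
16-wide encoder.  Model hyperparameters stay at their defaults in both.
All arithmetic is float64.  Max-pooling ties route gradients to the first
argmax.  Empty pooled segments contribute exact zeros to value and
gradient.  Masked softmaxes use a −1e30 offset on excluded positions.
The absolute-value interaction uses the sign-times-value form, whose
gradient is correct almost everywhere.

## Known limitations

- No GPU path and no mixed precision; the NumPy backend is intended for
  desk-scale studies, not full-corpus training.
- Published full-corpus F1 figures require the licensed DDIExtraction2013
  corpus, pretrained biomedical embeddings/encoder weights, and long
  fine-tuning runs; none of that is reproduced here.
- Named-entity recognition is out of scope: entities are taken from the
  corpus annotations.
- The attention formula is a documented stand-in (see above); no claim is
  made that it matches any particular prior implementation.
- Dependency parsing, POS tagging and shortest-dependency-path features
  used by some competing systems are deliberately absent.
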