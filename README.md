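# ddigauss

Relation extraction for **drug–drug interactions (DDIs)**: given a sentence
with annotated drug mentions, decide for every pair of mentions whether the
sentence asserts an interaction and of which kind — `mechanism`, `effect`,
`advice`, `int` (interaction stated without detail) or `negative`.  The
package implements the full pipeline for corpora in the SemEval-2013 Task 9
DDI XML dialect, two Gaussian-noise-augmented classifiers, and a synthetic
corpus generator so everything runs end-to-end with no external downloads.
It is aimed at biomedical text-mining practitioners and at anyone studying
additive-noise data augmentation for relation classification.

## Models

**Multichannel piecewise CNN (MCPCNN).**  A sentence with *n* drugs yields
C(n,2) = n(n−1)/2 candidate instances; in each, the target pair is
anonymized to `DRUG1`/`DRUG2` and other drugs to `DRUGN`.  Each token *i*
is embedded per channel as

    x_i = w_i ⊕ p_i^(1) ⊕ p_i^(2),

a word vector concatenated with two position vectors indexed by the signed
distance to the two anchors.  Channels (independent embedding tables, RGB
analogy) form a depth axis; filters of window sizes h ∈ {3,5,7,9} compute
c_i = tanh(w ∗ x_{i:i+h−1} + b), giving a feature map c ∈ R^{n−h+1}.
**Piecewise max pooling** takes segment maxima left of `DRUG1`, between the
anchors, and right of `DRUG2` (empty segment → 0), preserving coarse
sentence structure that a global max discards.  An input-level additive
attention re-weights token rows before convolution.  The pooled vector z
receives additive Gaussian noise (training only), dropout, and a softmax
head o = z·W_s + d over the five classes.

**Entity-marker relation head (R-BERT style).**  The sentence is encoded
with entity markers (`[CLS] … $ e1 $ … # e2 # … [SEP]`) and an entity
positional id sequence (1 on e1 tokens, 2 on e2, 0 elsewhere) added to the
encoder's input embeddings.  From the encoder's hidden states the head
pools `[CLS]` (start pooling), the two entity spans (average pooling by
default; max/self-attention also available) and optionally the three
context segments, projects each through affine+tanh, concatenates, and
applies Gaussian noise (σ = 0.3 default), dropout and softmax.  The
encoder is pluggable; a small seeded self-attention encoder ships for CPU
use.

**Gaussian-noise layer.**  Two schemes: plain Normal(0, σ) added to the
feature vector just before the classifier (default; σ = 0.1 for the CNN,
0.3 for the relation head), or the word-insertion scheme w'_j = w_j + x_j
with x_j drawn from a truncated Normal(0, σ) restricted to [0, 0.3] and
applied to each embedded component with probability 0.3.  Noise is active
in training passes only.

**Scoring** follows the DDI convention: micro precision/recall/F1 with
TP/FP/FN pooled over the four positive classes (negatives excluded), plus
per-class scores and a 5×5 confusion matrix.  Two filtering rules flag
trivially negative candidates (same-surface pairs; pairs inside pure
comma/conjunction coordination lists); flagged candidates are excluded
from training but auto-predicted negative at evaluation so every gold
pair is scored.

## Worked example

Candidate generation on a three-drug sentence:

```python
from ddigauss import Sentence, EntityMention, generate_candidates

text = "Aminoglutethimide decreases the effect of coumarin and warfarin"
ents = [EntityMention(f"e{k}", [(text.index(n), text.index(n) + len(n) - 1)],
                      "drug", n)
        for k, n in enumerate(["Aminoglutethimide", "coumarin", "warfarin"])]
for inst in generate_candidates(Sentence("s0", text, ents)):
    print(f"({inst.e1_surface}, {inst.e2_surface}): {' '.join(inst.tokens)}")
```

prints the three enumerated pairs (C(3,2) = 3), each anonymized for its
own target pair:

```
(Aminoglutethimide, coumarin): DRUG1 decreases the effect of DRUG2 and DRUGN
(Aminoglutethimide, warfarin): DRUG1 decreases the effect of DRUGN and DRUG2
(coumarin, warfarin): DRUGN decreases the effect of DRUG1 and DRUG2
```

A complete shell session on a generated corpus:

```bash
$ printf 'n_documents: 25\nsentences_per_document: [8, 8]\ndrugs_per_sentence: [2, 2]\np_duplicate_name: 0.0\n' > toy.yml
$ ddigauss synth --spec toy.yml --seed 11 --out toy.xml --ledger toy_ledger.json
wrote 200 sentences to toy.xml
$ ddigauss parse toy.xml --stats
parsed 25 documents
documents     25
sentences    200
pairs        212
negative      45
mechanism     31
effect        37
advice        55
int           44
$ printf 'train_cfg:\n  batch_size: 16\n  learning_rate: 0.001\n  max_epochs: 12\n  patience: 12\n  target_f1: 0.95\nmodel:\n  d: 16\n  max_len: 48\n' > rbert.yml
$ ddigauss train --model rbert --train toy.xml --config rbert.yml --seed 11
 epoch  train_loss  val_micro_f1
     0    1.888127      0.500000
   ...
     9    0.174547      0.967742
validation micro-F1: 0.9677
```

The training table logs the mean cross-entropy per epoch and the micro-F1
on the held-out 10% sentence-level validation split; training stops once
the convergence target is reached and the best-on-validation parameters
are kept.  `ddigauss train --model mcpcnn` runs the CNN the same way, and
`ddigauss candidates` / `ddigauss evaluate` expose the preprocessing and
the scorer separately.

## Layout

- `src/ddigauss/corpus_io.py` — DDI XML reader/writer, validation, stats
- `src/ddigauss/candidates.py` — pair enumeration, anonymization,
  filtering rules, position encoding, padding, entity-marker inputs
- `src/ddigauss/embeddings.py` — word2vec-text channels, position tables,
  instance embedding
- `src/ddigauss/mcpcnn.py`, `src/ddigauss/rbert.py` — the two models
- `src/ddigauss/autodiff.py` — minimal reverse-mode engine they share
- `src/ddigauss/training.py`, `src/ddigauss/metrics.py` — training loop,
  split, early stopping; DDI micro-F1 and confusion matrices
- `src/ddigauss/synthetic.py` — corpus and embedding-channel generator
- `docs/methods.md` — modelling assumptions, parameter choices, and
  limitations
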