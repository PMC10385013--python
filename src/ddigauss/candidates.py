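"""Candidate-instance construction for DDI classification.

A sentence with *n* annotated drug mentions yields ``C(n,2) = n(n-1)/2``
candidate instances, one per unordered pair.  For the piecewise-CNN route
the target pair is anonymized to ``DRUG1``/``DRUG2`` (offset order) and
every other drug mention to ``DRUGN``, so the classifier generalizes over
drug names and each instance contains exactly one candidate pair.  Two
rules flag trivially negative candidates:

* rule 1 (``same_drug``)    — both mentions have the same case-folded
  surface (or are listed as synonyms in a user-supplied table);
* rule 2 (``coordination``) — the mentions sit in a plain coordination
  list, i.e. every token strictly between the two anchors is a comma, a
  conjunction (``and``/``or``) or another drug anchor.

Flagged candidates keep their gold label; only *negative* flagged
candidates may be dropped from training, and at evaluation time flagged
candidates are auto-predicted negative so the scorer still sees every
gold pair.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

from .corpus_io import DrugPair, EntityMention, Sentence

DRUG1, DRUG2, DRUGN = "DRUG1", "DRUG2", "DRUGN"
PAD_TOKEN = "<PAD>"
_ANCHORS = {DRUG1, DRUG2, DRUGN}
_COORD_TOKENS = {",", "and", "or"}

#: punctuation separated into standalone tokens before whitespace splitting
_PUNCT_RE = re.compile(r'([.,;:()"/])')


def tokenize(text: str) -> list[str]:
    """Whitespace tokenizer with punctuation split off into own tokens."""
    return _PUNCT_RE.sub(r" \1 ", text).split()


@dataclass
class CandidateInstance:
    sentence_id: str
    pair_id: str
    tokens: list[str]
    p1: int
    p2: int
    dist_e1: list[int]
    dist_e2: list[int]
    label: str
    e1_surface: str = ""
    e2_surface: str = ""
    filtered: bool = False
    filter_reason: str = "none"  # none | same_drug | coordination
    pad_mask: list[bool] | None = None  # True on real tokens, set by padding

    def to_json(self) -> str:
        d = {
            "sentence_id": self.sentence_id,
            "pair_id": self.pair_id,
            "tokens": self.tokens,
            "p1": self.p1,
            "p2": self.p2,
            "dist_e1": self.dist_e1,
            "dist_e2": self.dist_e2,
            "label": self.label,
            "e1_surface": self.e1_surface,
            "e2_surface": self.e2_surface,
            "filtered": self.filtered,
            "filter_reason": self.filter_reason,
            "pad_mask": self.pad_mask,
        }
        return json.dumps(d, sort_keys=False)

    @classmethod
    def from_json(cls, line: str) -> "CandidateInstance":
        return cls(**json.loads(line))


@dataclass
class BertInput:
    """Entity-marker input for the transformer relation head."""

    tokens: list[str]
    entity_pos_ids: list[int]  # 1 on e1 tokens, 2 on e2 tokens, 0 elsewhere
    attention_mask: list[int]
    label: str
    e1_span: tuple[int, int]  # token-index span of e1 (inclusive)
    e2_span: tuple[int, int]
    sentence_id: str = ""
    pair_id: str = ""


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _anonymize(sentence: Sentence, e1: EntityMention, e2: EntityMention,
               others: list[EntityMention]) -> tuple[list[str], bool]:
    """Replace entity first-spans with anchor tokens.

    Returns (tokens, overlap_flag); overlap_flag is set when the two target
    spans overlap and cannot be disjointly replaced (the earlier one wins).
    """
    repl: list[tuple[tuple[int, int], str]] = []
    s1, s2 = e1.first_span(), e2.first_span()
    overlap = _spans_overlap(s1, s2)
    repl.append((s1, DRUG1))
    if not overlap:
        repl.append((s2, DRUG2))
    taken = [span for span, _ in repl]
    for ent in others:
        span = ent.first_span()
        if any(_spans_overlap(span, t) for t in taken):
            continue  # nested/overlapping secondary mention: leave as text
        repl.append((span, DRUGN))
        taken.append(span)
    repl.sort(key=lambda r: r[0][0])
    pieces, cursor = [], 0
    for (start, end), anchor in repl:
        pieces.append(sentence.text[cursor:start])
        pieces.append(f" {anchor} ")
        cursor = end + 1
    pieces.append(sentence.text[cursor:])
    return tokenize("".join(pieces)), overlap


def _distances(n: int, anchor: int) -> list[int]:
    return [i - anchor for i in range(n)]


def generate_candidates(sentence: Sentence) -> list[CandidateInstance]:
    """Enumerate all unordered entity pairs of a sentence as instances.

    Entities are ordered by first-span start offset; the earlier member of
    each pair becomes ``DRUG1``.  Labels come from the sentence's gold
    pairs; a pair without a gold annotation is labelled ``negative``.
    Exactly ``n(n-1)/2`` instances are returned for *n* entities.
    """
    ents = sorted(sentence.entities, key=lambda e: e.first_span())
    gold: dict[frozenset, DrugPair] = {
        frozenset((p.e1, p.e2)): p for p in sentence.pairs
    }
    out: list[CandidateInstance] = []
    for i in range(len(ents)):
        for j in range(i + 1, len(ents)):
            e1, e2 = ents[i], ents[j]
            others = [e for k, e in enumerate(ents) if k not in (i, j)]
            tokens, overlap = _anonymize(sentence, e1, e2, others)
            pair = gold.get(frozenset((e1.id, e2.id)))
            label = pair.itype if (pair and pair.ddi) else "negative"
            pair_id = pair.id if pair else f"{sentence.id}.auto.{e1.id}.{e2.id}"
            if overlap:
                # target spans collide: degenerate candidate, rule-1 flagged
                p1 = tokens.index(DRUG1)
                tokens = tokens[:p1 + 1] + [DRUG2] + tokens[p1 + 1:]
                p2 = p1 + 1
                filtered, reason = True, "same_drug"
            else:
                p1, p2 = tokens.index(DRUG1), tokens.index(DRUG2)
                filtered, reason = False, "none"
            out.append(CandidateInstance(
                sentence_id=sentence.id,
                pair_id=pair_id,
                tokens=tokens,
                p1=p1,
                p2=p2,
                dist_e1=_distances(len(tokens), p1),
                dist_e2=_distances(len(tokens), p2),
                label=label,
                e1_surface=e1.surface,
                e2_surface=e2.surface,
                filtered=filtered,
                filter_reason=reason,
            ))
    return out


# ---------------------------------------------------------------------------
# negative-instance filtering


def _same_drug(inst: CandidateInstance,
               synonyms: list[set[str]] | None) -> bool:
    a, b = inst.e1_surface.casefold(), inst.e2_surface.casefold()
    if a == b:
        return True
    if synonyms:
        for group in synonyms:
            folded = {s.casefold() for s in group}
            if a in folded and b in folded:
                return True
    return False


def _coordinated(inst: CandidateInstance) -> bool:
    between = inst.tokens[inst.p1 + 1 : inst.p2]
    return all(t in _COORD_TOKENS or t in _ANCHORS for t in between)


def filter_negatives(instances: list[CandidateInstance],
                     synonyms: list[set[str]] | None = None,
                     ) -> list[CandidateInstance]:
    """Set ``filtered``/``filter_reason`` flags; never touches labels.

    Idempotent: flags are recomputed from scratch on each call (an instance
    already flagged ``same_drug`` by construction stays flagged).
    """
    out = []
    for inst in instances:
        if _same_drug(inst, synonyms) or inst.filter_reason == "same_drug":
            out.append(replace(inst, filtered=True, filter_reason="same_drug"))
        elif _coordinated(inst):
            out.append(replace(inst, filtered=True, filter_reason="coordination"))
        else:
            out.append(replace(inst, filtered=False, filter_reason="none"))
    return out


def training_subset(instances: list[CandidateInstance]) -> list[CandidateInstance]:
    """Drop filtered *negative* candidates; gold positives are never dropped."""
    return [i for i in instances if not (i.filtered and i.label == "negative")]


# ---------------------------------------------------------------------------
# position encoding and length normalisation


def encode_positions(inst: CandidateInstance, max_dist: int) -> CandidateInstance:
    """Clip relative distances to ``[-max_dist, +max_dist]`` (saturating)."""
    clip = lambda d: max(-max_dist, min(max_dist, d))  # noqa: E731
    return replace(
        inst,
        dist_e1=[clip(d) for d in inst.dist_e1],
        dist_e2=[clip(d) for d in inst.dist_e2],
    )


def pad_or_truncate(inst: CandidateInstance, max_len: int = 150,
                    ) -> CandidateInstance:
    """Normalise an instance to exactly ``max_len`` tokens.

    Shorter instances are right-padded with :data:`PAD_TOKEN` (embedding
    index 0); longer ones are truncated to the smallest window containing
    both anchors, extended symmetrically.  Both anchors always survive.
    """
    n = len(inst.tokens)
    if inst.p2 - inst.p1 + 1 > max_len:
        raise ValueError(
            f"instance {inst.pair_id}: anchors span {inst.p2 - inst.p1 + 1} "
            f"tokens, cannot fit in max_len={max_len}"
        )
    if n <= max_len:
        pad = max_len - n
        return replace(
            inst,
            tokens=inst.tokens + [PAD_TOKEN] * pad,
            dist_e1=inst.dist_e1 + [0] * pad,
            dist_e2=inst.dist_e2 + [0] * pad,
            pad_mask=[True] * n + [False] * pad,
        )
    slack = max_len - (inst.p2 - inst.p1 + 1)
    start = inst.p1 - slack // 2
    start = max(0, min(start, n - max_len))
    end = start + max_len
    return replace(
        inst,
        tokens=inst.tokens[start:end],
        p1=inst.p1 - start,
        p2=inst.p2 - start,
        dist_e1=inst.dist_e1[start:end],
        dist_e2=inst.dist_e2[start:end],
        pad_mask=[True] * max_len,
    )


def prepare_instances(sentences: list[Sentence], max_dist: int = 60,
                      max_len: int = 150, apply_filter: bool = True,
                      synonyms: list[set[str]] | None = None,
                      ) -> list[CandidateInstance]:
    """Full candidate pipeline: enumerate, flag, clip, pad."""
    out: list[CandidateInstance] = []
    for sent in sentences:
        insts = generate_candidates(sent)
        if apply_filter:
            insts = filter_negatives(insts, synonyms)
        out.extend(
            pad_or_truncate(encode_positions(i, max_dist), max_len)
            for i in insts
        )
    return out


# ---------------------------------------------------------------------------
# transformer-side preprocessing


def default_bert_tokenizer(text: str) -> list[str]:
    """Lowercasing whitespace/punctuation fallback tokenizer for tests."""
    return [t.lower() for t in tokenize(text)]


CLS, SEP, BPAD = "[CLS]", "[SEP]", "[PAD]"


def preprocess_for_bert(sentence: Sentence, pair: DrugPair,
                        tokenizer=None, max_len: int = 128,
                        e1_marker: str = "$", e2_marker: str = "#",
                        ) -> BertInput:
    """Build entity-marker input: ``[CLS] .. $ e1 $ .. # e2 # .. [SEP]``.

    Drug names are *not* anonymized on this route.  ``entity_pos_ids`` is 1
    exactly on e1's wordpieces, 2 on e2's, 0 elsewhere (markers and control
    tokens included).
    """
    tokenizer = tokenizer or default_bert_tokenizer
    ea = sentence.entity_by_id(pair.e1)
    eb = sentence.entity_by_id(pair.e2)
    if ea.first_span() > eb.first_span():
        ea, eb = eb, ea
    (s1, e1_), (s2, e2_) = ea.first_span(), eb.first_span()
    if _spans_overlap((s1, e1_), (s2, e2_)):
        raise ValueError(f"pair {pair.id}: overlapping entity spans")
    text = sentence.text
    parts = [text[:s1], text[s1:e1_ + 1], text[e1_ + 1:s2],
             text[s2:e2_ + 1], text[e2_ + 1:]]
    c0, t_e1, c1, t_e2, c2 = (tokenizer(p) for p in parts)
    for ent, toks in ((ea, t_e1), (eb, t_e2)):
        if not toks:
            raise ValueError(
                f"entity {ent.id}: span destroyed by tokenization"
            )
    tokens = [CLS] + c0 + [e1_marker] + t_e1 + [e1_marker] + c1
    e1_span = (len(tokens) - len(c1) - len(t_e1) - 1,
               len(tokens) - len(c1) - 2)
    tokens += [e2_marker] + t_e2 + [e2_marker]
    e2_span = (len(tokens) - len(t_e2) - 1, len(tokens) - 2)
    tokens += c2
    if len(tokens) + 1 > max_len:
        if e2_span[1] + 3 > max_len:  # closing marker + [SEP] must survive
            raise ValueError(
                f"pair {pair.id}: entities do not fit in max_len={max_len}"
            )
        tokens = tokens[: max_len - 1]
    tokens.append(SEP)
    real = len(tokens)
    tokens += [BPAD] * (max_len - real)
    ids = [0] * max_len
    for k in range(e1_span[0], e1_span[1] + 1):
        ids[k] = 1
    for k in range(e2_span[0], e2_span[1] + 1):
        ids[k] = 2
    gold = pair.itype if pair.ddi else "negative"
    return BertInput(
        tokens=tokens,
        entity_pos_ids=ids,
        attention_mask=[1] * real + [0] * (max_len - real),
        label=gold,
        e1_span=e1_span,
        e2_span=e2_span,
        sentence_id=sentence.id,
        pair_id=pair.id,
    )


def write_jsonl(instances: list[CandidateInstance], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(inst.to_json() + "\n")


def read_jsonl(path) -> list[CandidateInstance]:
    with open(path, encoding="utf-8") as fh:
        return [CandidateInstance.from_json(line) for line in fh if line.strip()]
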