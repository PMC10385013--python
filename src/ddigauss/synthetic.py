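"""Synthetic DDI corpora and embedding channels with controlled structure.

The generator emulates the two external resources the pipeline normally
consumes — an annotated DDI XML corpus and a set of word-embedding
channels — so every module is exercisable without downloads.  Each
positive sentence embeds exactly one class-specific trigger phrase around
its target drug pair (the four interaction classes are characterized by
typical wordings: advice = dosing recommendations, effect = observed
outcome, mechanism = pharmacokinetic process, int = an interaction stated
without detail); negatives carry no trigger, or only a coordination list.
Two corpus phenomena that the negative-filtering rules target are
injected on demand: same-surface duplicate mentions (rule-1 fodder) and
comma/conjunction drug lists (rule-2 fodder).  A JSON-able ledger records
every draw and is the ground truth for stochastic tests.

Drug names are pronounceable CV-syllable strings, not real drug names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import tokenize
from .corpus_io import CLASS_ORDER, Document, DrugPair, EntityMention, Sentence
from .embeddings import EmbeddingTable
from .candidates import PAD_TOKEN

#: one template lexicon per class; {D1}/{D2} mark the target pair
TRIGGER_TEMPLATES: dict[str, list[str]] = {
    "advice": [
        "{D1} should not be administered to patients receiving {D2}",
        "caution is advised if {D1} is coadministered with {D2}",
        "concurrent use of {D1} with {D2} should be avoided",
    ],
    "effect": [
        "{D1} enhanced the sedative effect of {D2}",
        "{D1} induced hypotension that was potentiated by {D2}",
        "{D1} may antagonize the bacteriostatic action of {D2}",
    ],
    "mechanism": [
        "{D1} prolonged the plasma half-life of {D2}",
        "{D1} decreases the renal clearance of {D2}",
        "{D1} inhibits the hepatic metabolism of {D2}",
    ],
    "int": [
        "the interaction of {D1} with {D2} is not well characterized",
        "an interaction linking {D1} with {D2} has been reported",
    ],
    "negative": [
        "{D1} was measured in serum while {D2} levels remained stable",
        "patients took {D1} daily whereas {D2} was discontinued earlier",
        "{D1} is supplied as tablets but {D2} comes as capsules",
    ],
}

#: pure comma/conjunction list — every inner pair is rule-2 fodder
_LIST_TEMPLATE = "{LIST} were included in the screening panel"

#: class-discriminative words (appear only in that class's templates)
TRIGGER_LEXICONS: dict[str, list[str]] = {
    "advice": ["administered", "receiving", "caution", "advised",
               "coadministered", "avoided", "concurrent"],
    "effect": ["enhanced", "sedative", "potentiated", "antagonize",
               "hypotension", "bacteriostatic"],
    "mechanism": ["prolonged", "half-life", "clearance", "metabolism",
                  "hepatic", "renal", "inhibits"],
    "int": ["interaction", "characterized", "linking", "reported"],
}

_PREFIXES = ["in this study", "previous reports indicate that", ""]

_CONSONANTS = list("bdfglmnprstvz")
_VOWELS = list("aeiou")


@dataclass
class SyntheticSpec:
    n_documents: int = 50
    sentences_per_document: tuple[int, int] = (4, 8)
    class_proportions: dict[str, float] = field(default_factory=lambda: {
        c: 0.2 for c in CLASS_ORDER
    })
    drugs_per_sentence: tuple[int, int] = (2, 4)
    p_coordination: float = 0.3
    p_duplicate_name: float = 0.05
    vocabulary_size: int = 400  # size of the synthetic drug-name pool
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if set(self.class_proportions) != set(CLASS_ORDER):
            raise ValueError("proportions must cover all five classes")
        lo, hi = self.sentences_per_document
        if not (1 <= lo <= hi):
            raise ValueError("invalid sentences_per_document range")
        lo, hi = self.drugs_per_sentence
        if not (2 <= lo <= hi):
            raise ValueError("drugs_per_sentence range must start at >= 2")
        if self.vocabulary_size < hi + 2:
            raise ValueError("vocabulary too small for drugs_per_sentence")


def _drug_name(rng: np.random.Generator) -> str:
    n_syl = int(rng.integers(2, 5))
    name = "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syl)
    )
    return name.capitalize()


class _SentenceBuilder:
    """Accumulates text pieces while tracking entity character spans."""

    def __init__(self, sent_id: str, rng: np.random.Generator):
        self.sent_id = sent_id
        self.rng = rng
        self.pieces: list[str] = []
        self.length = 0
        self.entities: list[EntityMention] = []

    def add_text(self, text: str):
        if not text:
            return
        if self.pieces:
            text = " " + text
        self.pieces.append(text)
        self.length += len(text)

    def add_drug(self, name: str) -> str:
        sep = " " if self.pieces else ""
        start = self.length + len(sep)
        self.pieces.append(sep + name)
        self.length += len(sep) + len(name)
        eid = f"{self.sent_id}.e{len(self.entities)}"
        etype = str(self.rng.choice(
            ["drug", "brand", "group", "drug_n"], p=[0.7, 0.1, 0.1, 0.1],
        ))
        self.entities.append(EntityMention(
            id=eid, char_spans=[(start, start + len(name) - 1)],
            etype=etype, surface=name,
        ))
        return eid

    def fill_template(self, template: str, d1: str, d2: str,
                      ) -> tuple[str, str]:
        id1 = id2 = ""
        for word in template.split():
            if word == "{D1}":
                id1 = self.add_drug(d1)
            elif word == "{D2}":
                id2 = self.add_drug(d2)
            else:
                self.add_text(word)
        return id1, id2

    def text(self) -> str:
        return "".join(self.pieces)


def _make_sentence(sent_id: str, label: str, spec: SyntheticSpec,
                   name_pool: list[str], rng: np.random.Generator) -> dict:
    b = _SentenceBuilder(sent_id, rng)
    lo, hi = spec.drugs_per_sentence
    n_drugs = int(rng.integers(lo, hi + 1))
    names = [name_pool[i] for i in
             rng.choice(len(name_pool), size=n_drugs, replace=False)]
    coordination = rng.random() < spec.p_coordination
    duplicate = rng.random() < spec.p_duplicate_name
    prefix = str(rng.choice(_PREFIXES))
    record = {"id": sent_id, "label": label, "template": None,
              "n_drugs": n_drugs, "target_pair": None,
              "same_drug_pairs": [], "coordination_pairs": []}

    coord_ids: list[str] = []
    if label == "negative" and coordination:
        # pure coordination list: all pairs are rule-2 fodder
        n_list = max(n_drugs, 3)
        if n_list > len(names):  # resample distinct names for the list
            names = [name_pool[i] for i in
                     rng.choice(len(name_pool), size=n_list, replace=False)]
        b.add_text(prefix)
        for i, name in enumerate(names[:-1]):
            coord_ids.append(b.add_drug(name))
            if i < len(names) - 2:
                b.add_text(",")
        b.add_text("and")
        coord_ids.append(b.add_drug(names[-1]))
        for part in _LIST_TEMPLATE.split()[1:]:
            b.add_text(part)
        record["template"] = "coordination_list"
    else:
        templates = TRIGGER_TEMPLATES[label]
        t_idx = int(rng.integers(len(templates)))
        template = templates[t_idx]
        b.add_text(prefix)
        id1, id2 = b.fill_template(template, names[0], names[1])
        record["template"] = f"{label}/{t_idx}"
        if label != "negative":
            record["target_pair"] = [id1, id2]
        extras = names[2:]
        if extras:
            if len(extras) >= 2:
                b.add_text("; unrelated medications included")
                for i, name in enumerate(extras[:-1]):
                    coord_ids.append(b.add_drug(name))
                    if i < len(extras) - 2:
                        b.add_text(",")
                b.add_text("and")
                coord_ids.append(b.add_drug(extras[-1]))
            else:
                b.add_text("; separately")
                b.add_drug(extras[0])
                b.add_text("was also prescribed")
        if duplicate:
            # second mention with the identical surface: rule-1 fodder
            dup_id = b.add_drug(names[0])
            b.add_text("is another name of the same product")
            record["same_drug_pairs"].append([id1, dup_id])

    for i in range(len(coord_ids)):
        for j in range(i + 1, len(coord_ids)):
            record["coordination_pairs"].append([coord_ids[i], coord_ids[j]])

    sent = Sentence(id=sent_id, text=b.text(), entities=b.entities)
    target = set(record["target_pair"] or [])
    ents = sorted(sent.entities, key=lambda e: e.first_span())
    k = 0
    for i in range(len(ents)):
        for j in range(i + 1, len(ents)):
            pair_ids = {ents[i].id, ents[j].id}
            positive = pair_ids == target
            sent.pairs.append(DrugPair(
                id=f"{sent_id}.p{k}", e1=ents[i].id, e2=ents[j].id,
                ddi=positive, itype=label if positive else None,
            ))
            k += 1
    record["n_pairs"] = k
    return {"sentence": sent, "record": record}


def generate_corpus(spec: SyntheticSpec,
                    ) -> tuple[list[Document], dict]:
    """Generate a DDI-XML-valid corpus plus the generation ledger.

    Deterministic given ``spec.seed``; the ledger records per-sentence
    draws (label, template, target pair, filter-eligible pairs) and
    aggregate class counts at sentence and pair level.
    """
    rng = np.random.default_rng(spec.seed)
    name_pool = []
    seen = set()
    while len(name_pool) < spec.vocabulary_size:
        name = _drug_name(rng)
        if name not in seen:
            seen.add(name)
            name_pool.append(name)
    classes = list(CLASS_ORDER)
    probs = np.array([spec.class_proportions[c] for c in classes])
    docs: list[Document] = []
    records = []
    sentence_counts = {c: 0 for c in classes}
    pair_counts = {c: 0 for c in classes}
    lo, hi = spec.sentences_per_document
    for d in range(spec.n_documents):
        doc = Document(id=f"d{d}", source_tag="synthetic")
        n_sent = int(rng.integers(lo, hi + 1))
        for s in range(n_sent):
            label = classes[int(rng.choice(len(classes), p=probs))]
            made = _make_sentence(f"d{d}.s{s}", label, spec, name_pool, rng)
            doc.sentences.append(made["sentence"])
            records.append(made["record"])
            sentence_counts[label] += 1
            n_pos = 1 if made["record"]["target_pair"] else 0
            pair_counts[label] += n_pos
            pair_counts["negative"] += made["record"]["n_pairs"] - n_pos
        docs.append(doc)
    ledger = {
        "seed": spec.seed,
        "sentence_class_counts": sentence_counts,
        "pair_class_counts": pair_counts,
        "sentences": records,
    }
    return docs, ledger


def corpus_vocabulary(docs: list[Document]) -> list[str]:
    """All surface tokens of a corpus plus the anonymization anchors."""
    vocab: dict[str, None] = {"DRUG1": None, "DRUG2": None, "DRUGN": None}
    for doc in docs:
        for sent in doc.sentences:
            for tok in tokenize(sent.text):
                vocab.setdefault(tok, None)
    return list(vocab)


def generate_channel_embeddings(vocab: list[str], k: int,
                                n_channels: int = 2, seed: int = 0,
                                trigger_lexicons: dict | None = None,
                                ) -> list[EmbeddingTable]:
    """Seeded random embedding channels with class-separable trigger rows.

    Base rows are Gaussian(0, 1/sqrt(k)); words in a class's trigger
    lexicon additionally receive that class's offset direction, scaled by
    a channel-specific factor, so trigger rows of different classes are
    linearly separable by construction and the classification task is
    learnable.  The PAD row (index 0) is zero.
    """
    if k < 1:
        raise ValueError("embedding dimensionality must be >= 1")
    if not 1 <= n_channels <= 5:
        raise ValueError("between 1 and 5 channels")
    lexicons = trigger_lexicons if trigger_lexicons is not None \
        else TRIGGER_LEXICONS
    rng = np.random.default_rng(seed)
    directions = {}
    for cls in sorted(lexicons):
        u = rng.normal(size=k)
        directions[cls] = u / np.linalg.norm(u)
    word_to_class = {}
    for cls, words in lexicons.items():
        for w in words:
            word_to_class[w] = cls
    tables = []
    for ch in range(n_channels):
        vocab_map = {PAD_TOKEN: 0}
        rows = [np.zeros(k)]
        scale = rng.uniform(0.75, 1.25)
        for word in vocab:
            if word == PAD_TOKEN:
                continue
            base = rng.normal(0.0, 1.0 / np.sqrt(k), size=k)
            cls = word_to_class.get(word)
            if cls is not None:
                base = 0.25 * base + 2.0 * scale * directions[cls]
            vocab_map[word] = len(rows)
            rows.append(base)
        tables.append(EmbeddingTable(
            vocab=vocab_map, matrix=np.stack(rows), k=k,
            name=f"synthetic-ch{ch}",
        ))
    return tables
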