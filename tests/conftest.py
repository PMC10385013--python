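import numpy as np
import pytest

from ddigauss.corpus_io import Document, DrugPair, EntityMention, Sentence
from ddigauss.synthetic import SyntheticSpec, generate_corpus


def make_sentence(text: str, names: list[str], pairs=None,
                  sent_id: str = "s0") -> Sentence:
    """Build a Sentence by locating each name's first occurrence."""
    entities = []
    cursor = {}
    for k, name in enumerate(names):
        start = text.index(name, cursor.get(name, 0))
        cursor[name] = start + 1
        entities.append(EntityMention(
            id=f"e{k}", char_spans=[(start, start + len(name) - 1)],
            etype="drug", surface=name,
        ))
    sent = Sentence(id=sent_id, text=text, entities=entities)
    for k, (e1, e2, itype) in enumerate(pairs or []):
        sent.pairs.append(DrugPair(
            id=f"p{k}", e1=e1, e2=e2,
            ddi=itype is not None, itype=itype,
        ))
    return sent


@pytest.fixture
def table4_sentence() -> Sentence:
    """The three-drug worked example with gold effect relations."""
    return make_sentence(
        "Aminoglutethimide decreases the effect of coumarin and warfarin",
        ["Aminoglutethimide", "coumarin", "warfarin"],
        pairs=[("e0", "e1", "effect"), ("e0", "e2", "effect"),
               ("e1", "e2", None)],
    )


@pytest.fixture
def minimal_doc() -> Document:
    sent = make_sentence(
        "Alphacillin may antagonize Betamycin",
        ["Alphacillin", "Betamycin"],
        pairs=[("e0", "e1", "effect")],
    )
    return Document(id="d0", source_tag="test", sentences=[sent])


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic ~130-sentence synthetic corpus plus its ledger."""
    spec = SyntheticSpec(n_documents=20, sentences_per_document=(5, 8),
                         seed=42)
    return generate_corpus(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
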