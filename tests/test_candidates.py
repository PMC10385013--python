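from itertools import combinations

import pytest

from ddigauss.candidates import (
    PAD_TOKEN,
    CandidateInstance,
    default_bert_tokenizer,
    encode_positions,
    filter_negatives,
    generate_candidates,
    pad_or_truncate,
    preprocess_for_bert,
    tokenize,
    training_subset,
)
from ddigauss.corpus_io import DrugPair

from conftest import make_sentence


def lower_text(inst):
    return " ".join(inst.tokens).lower()


class TestGenerateCandidates:
    def test_worked_example_matches_published_anonymizations(
            self, table4_sentence):
        # one anonymized sequence per enumerated pair, offset order
        expected = {
            ("Aminoglutethimide", "coumarin"):
                "drug1 decreases the effect of drug2 and drugn",
            ("Aminoglutethimide", "warfarin"):
                "drug1 decreases the effect of drugn and drug2",
            ("coumarin", "warfarin"):
                "drugn decreases the effect of drug1 and drug2",
        }
        insts = generate_candidates(table4_sentence)
        assert len(insts) == 3
        got = {(i.e1_surface, i.e2_surface): lower_text(i) for i in insts}
        assert got == expected

    def test_labels_follow_gold_pairs(self, table4_sentence):
        by_label = sorted(i.label for i in generate_candidates(
            table4_sentence))
        assert by_label == ["effect", "effect", "negative"]

    def test_single_entity_yields_nothing(self):
        sent = make_sentence("Alphacillin was administered",
                             ["Alphacillin"])
        assert generate_candidates(sent) == []

    @pytest.mark.parametrize("n", range(13))
    def test_count_law_matches_pair_enumeration(self, n):
        names = [f"Drug{chr(97 + k)}x" for k in range(n)]
        sent = make_sentence("the panel held " + " plus ".join(names),
                             names) if n else make_sentence("nothing", [])
        insts = generate_candidates(sent)
        assert len(insts) == n * (n - 1) // 2
        assert len(insts) == len(list(combinations(range(n), 2)))

    def test_anchor_invariants(self, table4_sentence):
        for inst in generate_candidates(table4_sentence):
            assert inst.p1 < inst.p2
            assert inst.tokens[inst.p1] == "DRUG1"
            assert inst.tokens[inst.p2] == "DRUG2"
            assert inst.dist_e1[inst.p1] == 0
            assert inst.dist_e2[inst.p2] == 0
            assert inst.dist_e1 == [k - inst.p1
                                    for k in range(len(inst.tokens))]

    def test_deanonymization_recovers_token_multiset(self, table4_sentence):
        base = sorted(tokenize(table4_sentence.text))
        surfaces = {e.id: e.surface
                    for e in table4_sentence.entities}
        for inst in generate_candidates(table4_sentence):
            others = [s for eid, s in surfaces.items()
                      if s not in (inst.e1_surface, inst.e2_surface)]
            restored = []
            oi = iter(others)
            for tok in inst.tokens:
                if tok == "DRUG1":
                    restored.extend(tokenize(inst.e1_surface))
                elif tok == "DRUG2":
                    restored.extend(tokenize(inst.e2_surface))
                elif tok == "DRUGN":
                    restored.extend(tokenize(next(oi)))
                else:
                    restored.append(tok)
            assert sorted(restored) == base


class TestFilterNegatives:
    def test_same_surface_pair_flagged(self):
        sent = make_sentence(
            "Tetracycline blood levels mirrored Tetracycline intake",
            ["Tetracycline", "Tetracycline"],
        )
        (inst,) = filter_negatives(generate_candidates(sent))
        assert inst.filtered and inst.filter_reason == "same_drug"

    def test_synonym_table_extends_same_drug_rule(self):
        sent = make_sentence("Acetamol versus Paracetine trials",
                             ["Acetamol", "Paracetine"])
        (inst,) = filter_negatives(generate_candidates(sent),
                                   synonyms=[{"acetamol", "paracetine"}])
        assert inst.filter_reason == "same_drug"

    def test_coordination_list_pair_flagged(self):
        sent = make_sentence(
            "aminoglycosides, tetracyclines, bacitracin, polymyxins",
            ["aminoglycosides", "tetracyclines", "bacitracin",
             "polymyxins"],
        )
        insts = filter_negatives(generate_candidates(sent))
        assert all(i.filter_reason == "coordination" for i in insts)

    def test_verb_separated_pair_not_flagged(self, table4_sentence):
        insts = filter_negatives(generate_candidates(table4_sentence))
        first = next(i for i in insts if i.e2_surface == "coumarin")
        assert not first.filtered

    def test_flags_only_never_labels_and_idempotent(self, small_corpus):
        docs, _ = small_corpus
        sents = [s for d in docs for s in d.sentences]
        insts = [i for s in sents for i in generate_candidates(s)]
        once = filter_negatives(insts)
        twice = filter_negatives(once)
        assert [i.label for i in once] == [i.label for i in insts]
        assert [(i.filtered, i.filter_reason) for i in once] == \
            [(i.filtered, i.filter_reason) for i in twice]

    def test_training_subset_never_drops_gold_positives(self, small_corpus):
        docs, _ = small_corpus
        sents = [s for d in docs for s in d.sentences]
        insts = filter_negatives(
            [i for s in sents for i in generate_candidates(s)])
        kept = training_subset(insts)
        n_pos = sum(i.label != "negative" for i in insts)
        assert sum(i.label != "negative" for i in kept) == n_pos


class TestPositionsAndPadding:
    def test_distances_from_both_anchors(self):
        sent = make_sentence("Abc decreases the effect of Xyz",
                             ["Abc", "Xyz"])
        (inst,) = generate_candidates(sent)
        assert inst.dist_e1 == [0, 1, 2, 3, 4, 5]
        assert inst.dist_e2 == [-5, -4, -3, -2, -1, 0]

    def test_clipping_saturates(self):
        filler = " ".join(f"w{k}" for k in range(200))
        sent = make_sentence(f"Abc {filler} Xyz", ["Abc", "Xyz"])
        (inst,) = generate_candidates(sent)
        enc = encode_positions(inst, max_dist=60)
        assert max(enc.dist_e1) == 60 and min(enc.dist_e2) == -60
        assert enc.dist_e1[enc.p1] == 0

    def test_padding_to_fixed_length(self):
        sent = make_sentence("Abc decreases the effect of Xyz",
                             ["Abc", "Xyz"])
        (inst,) = generate_candidates(sent)
        padded = pad_or_truncate(inst, max_len=150)
        assert len(padded.tokens) == 150
        assert padded.tokens.count(PAD_TOKEN) == 144
        assert padded.pad_mask == [True] * 6 + [False] * 144

    def test_exact_length_instance_unchanged(self):
        names = ["Abc", "Xyz"]
        filler = " ".join(f"w{k}" for k in range(147))
        sent = make_sentence(f"Abc with {filler} Xyz"[: 10**6], names)
        (inst,) = generate_candidates(sent)
        assert len(inst.tokens) == 150  # sanity of the construction
        padded = pad_or_truncate(inst, max_len=150)
        assert padded.tokens == inst.tokens

    def test_truncation_window_keeps_both_anchors(self):
        pre = " ".join(f"a{k}" for k in range(5))
        mid = " ".join(f"m{k}" for k in range(114))
        post = " ".join(f"z{k}" for k in range(79))
        sent = make_sentence(f"{pre} Abc {mid} Xyz {post}", ["Abc", "Xyz"])
        (inst,) = generate_candidates(sent)
        assert len(inst.tokens) == 200 and inst.p1 == 5 and inst.p2 == 120
        out = pad_or_truncate(inst, max_len=150)
        assert len(out.tokens) == 150
        assert out.tokens[out.p1] == "DRUG1"
        assert out.tokens[out.p2] == "DRUG2"
        # anchors-first windowing rule, applied by hand: window must start
        # at max(0, p1 - (150 - 116)//2) = 0 (clipped) .. but never cut p2
        assert out.p2 - out.p1 == 115

    def test_anchors_that_cannot_fit_raise(self):
        mid = " ".join(f"m{k}" for k in range(200))
        sent = make_sentence(f"Abc {mid} Xyz", ["Abc", "Xyz"])
        (inst,) = generate_candidates(sent)
        with pytest.raises(ValueError, match=inst.pair_id):
            pad_or_truncate(inst, max_len=150)

    def test_jsonl_roundtrip(self, table4_sentence, tmp_path):
        from ddigauss.candidates import read_jsonl, write_jsonl
        insts = [pad_or_truncate(encode_positions(i, 60), 30)
                 for i in generate_candidates(table4_sentence)]
        path = tmp_path / "c.jsonl"
        write_jsonl(insts, path)
        assert read_jsonl(path) == insts


class TestBertPreprocessing:
    def test_marker_layout_and_entity_ids(self):
        sent = make_sentence("Aban interacts with Bodol",
                             ["Aban", "Bodol"],
                             pairs=[("e0", "e1", "mechanism")])
        out = preprocess_for_bert(sent, sent.pairs[0], max_len=12)
        assert out.tokens == ["[CLS]", "$", "aban", "$", "interacts",
                              "with", "#", "bodol", "#", "[SEP]",
                              "[PAD]", "[PAD]"]
        assert out.entity_pos_ids == [0, 0, 1, 0, 0, 0, 0, 2, 0, 0, 0, 0]
        assert out.attention_mask == [1] * 10 + [0] * 2
        assert out.label == "mechanism"

    def test_context_tokens_all_zero(self):
        sent = make_sentence("Aban interacts strongly with Bodol today",
                             ["Aban", "Bodol"],
                             pairs=[("e0", "e1", None)])
        out = preprocess_for_bert(sent, sent.pairs[0], max_len=16)
        marked = set(range(out.e1_span[0], out.e1_span[1] + 1)) | \
            set(range(out.e2_span[0], out.e2_span[1] + 1))
        for k, v in enumerate(out.entity_pos_ids):
            if k not in marked:
                assert v == 0

    def test_names_not_anonymized(self):
        sent = make_sentence("Aban interacts with Bodol",
                             ["Aban", "Bodol"],
                             pairs=[("e0", "e1", "int")])
        out = preprocess_for_bert(sent, sent.pairs[0], max_len=12)
        assert "aban" in out.tokens and "drug1" not in out.tokens

    @pytest.mark.parametrize("max_len", [12, 20, 40])
    def test_padded_length_is_exact(self, max_len):
        sent = make_sentence("Aban interacts with Bodol",
                             ["Aban", "Bodol"],
                             pairs=[("e0", "e1", "effect")])
        out = preprocess_for_bert(sent, sent.pairs[0], max_len=max_len)
        assert len(out.tokens) == max_len
        assert len(out.entity_pos_ids) == max_len

    def test_multiword_entity_block(self):
        sent = make_sentence(
            "Tetracycline may antagonize beta lactam agents",
            ["Tetracycline", "beta lactam agents"],
            pairs=[("e0", "e1", "effect")],
        )
        out = preprocess_for_bert(sent, sent.pairs[0], max_len=16)
        a, b = out.e2_span
        assert out.tokens[a:b + 1] == ["beta", "lactam", "agents"]
        assert all(v == 2 for v in out.entity_pos_ids[a:b + 1])

    def test_entities_must_fit(self):
        sent = make_sentence("Aban interacts with Bodol",
                             ["Aban", "Bodol"],
                             pairs=[("e0", "e1", "effect")])
        with pytest.raises(ValueError, match="max_len"):
            preprocess_for_bert(sent, sent.pairs[0], max_len=6)

    def test_destroyed_entity_span_raises(self):
        sent = make_sentence("Aban interacts with Bodol",
                             ["Aban", "Bodol"],
                             pairs=[("e0", "e1", "effect")])
        eat_all = lambda text: []  # noqa: E731
        with pytest.raises(ValueError, match="destroyed"):
            preprocess_for_bert(sent, sent.pairs[0], tokenizer=eat_all,
                                max_len=12)


def test_default_bert_tokenizer_lowercases_and_splits():
    assert default_bert_tokenizer('Abc, (Xyz)/Q.') == \
        ["abc", ",", "(", "xyz", ")", "/", "q", "."]
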