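"""Dictionary compilation, subtree filtering and corpus augmentation."""

import random

import pytest

from dxnorm import (
    CanonConfig,
    LexiconRecord,
    Mention,
    NormalizationDictionary,
    augment_from_corpus,
    canonicalize,
    compile_dictionary,
    filter_by_subtree,
    normalize_mention,
    read_lexicon_tsv,
)


def rec(cid, name, trees=()):
    return LexiconRecord(cid, name, tuple(trees))


class TestSubtreeFilter:
    def test_prefix_match_retained(self):
        kept = filter_by_subtree([rec("D1", "x", ["C08.381"])], ["C", "F"])
        assert len(kept) == 1

    def test_other_subtree_dropped(self):
        assert filter_by_subtree([rec("D1", "x", ["D02.455"])], ["C", "F"]) == []

    def test_any_tree_number_suffices(self):
        kept = filter_by_subtree([rec("D1", "x", ["A01", "F03.600"])], ["C", "F"])
        assert len(kept) == 1

    def test_no_tree_numbers_dropped(self):
        assert filter_by_subtree([rec("D1", "x")]) == []

    def test_empty_prefixes_rejected(self):
        with pytest.raises(ValueError):
            filter_by_subtree([], [])


class TestCompile:
    def test_single_record_single_key(self, cfg):
        d = compile_dictionary([rec("D001930", "Brain Damage, Chronic")])
        assert len(d.entries) == 1
        (key,) = d.entries
        assert key == canonicalize("Brain Damage, Chronic", cfg)

    def test_identical_canonical_synonyms_deduplicate_triples(self):
        d = compile_dictionary(
            [rec("D1", "brain damage"), rec("D1", "brain damage")]
        )
        assert len(d) == 1

    def test_homonyms_share_key(self):
        d = compile_dictionary([rec("D1", "cold"), rec("D2", "cold")])
        (key,) = d.entries
        assert d.ids_for(key) == {"D1", "D2"}

    def test_keys_match_independent_recanonicalisation(self, cfg):
        rng = random.Random(3)
        words = ["airway", "blocked", "chronic", "lung", "disease", "acute"]
        records = [
            rec(f"D{i}", " ".join(rng.sample(words, rng.randint(1, 3))))
            for i in range(10)
        ]
        d = compile_dictionary(records, cfg)
        expected_keys = {canonicalize(r.name, cfg) for r in records}
        assert set(d.entries) == expected_keys
        for key, bucket in d.entries.items():
            for e in bucket:
                assert canonicalize(e.name, cfg) == key

    def test_permutation_invariance(self, toy_records):
        rng = random.Random(11)
        shuffled = toy_records[:]
        rng.shuffle(shuffled)
        a = compile_dictionary(toy_records)
        b = compile_dictionary(shuffled)
        assert a.entries == b.entries

    def test_empty_canonical_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            d = compile_dictionary([rec("D1", "of the")])
        assert len(d) == 0
        assert "canonicalises to empty" in caplog.text


class TestAugment:
    def gold(self, text, cid, doc="1000"):
        return Mention(doc, 0, len(text), text, "Disease", cid)

    def test_brain_damage_worked_example(self, cfg):
        base = compile_dictionary([rec("D000001", "nervous system disease", ["C10"])])
        aug = augment_from_corpus(base, [self.gold("brain damage", "D001930")], cfg)
        key = canonicalize("brain damage", cfg)
        assert aug.ids_for(key) == {"D001930"}
        res = normalize_mention("brain damage", aug, [], None, cfg)
        assert (res.concept_id, res.method, res.score) == ("D001930", "direct", 1.0)

    def test_already_present_pair_is_noop(self, toy_dict, cfg):
        gold = [self.gold("lung cancer", "D000003")]
        aug = augment_from_corpus(toy_dict, gold, cfg)
        assert aug.entries == toy_dict.entries

    def test_same_form_new_id_added(self, toy_dict, cfg):
        aug = augment_from_corpus(toy_dict, [self.gold("lung cancer", "D999999")], cfg)
        key = canonicalize("lung cancer", cfg)
        assert aug.ids_for(key) == {"D000003", "D999999"}

    def test_composite_ids_split_and_sentinel_skipped(self, toy_dict, cfg):
        gold = [
            self.gold("renal failure", "D100|D200"),
            self.gold("mystery illness", "-1"),
        ]
        aug = augment_from_corpus(toy_dict, gold, cfg)
        assert aug.ids_for(canonicalize("renal failure", cfg)) == {"D100", "D200"}
        assert canonicalize("mystery illness", cfg) not in aug.entries

    def test_missing_id_skipped_with_warning(self, toy_dict, caplog):
        with caplog.at_level("WARNING"):
            aug = augment_from_corpus(toy_dict, [self.gold("new thing", None)])
        assert len(aug) == len(toy_dict)
        assert "lacks a concept ID" in caplog.text

    def test_growth_counts_novel_forms_exactly(self, cfg):
        base = compile_dictionary([rec(f"D{i}", f"disease type{i}") for i in range(5)])
        known = [self.gold(f"disease type{i}", f"D{i}") for i in range(5)]
        novel = [self.gold(f"novel illness {c}", f"N{c}") for c in "abcde"]
        # 15 repeated known mentions + 5 novel ones
        gold = known * 3 + novel
        aug = augment_from_corpus(base, gold, cfg)
        new_keys = set(aug.entries) - set(base.entries)
        assert new_keys == {canonicalize(m.text, cfg) for m in novel}
        assert len(aug) == len(base) + 5

    def test_idempotent_and_never_shrinks(self, toy_dict, cfg):
        gold = [self.gold("brain damage", "D001930"), self.gold("lung cancer", "D000003")]
        once = augment_from_corpus(toy_dict, gold, cfg)
        twice = augment_from_corpus(once, gold, cfg)
        assert once.entries == twice.entries
        assert len(once) >= len(toy_dict)
        for key, bucket in toy_dict.entries.items():
            assert bucket <= once.entries[key]


def test_lexicon_tsv_round_trip_and_synonyms():
    tsv = (
        "id\ttree_numbers\tname\tsynonyms\n"
        "D1\tC08.381;C10\tchronic airway blockage\tblockage of airways|blocked airways\n"
        "D2\tD02\tsolvent\t\n"
    )
    records = read_lexicon_tsv(tsv)
    assert len(records) == 4  # D1 name + 2 synonyms, D2 name
    assert records[0].tree_numbers == ("C08.381", "C10")
    assert {r.concept_id for r in records} == {"D1", "D2"}


def test_dictionary_tsv_round_trip(toy_dict):
    text = toy_dict.to_tsv()
    back = NormalizationDictionary.from_tsv(text, CanonConfig())
    assert back.entries == toy_dict.entries
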