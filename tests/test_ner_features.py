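"""Token features and the BIO codec."""

import pytest
from hypothesis import given, strategies as st

from dxnorm import LexiconRecord, Mention, compile_dictionary
from dxnorm.ner_features import (
    DictionaryTagger,
    Token,
    bio_decode,
    bio_encode,
    char_ngrams,
    context_ngrams,
    dict_features,
    featurize_sentence,
    ortho_features,
    read_token_tsv,
    word_shape,
    write_crfsuite,
)

from .oracles import interval_dict_matches


def toks(*surfaces):
    out, pos = [], 0
    for s in surfaces:
        out.append(Token(s, pos, pos + len(s), "NN", s.lower(), "NP"))
        pos += len(s) + 1
    return out


class TestCharNgrams:
    @pytest.mark.parametrize(
        "surface,n2,n3,n4",
        [("ab", 1, 0, 0), ("copd", 3, 2, 1), ("x", 0, 0, 0), ("lungs", 4, 3, 2)],
    )
    def test_counts_are_len_minus_n_plus_one(self, surface, n2, n3, n4):
        feats = char_ngrams(Token(surface))
        got = {n: sum(k.startswith(f"ng{n}[") for k in feats) for n in (2, 3, 4)}
        # repeated substrings collapse, so counts are upper bounds and exact
        # for repetition-free surfaces like these
        assert got == {2: n2, 3: n3, 4: n4}

    def test_ngram_contents(self):
        assert set(char_ngrams(Token("ab"))) == {"ng2[ab]"}


class TestContextNgrams:
    def test_single_token_sentence_only_offset_zero(self):
        sent = toks("copd")
        feats = context_ngrams(sent, 0)
        assert all("[0]" in k for k in feats)
        assert "w[0]=copd" in feats

    def test_window_arithmetic_mid_sentence(self):
        sent = toks(*"abcdefg")
        feats = context_ngrams(sent, 3)
        assert sum(k.startswith("w[") and "|" not in k for k in feats) == 7
        assert sum(k.startswith("w[") and "|" in k for k in feats) == 6

    def test_window_clipped_at_bounds(self):
        sent = toks(*"abcdefg")
        feats = context_ngrams(sent, 0)
        assert sum(k.startswith("w[") and "|" not in k for k in feats) == 4  # 0..+3
        assert "w[-1]=?" not in feats

    def test_golden_feature_set_by_independent_enumeration(self):
        sent = toks("copd", "is", "chronic")
        feats = context_ngrams(sent, 1)
        expected = set()
        for off, t in [(-1, sent[0]), (0, sent[1]), (1, sent[2])]:
            expected |= {
                f"w[{off}]={t.surface}",
                f"pos[{off}]={t.pos}",
                f"lem[{off}]={t.lemma}",
            }
        for off, (a, b) in [(-1, (sent[0], sent[1])), (0, (sent[1], sent[2]))]:
            expected |= {
                f"w[{off}]|w[{off + 1}]={a.surface}|{b.surface}",
                f"pos[{off}]|pos[{off + 1}]={a.pos}|{b.pos}",
                f"lem[{off}]|lem[{off + 1}]={a.lemma}|{b.lemma}",
            }
        assert set(feats) == expected


class TestOrtho:
    @pytest.mark.parametrize(
        "surface,shape", [("IL-6", "AA_0"), ("COPD", "AAAA"), ("p53", "a00")]
    )
    def test_word_shape_mapping(self, surface, shape):
        assert word_shape(surface) == shape

    def test_flags(self):
        f = ortho_features(Token("IL-6"))
        assert f["has_digit"] and f["has_special"] and not f["all_upper"]
        assert ortho_features(Token("COPD"))["all_upper"]
        assert not ortho_features(Token("p53"))["all_upper"]


class TestDictFeatures:
    @pytest.fixture()
    def disease_dict(self):
        return compile_dictionary(
            [
                LexiconRecord("D1", "chronic obstructive pulmonary disease"),
                LexiconRecord("D2", "lung"),
                LexiconRecord("D3", "lung cancer"),
            ]
        )

    def test_full_name_tagged_bii(self, disease_dict):
        sent = toks("chronic", "obstructive", "pulmonary", "disease", "kills")
        feats = dict_features(sent, {"dx": disease_dict})
        tags = [
            next((k[-1] for k in f if k.startswith("dict[dx]")), "O") for f in feats
        ]
        assert tags == ["B", "I", "I", "I", "O"]

    def test_no_match_all_clear(self, disease_dict):
        feats = dict_features(toks("nothing", "matches", "here"), {"dx": disease_dict})
        assert all(not f for f in feats)

    def test_longest_match_wins_nested_names(self, disease_dict):
        sent = toks("Lung", "cancer", "spread")
        feats = dict_features(sent, {"dx": disease_dict})
        tags = [
            next((k[-1] for k in f if k.startswith("dict[dx]")), "O") for f in feats
        ]
        assert tags == ["B", "I", "O"]

    @pytest.mark.parametrize(
        "surfaces",
        [
            ["lung", "cancer", "lung", "and", "lung", "cancer"],
            ["disease", "lung", "chronic", "obstructive", "pulmonary", "disease"],
            ["lung"] * 7,
        ],
    )
    def test_matches_exhaustive_interval_oracle(self, disease_dict, surfaces):
        sent = toks(*surfaces)
        feats = dict_features(sent, {"dx": disease_dict})
        got = [
            next((k[-1] for k in f if k.startswith("dict[dx]")), "O") for f in feats
        ]
        name_seqs = {
            ("chronic", "obstructive", "pulmonary", "disease"),
            ("lung",),
            ("lung", "cancer"),
        }
        assert got == interval_dict_matches([s.lower() for s in surfaces], name_seqs)


class TestBioCodec:
    def test_no_spans_all_outside(self):
        assert bio_encode([], toks("a", "b")) == ["O", "O"]

    def test_two_token_span(self):
        sent = toks("chronic", "bronchitis", "is", "bad")
        span = Mention("d", 0, 18, "chronic bronchitis", "Disease")
        assert bio_encode([span], sent) == ["B-Disease", "I-Disease", "O", "O"]

    def test_round_trip(self):
        sent = toks("chronic", "bronchitis", "is", "bad")
        spans = [Mention("d", 0, 18, "chronic bronchitis", "Disease")]
        assert bio_decode(bio_encode(spans, sent), sent, "d") == spans

    def test_decode_repairs_illegal_i_after_o(self):
        sent = toks("a", "bad", "cough")
        out = bio_decode(["O", "I-Disease", "I-Disease"], sent, "d")
        assert len(out) == 1
        assert (out[0].begin, out[0].end, out[0].type) == (2, 11, "Disease")

    def test_same_type_overlap_raises(self):
        sent = toks("aa", "bb", "cc")
        spans = [
            Mention("d", 0, 5, "aa bb", "Disease"),
            Mention("d", 3, 8, "bb cc", "Disease"),
        ]
        with pytest.raises(ValueError):
            bio_encode(spans, sent)

    @given(
        st.lists(
            st.tuples(st.integers(0, 9), st.integers(1, 3)), max_size=4
        )
    )
    def test_random_nonoverlapping_spans_round_trip(self, raw):
        sent = toks(*[f"tok{i}" for i in range(10)])
        spans, used = [], set()
        for start, length in raw:
            end_tok = min(start + length, 10) - 1
            if set(range(start, end_tok + 1)) & used:
                continue
            used.update(range(start, end_tok + 1))
            b, e = sent[start].begin, sent[end_tok].end
            text = " ".join(t.surface for t in sent[start : end_tok + 1])
            spans.append(Mention("d", b, e, text, "Disease"))
        labels = bio_encode(spans, sent)
        assert sorted(bio_decode(labels, sent, "d")) == sorted(spans)


class TestBaselineAndIO:
    def test_dictionary_tagger_satisfies_interface(self):
        d = compile_dictionary([LexiconRecord("D3", "lung cancer")])
        tagger = DictionaryTagger({"Disease": d})
        sent = toks("lung", "cancer", "kills")
        tagger.train([sent])
        assert tagger.label(sent) == ["B-Disease", "I-Disease", "O"]

    def test_token_tsv_round_trip_shape(self):
        tsv = "Lung\t0\t4\tNN\tlung\tNP\tB-Disease\ncancer\t5\t11\tNN\tcancer\tNP\tI-Disease\n\nNext\t0\t4\tJJ\tnext\tNP\tO\n"
        sents = read_token_tsv(tsv)
        assert [len(s) for s in sents] == [2, 1]
        assert sents[0][0].label == "B-Disease"

    def test_crfsuite_output_layout(self):
        sent = toks("p53", "rocks")
        out = write_crfsuite([sent])
        lines = out.strip().split("\n")
        assert len(lines) == 2
        first = lines[0].split("\t")
        assert first[0] == "O"  # label column first
        assert any(f.startswith("shape[a00]") for f in first)

    def test_featurize_is_pure(self):
        sent = toks("IL-6", "rises")
        assert featurize_sentence(sent) == featurize_sentence(sent)
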