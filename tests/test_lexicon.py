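import math

import pytest

from aitext.lexicon import (CategoryDictionary, Lexicon, LexiconEntry,
                            LexiconFormatError, LexiconValidationError, MatchStage,
                            WordClass, load_category_dictionary, load_lexicon,
                            save_category_dictionary, save_lexicon)

HEADER = "word\tbaseform\tclass\tvalence\tarousal\timageability\tfreq\n"


def write_lexicon(tmp_path, rows):
    path = tmp_path / "lex.tsv"
    path.write_text(HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


class TestLoadLexicon:
    def test_loads_all_valid_rows(self, tmp_path):
        path = write_lexicon(tmp_path, [
            ("hund", "hund", "noun", 1.0, 2.0, 6.5, 120),
            ("haus", "haus", "noun", 0.5, 1.2, 7.0, 300),
            ("rennen", "rennen", "verb", -1.0, 4.0, 4.0, 15),
        ])
        assert len(load_lexicon(path)) == 3

    @pytest.mark.parametrize("row", [
        ("bad", "bad", "noun", 9.0, 2.0, 4.0, 10),     # valence beyond +3
        ("bad", "bad", "noun", 0.0, 0.5, 4.0, 10),     # arousal below 1
        ("bad", "bad", "noun", 0.0, 2.0, 8.0, 10),     # imageability beyond 7
        ("bad", "bad", "noun", 0.0, 2.0, 4.0, -1.0),   # negative frequency
    ])
    def test_out_of_range_rating_is_rejected(self, tmp_path, row):
        with pytest.raises(LexiconValidationError):
            load_lexicon(write_lexicon(tmp_path, [row]))

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("word\tbaseform\tclass\n" "hund\thund\tnoun\n")
        with pytest.raises(LexiconFormatError):
            load_lexicon(path)

    def test_inflected_and_base_rows_coexist(self, tmp_path):
        lex = load_lexicon(write_lexicon(tmp_path, [
            ("hunde", "hund", "noun", "NA", "NA", "NA", "NA"),
            ("hund", "hund", "noun", 1.0, 2.0, 6.5, 120),
        ]))
        assert lex.get("hunde") is not None
        assert lex.get("hund") is not None
        assert lex.baseform_index["hund"].word == "hund"

    def test_duplicate_words_keep_first(self, tmp_path):
        lex = load_lexicon(write_lexicon(tmp_path, [
            ("hund", "hund", "noun", 1.0, 2.0, 6.5, 120),
            ("hund", "hund", "noun", -2.0, 3.0, 2.0, 5),
        ]))
        assert len(lex) == 1
        assert lex.get("hund").valence == 1.0

    def test_roundtrip_preserves_lookups(self, tmp_path, tiny_lexicon):
        path = tmp_path / "roundtrip.tsv"
        save_lexicon(tiny_lexicon, path)
        reloaded = load_lexicon(path)
        for token in ["hund", "hunde", "freundlichste", "rennt", "und", "nix"]:
            e1, s1 = tiny_lexicon.lookup(token)
            e2, s2 = reloaded.lookup(token)
            assert s1 == s2
            assert (e1 is None) == (e2 is None)
            if e1 is not None:
                assert e1.word == e2.word and e1.valence == pytest.approx(e2.valence)


class TestLookup:
    def test_verbatim_rated_token_matches_raw(self, tiny_lexicon):
        entry, stage = tiny_lexicon.lookup("hund")
        assert stage is MatchStage.RAW
        assert entry.word == "hund"

    def test_inflected_token_resolves_via_baseform(self, tiny_lexicon):
        entry, stage = tiny_lexicon.lookup("freundlichste")
        assert stage is MatchStage.BASEFORM
        assert entry.word == "freundlich"
        assert entry.valence == 2.0

    def test_unknown_token_misses(self, tiny_lexicon):
        entry, stage = tiny_lexicon.lookup("zzz")
        assert stage is MatchStage.MISS and entry is None

    def test_case_insensitive(self, tiny_lexicon):
        assert tiny_lexicon.lookup("Hund")[1] is MatchStage.RAW
        assert tiny_lexicon.lookup("HUNDE")[1] is MatchStage.BASEFORM

    def test_raw_matches_subset_of_all_matches(self, tiny_lexicon):
        """Baseform conversion can only add matches, never remove them."""
        tokens = ["hund", "hunde", "freundlich", "freundlichste", "rennt",
                  "spielt", "haus", "zzz", "und"]
        raw = sum(tiny_lexicon.lookup(t)[1] is MatchStage.RAW for t in tokens)
        matched = sum(tiny_lexicon.lookup(t)[1] is not MatchStage.MISS for t in tokens)
        assert raw <= matched

    def test_empty_token_rejected(self, tiny_lexicon):
        with pytest.raises(ValueError):
            tiny_lexicon.lookup("")


class TestCategoryDictionary:
    def test_parse_dic_file(self, tmp_path):
        path = tmp_path / "cats.dic"
        lines = ["%"] + [f"{i}\tcat{i:02d}" for i in range(1, 65)] + ["%"]
        lines += [f"word{j}\t{j % 64 + 1}" for j in range(10)]
        path.write_text("\n".join(lines))
        dic = load_category_dictionary(path)
        assert len(dic.categories) == 64
        assert len(dic.patterns) == 10

    def test_wildcard_line_maps_to_both_categories(self, tmp_path):
        path = tmp_path / "cats.dic"
        path.write_text("%\n1\taffect\n3\tleisure\n7\tsocial\n%\nspiel*\t3\t7\n")
        dic = load_category_dictionary(path)
        assert dic.patterns["spiel*"] == {"leisure", "social"}
        # category order follows ids
        assert dic.categories == ["affect", "leisure", "social"]

    def test_empty_pattern_section_is_valid(self, tmp_path):
        path = tmp_path / "cats.dic"
        path.write_text("%\n1\tonly\n%\n")
        dic = load_category_dictionary(path)
        assert dic.categories == ["only"] and dic.patterns == {}

    def test_unknown_id_is_format_error(self, tmp_path):
        path = tmp_path / "cats.dic"
        path.write_text("%\n1\tonly\n%\nspiel*\t2\n")
        with pytest.raises(LexiconFormatError):
            load_category_dictionary(path)

    def test_wildcard_matches_prefix_and_exact(self, tiny_dictionary):
        assert tiny_dictionary.match("spiel") == {"leisure"}
        assert tiny_dictionary.match("spielte") == {"leisure"}
        assert tiny_dictionary.match("hund") == {"social", "leisure"}
        assert tiny_dictionary.match("hunde") == set()   # exact pattern, no wildcard

    def test_roundtrip(self, tmp_path, tiny_dictionary):
        path = tmp_path / "rt.dic"
        save_category_dictionary(tiny_dictionary, path)
        reloaded = load_category_dictionary(path)
        assert reloaded.categories == tiny_dictionary.categories
        assert reloaded.patterns == tiny_dictionary.patterns
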