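"""Dictionary/rule-based relation mining: segmentation, matching, scoring."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypcocktail.errors import UnknownTermError, ValidationError
from cypcocktail.kb import Role, normalize_enzyme_name
from cypcocktail.synthetic import (
    GeneratorConfig,
    fixture_lexicons,
    fixture_tables_kb,
    generate_corpus,
)
from cypcocktail.textmine import (
    AbstractRecord,
    Lexicons,
    Mention,
    RelationHit,
    ScoringParams,
    classify_role,
    deduplicate,
    find_mentions,
    mine_corpus,
    query_match,
    score_relation,
    segment,
)


@pytest.fixture(scope="module")
def lexicons():
    return fixture_lexicons()


def _flat(text):
    return [t for sent in segment(text) for t in sent]


class TestSegment:
    def test_two_terminal_periods_two_sentences(self):
        sents = segment("CYP3A4 metabolizes vincristine. It is inhibited by ketoconazole.")
        assert len(sents) == 2

    def test_empty_text(self):
        assert segment("") == []
        assert segment("   ") == []

    def test_abbreviations_do_not_break_sentences(self):
        sents = segment("Prodrugs, e.g. cyclophosphamide, need activation. A second point.")
        assert len(sents) == 2

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.sampled_from(
                ["CYP3A4 metabolizes vincristine.", "A second claim!",
                 "Is this so?", "Numbers like 3A4 and L-asparaginase occur."]
            ),
            min_size=0,
            max_size=6,
        )
    )
    def test_token_offsets_index_back_into_text(self, pieces):
        text = " ".join(pieces)
        for sent in segment(text):
            for token in sent:
                assert text[token.start : token.end] == token.text


class TestFindMentions:
    def test_exact_dictionary_hits(self, lexicons):
        tokens = _flat("cyclophosphamide and CYP3A4")
        drugs = find_mentions(tokens, lexicons.drugs)
        cyps = find_mentions(tokens, lexicons.enzymes)
        assert [m.canonical for m in drugs] == ["Cyclophosphamide"]
        assert [m.canonical for m in cyps] == ["CYP3A4"]

    def test_longest_match_wins(self):
        lexicon = {
            "methotrexate": frozenset({"methotrexate"}),
            "methotrexate sodium": frozenset({"methotrexate sodium"}),
        }
        tokens = _flat("patients received methotrexate sodium weekly")
        mentions = find_mentions(tokens, lexicon)
        assert [m.canonical for m in mentions] == ["methotrexate sodium"]

    def test_multiword_and_spaced_enzyme_synonyms(self, lexicons):
        tokens = _flat("High-dose methotrexate affects CYP 3A4 indirectly")
        assert [m.canonical for m in find_mentions(tokens, lexicons.drugs)] == ["HDMTX"]
        assert [m.canonical for m in find_mentions(tokens, lexicons.enzymes)] == ["CYP3A4"]

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=5_000))
    def test_matches_brute_force_substring_scan(self, seed, lexicons):
        """Mentions equal a naive scanner that tries every synonym at every
        token position (token-boundary-respecting, longest-first)."""
        records, _ = generate_corpus(
            fixture_tables_kb(), GeneratorConfig(seed=seed, n_abstracts=5)
        )
        tokenize = lambda s: tuple(t.text.lower() for t in _flat(s))
        for lexicon in (lexicons.drugs, lexicons.enzymes):
            phrases = sorted(
                ((tokenize(s), c) for c, syns in lexicon.items() for s in syns),
                key=lambda kv: -len(kv[0]),
            )
            for record in records:
                tokens = _flat(record.abstract)
                lowered = [t.text.lower() for t in tokens]
                expected, i = [], 0
                while i < len(lowered):
                    for phrase, canonical in phrases:
                        if phrase and tuple(lowered[i : i + len(phrase)]) == phrase:
                            expected.append((canonical, tokens[i].index))
                            i += len(phrase)
                            break
                    else:
                        i += 1
                got = [
                    (m.canonical, m.first.index)
                    for m in find_mentions(tokens, lexicon)
                ]
                assert got == expected


class TestQueryMatch:
    def test_title_clause(self, lexicons):
        record = AbstractRecord("1", "Cyclophosphamide is activated by CYP2B6", "")
        assert query_match(record, lexicons) is True

    def test_abstract_clause_requires_interaction_term(self, lexicons):
        record = AbstractRecord(
            "2", "A study", "Cyclophosphamide levels and CYP3A4 expression were measured."
        )
        assert query_match(record, lexicons) is False
        with_term = AbstractRecord(
            "3", "A study", "Cyclophosphamide is metabolized by CYP3A4."
        )
        assert query_match(with_term, lexicons) is True

    def test_empty_record(self, lexicons):
        assert query_match(AbstractRecord("4", "", ""), lexicons) is False

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=5_000))
    def test_monotone_under_text_growth(self, seed, lexicons):
        records, _ = generate_corpus(
            fixture_tables_kb(), GeneratorConfig(seed=seed, n_abstracts=5)
        )
        for record in records:
            if query_match(record, lexicons):
                grown = AbstractRecord(
                    record.pmid,
                    record.title,
                    record.abstract + " Additional unrelated closing remark.",
                )
                assert query_match(grown, lexicons) is True


def _mention(pmid, tok_index, sentence, text="x", start=0):
    from cypcocktail.textmine import Token

    token = Token(text, start, index=tok_index, sentence=sentence)
    return Mention(text, token, token, pmid)


class TestScoreRelation:
    def test_adjacent_same_sentence_canonical_order_is_maximal(self):
        # "CYP3A4 metabolizes vincristine": enzyme-term-drug, distance 2
        cyp = _mention("1", 0, 0)
        term = _mention("1", 1, 0)
        drug = _mention("1", 2, 0)
        params = ScoringParams()
        score = score_relation(drug, cyp, term, params)
        assert score == params.base - params.w_dist * 2 + params.b_sent + params.b_order

    def test_distant_cross_sentence_pair_scores_zero(self):
        drug = _mention("1", 0, 0)
        cyp = _mention("1", 40, 2)
        term = _mention("1", 1, 0)
        assert score_relation(drug, cyp, term) == 0.0

    def test_mentions_from_different_records_rejected(self):
        with pytest.raises(ValidationError):
            score_relation(_mention("1", 0, 0), _mention("2", 1, 0), _mention("1", 2, 0))

    def test_score_non_increasing_in_distance(self):
        params = ScoringParams()
        scores = []
        for gap in range(1, 25):
            drug = _mention("1", 0, 0)
            term = _mention("1", 1, 0)
            cyp = _mention("1", gap, 0)
            scores.append(score_relation(drug, cyp, term, params))
            # direct formula evaluation as the independent check
            expected = max(
                0.0,
                params.base - params.w_dist * gap + params.b_sent
                + params.b_order * (0 < 1 < gap),
            )
            assert scores[-1] == expected
        assert all(a >= b for a, b in zip(scores[1:], scores[2:]))

    def test_redundancy_bonus(self):
        drug = _mention("1", 0, 0)
        term = _mention("1", 1, 0)
        cyp = _mention("1", 2, 0)
        base = score_relation(drug, cyp, term)
        assert score_relation(drug, cyp, term, redundancy=2) == base + 2.0


class TestClassifyRole:
    @pytest.mark.parametrize(
        "term, role",
        [
            ("inhibited", Role.INHIBITOR),
            ("inhibitory", Role.INHIBITOR),
            ("induces", Role.INDUCER),
            ("induction", Role.INDUCER),
            ("metabolized", Role.SUBSTRATE),
            ("metabolism", Role.SUBSTRATE),
            ("substrate", Role.SUBSTRATE),
        ],
    )
    def test_inflection_families(self, lexicons, term, role):
        assert classify_role(term, lexicons) is role

    def test_unknown_term_rejected(self, lexicons):
        with pytest.raises(UnknownTermError):
            classify_role("phosphorylates", lexicons)


class TestDeduplicate:
    def _hit(self, pmid, drug, score, offset=0):
        return RelationHit(
            pmid, drug, normalize_enzyme_name("3A4"), Role.SUBSTRATE, score,
            evidence=((offset, offset + 4),),
        )

    def test_highest_score_wins(self):
        kept = deduplicate([self._hit("1", "a", 7.0), self._hit("1", "a", 9.0)])
        assert len(kept) == 1 and kept[0].score == 9.0

    def test_empty_input(self):
        assert deduplicate([]) == []

    def test_per_corpus_mode_merges_across_pmids(self):
        hits = [self._hit("1", "a", 7.0), self._hit("2", "a", 9.0)]
        assert len(deduplicate(hits)) == 2
        merged = deduplicate(hits, per_corpus=True)
        assert len(merged) == 1 and merged[0].pmid == "2"

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["1", "2", "3"]),
                st.sampled_from(["a", "b"]),
                st.floats(min_value=0, max_value=20, allow_nan=False),
            ),
            max_size=12,
        )
    )
    def test_idempotent_and_never_longer(self, raw):
        hits = [self._hit(p, d, s) for p, d, s in raw]
        once = deduplicate(hits)
        assert len(once) <= len(hits)
        assert deduplicate(once) == once
        keys = [h.key for h in once]
        assert len(keys) == len(set(keys))


class TestMineCorpus:
    def test_planted_relations_recovered_exactly(self, lexicons):
        kb = fixture_tables_kb()
        records, truth = generate_corpus(kb, GeneratorConfig(seed=42, n_abstracts=100))
        hits, summary = mine_corpus(records, lexicons)
        truth_keys = {(t.pmid, t.drug, t.enzyme, t.role) for t in truth}
        hit_keys = {(h.pmid, h.drug, h.enzyme.name, h.role) for h in hits}
        assert len(truth_keys) == 40
        assert hit_keys == truth_keys  # precision = recall = 1.0
        assert summary.records_screened == 100

    def test_corpus_without_lexicon_terms(self, lexicons):
        records = [AbstractRecord("1", "An unrelated title", "Entirely unrelated text.")]
        hits, summary = mine_corpus(records, lexicons)
        assert hits == [] and summary.query_hits == 0

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2_000))
    def test_summary_bookkeeping(self, seed, lexicons):
        records, _ = generate_corpus(
            fixture_tables_kb(),
            GeneratorConfig(seed=seed, n_abstracts=30, distractor_rate=0.6),
        )
        hits, summary = mine_corpus(records, lexicons)
        assert summary.hits_above_threshold - summary.duplicates_removed == len(hits)
        assert summary.hits_returned == len(hits)
        assert summary.query_hits <= summary.records_screened
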