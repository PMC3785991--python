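import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxcircles.corpus import Tweet
from rxcircles.lexicon import (
    ABUSE_CATEGORIES,
    DRUG_CATEGORIES,
    AbuseLexicon,
    CategorizedTweet,
    DrugLexicon,
    categorize_abuse,
    categorize_corpus,
    categorize_drugs,
    categorize_tweet,
    extract_mentions,
    match_keywords,
)


class TestMatchKeywords:
    @pytest.mark.parametrize(
        "text, keywords, expected",
        [
            ("I took three painkillers", ["painkiller*"], True),
            ("I was overdosing", ["overdose"], False),  # plain keyword = whole token
            ("nice pain killer combo", ["pain killer*"], True),
            ("my pain killers arrived", ["pain killer*"], True),
            ("PAINKILLER!", ["painkiller*"], True),  # case-insensitive, punctuation
            ("sleeping pills again", ["sleeping pills"], True),
            ("sleeping on pills", ["sleeping pills"], False),  # phrase must be contiguous
            ("a network of people", ["two"], False),  # no substring matches
            ("pop", ["pop*"], True),  # wildcard matches the bare stem
            ("", ["overdose"], False),
            ("anything", [], False),
        ],
    )
    def test_semantics(self, text, keywords, expected):
        assert match_keywords(text, keywords) is expected

    def test_rejects_inner_wildcard(self):
        with pytest.raises(ValueError):
            match_keywords("x", ["pa*in"])


class TestCategorizeDrugs:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Seriously. Need adderall. Will pay $$$. Help me.", {"Adderall"}),
            ("For me it's a nice ritalin/sangria combo :)", {"Stimulants"}),
            ("good morning", set()),
            ("xanax and valium day", {"Xanax", "Valium"}),
            ("took some Oxycontin and a stimulant", {"Painkillers", "Stimulants"}),
        ],
    )
    def test_examples(self, text, expected, drug_lex):
        assert categorize_drugs(text, drug_lex) == expected

    def test_exactly_seven_categories(self, drug_lex):
        assert tuple(drug_lex.categories) == DRUG_CATEGORIES


class TestCategorizeAbuse:
    def test_seeking_example(self, abuse_lex):
        text = "Seriously. Need adderall. Will pay $$$. Help me."
        assert "seeking" in categorize_abuse(text, {"Adderall"}, abuse_lex)

    def test_trading_example(self, abuse_lex):
        text = "looking to buy ~20-40 mg adderall, email"
        assert "trading_selling" in categorize_abuse(text, {"Adderall"}, abuse_lex)

    def test_no_drug_no_abuse(self, abuse_lex):
        assert categorize_abuse("need to buy three things", set(), abuse_lex) == set()

    def test_coingestion_keyword_inert_for_own_drug(self, abuse_lex):
        # a drug cannot be its own co-ingestant
        assert "co_ingestion" not in categorize_abuse("xanax then more xanax", {"Xanax"}, abuse_lex)
        assert "co_ingestion" not in categorize_abuse("adderall o clock", {"Adderall"}, abuse_lex)

    def test_coingestion_fires_via_other_drug_keyword(self, abuse_lex):
        # Xanax post mentioning adderall: co-ingestion via the "adderall" keyword
        text = "xanax with a side of adderall"
        drugs = categorize_drugs(text)
        assert drugs == {"Xanax", "Adderall"}
        assert "co_ingestion" in categorize_abuse(text, drugs, abuse_lex)

    def test_study_keywords_are_adderall_only(self, abuse_lex):
        assert "alternative_motives_dependence" not in categorize_abuse(
            "valium before my test", {"Valium"}, abuse_lex
        )
        assert "alternative_motives_dependence" in categorize_abuse(
            "adderall before my test", {"Adderall"}, abuse_lex
        )

    def test_skinny_is_stimulants_only(self, abuse_lex):
        assert "alternative_motives_dependence" not in categorize_abuse(
            "xanax makes me skinny", {"Xanax"}, abuse_lex
        )
        assert "alternative_motives_dependence" in categorize_abuse(
            "ritalin makes me skinny", {"Stimulants"}, abuse_lex
        )

    def test_exactly_eight_categories(self, abuse_lex):
        assert tuple(abuse_lex.categories) == ABUSE_CATEGORIES


class TestExtractMentions:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("@alice hi @bob_123", ["alice", "bob_123"]),
            ("mail me at foo@bar.com", []),
            ("@alice @alice", ["alice"]),
            ("RT @someuser I should win an award", ["someuser"]),
            ("@" + "a" * 15, ["a" * 15]),
            ("@" + "a" * 16, []),  # handles are at most 15 characters
            ("(@paren) ok", ["paren"]),
            ("no mentions here", []),
        ],
    )
    def test_examples(self, text, expected):
        assert extract_mentions(text) == expected


class TestCategorizeCorpus:
    def test_empty(self):
        assert categorize_corpus([]) == []

    def test_non_drug_tweet_has_empty_sets(self):
        [ct] = categorize_corpus([Tweet("1", "u", "good morning")])
        assert ct.drug_categories == frozenset() and ct.abuse_categories == frozenset()

    def test_order_and_determinism(self):
        tweets = [
            Tweet("1", "u1", "Seriously. Need adderall. Will pay $$$. Help me."),
            Tweet("2", "u2", "For me it's a nice ritalin/sangria combo :)"),
            Tweet("3", "u3", "good morning @alice"),
        ]
        out1 = categorize_corpus(tweets)
        out2 = categorize_corpus(tweets)
        assert out1 == out2
        assert [c.tweet.tweet_id for c in out1] == ["1", "2", "3"]
        assert out1[0].drug_categories == {"Adderall"} and "seeking" in out1[0].abuse_categories
        assert out1[1].drug_categories == {"Stimulants"}
        assert out1[2].mentions == ("alice",) and not out1[2].is_mention_tweet

    def test_abuse_requires_drug_is_enforced(self):
        with pytest.raises(ValueError):
            CategorizedTweet(
                tweet=Tweet("1", "u", "x"),
                drug_categories=frozenset(),
                abuse_categories=frozenset({"seeking"}),
                mentions=(),
            )


words = st.lists(
    st.sampled_from(["adderall", "xanax", "need", "buy", "morning", "three", "pop", "hello"]),
    min_size=0,
    max_size=8,
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(tokens=words)
def test_abuse_requires_drug_property(tokens):
    """No post ever receives behavior categories without a drug category."""
    ct = categorize_tweet(Tweet("1", "u", " ".join(tokens)))
    if not ct.drug_categories:
        assert not ct.abuse_categories


@settings(max_examples=40, deadline=None, derandomize=True)
@given(tokens=words, extra=st.sampled_from(["hello", "morning", "zzz"]))
def test_adding_a_keyword_is_monotone(tokens, extra):
    """Extending a keyword list never removes a category from any post."""
    text = " ".join(tokens)
    base = DrugLexicon.default()
    grown = DrugLexicon({**base.categories, "Adderall": base.categories["Adderall"] + (extra,)})
    assert categorize_drugs(text, base) <= categorize_drugs(text, grown)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(tokens=words)
def test_restriction_soundness(tokens):
    """Dropping Xanax from a post's drug set can only remove gated behaviors."""
    text = " ".join(tokens)
    with_x = categorize_abuse(text, {"Xanax", "Valium"})
    without_x = categorize_abuse(text, {"Valium"})
    # the only Xanax-gated rule *disables* a co-ingestion keyword, so removing
    # Xanax can add at most co_ingestion and never removes anything else
    assert with_x - without_x == set()
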