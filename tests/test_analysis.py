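import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxcircles.analysis import (
    abuse_level,
    aggregate_summaries,
    build_interaction_graph,
    fisher_mean,
    pearson,
    select_index_users,
    summarize_circle,
    topic_vector,
)
from rxcircles.corpus import load_summary_fixture
from rxcircles.discovery import SocialCircle
from rxcircles.lexicon import DRUG_CATEGORIES

from .conftest import make_ct


def circle_of(members, index=None):
    index = index or members[0]
    steps = {index: 0, **{m: i + 1 for i, m in enumerate(m for m in members if m != index)}}
    return SocialCircle(index_user=index, members=steps, target_size=len(members))


class TestSelectIndexUsers:
    def make_user(self, user, n_drug, with_abuse=True):
        cats = [make_ct(user, drugs={"Adderall"}, tweet_id=f"{user}-{i}") for i in range(n_drug)]
        if with_abuse and cats:
            cats[0] = make_ct(user, drugs={"Adderall"}, abuse={"seeking"}, tweet_id=f"{user}-0")
        cats.append(make_ct(user, tweet_id=f"{user}-x"))  # one non-drug post
        return cats

    def test_count_window_is_half_open(self):
        corpus = {
            "below": self.make_user("below", 9),
            "lo": self.make_user("lo", 10),
            "hi": self.make_user("hi", 99),
            "above": self.make_user("above", 100),
        }
        assert select_index_users(corpus) == ["hi", "lo"]  # sorted by id

    def test_abuse_requirement(self):
        corpus = {
            "clean": self.make_user("clean", 45, with_abuse=False),
            "abuser": self.make_user("abuser", 45, with_abuse=True),
        }
        assert select_index_users(corpus) == ["abuser"]
        assert select_index_users(corpus, require_abuse=False) == ["abuser", "clean"]


class TestTopicVector:
    def test_single_category(self):
        cats = [make_ct("u", drugs={"Adderall"}, tweet_id=str(i)) for i in range(10)]
        tv = topic_vector(cats)
        assert tv.defined and tv.n_drug_tweets == 10
        assert tv.proportions == (1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def test_no_drug_tweets_is_undefined(self):
        tv = topic_vector([make_ct("u")])
        assert not tv.defined and tv.n_drug_tweets == 0

    def test_multi_label_proportions(self):
        cats = [
            make_ct("u", drugs={"Adderall", "Xanax"}, tweet_id="1"),
            make_ct("u", drugs={"Xanax"}, tweet_id="2"),
        ]
        tv = topic_vector(cats)
        by_cat = dict(zip(DRUG_CATEGORIES, tv.proportions))
        assert by_cat["Adderall"] == 0.5 and by_cat["Xanax"] == 1.0
        assert sum(tv.proportions) == 1.5  # entries may sum past 1


class TestPearson:
    def test_identity(self):
        res = pearson([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.defined and res.r == pytest.approx(1.0)

    def test_zero_variance_is_undefined_not_an_exception(self):
        res = pearson([1, 1, 1], [1, 2, 3])
        assert not res.defined and math.isnan(res.r)

    def test_fixture_engagement_abuse_correlations(self):
        rows = load_summary_fixture()
        mu = [r.mention_users for r in rows]
        r1 = pearson(mu, [r.abuse_ge1_users for r in rows])
        r2 = pearson(mu, [r.abuse_ge2_users for r in rows])
        assert r1.r == pytest.approx(0.85, abs=0.005)
        assert r1.p < 0.001
        assert r2.r == pytest.approx(0.81, abs=0.005)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])


class TestFisherMean:
    def test_constant_list_is_fixed_point(self):
        assert fisher_mean([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_zero(self):
        assert fisher_mean([0.0]) == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_mean([])

    def test_clamps_unit_correlation_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            out = fisher_mean([1.0, 0.0])
        assert 0.0 < out < 1.0

    def test_fixture_topic_correlations(self):
        rs = [r.topic_correlation for r in load_summary_fixture()]
        assert fisher_mean(rs) == pytest.approx(0.73, abs=0.005)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        rs=st.lists(
            st.floats(min_value=-0.99, max_value=0.99, allow_nan=False), min_size=1, max_size=20
        )
    )
    def test_bounded_by_extremes(self, rs):
        out = fisher_mean(rs)
        assert min(rs) - 1e-12 <= out <= max(rs) + 1e-12


class TestAbuseLevel:
    def test_counts_distinct_categories(self):
        cats = [
            make_ct("u", drugs={"Xanax"}, abuse={"seeking", "co_ingestion"}, tweet_id="1"),
            make_ct("u", drugs={"Xanax"}, abuse={"seeking"}, tweet_id="2"),
        ]
        assert abuse_level(cats) == 2

    def test_adding_a_tweet_never_decreases(self):
        base = [make_ct("u", drugs={"Xanax"}, abuse={"seeking"}, tweet_id="1")]
        extra = make_ct("u", drugs={"Xanax"}, abuse={"trading_selling"}, tweet_id="2")
        assert abuse_level(base + [extra]) >= abuse_level(base)


class TestSummarizeCircle:
    def test_all_zero_circle(self):
        circ = circle_of(["a", "b", "c"])
        s = summarize_circle(circ, {m: [make_ct(m)] for m in "abc"})
        assert (s.drug_tweets, s.drug_tweet_users, s.mention_tweets, s.mention_users) == (0, 0, 0, 0)
        assert (s.abuse_ge1_users, s.abuse_ge2_users) == (0, 0)
        assert not s.topic_correlation_defined

    def test_single_member_circle_has_undefined_correlation(self):
        circ = circle_of(["a"])
        s = summarize_circle(circ, {"a": [make_ct("a", drugs={"Xanax"})]})
        assert s.drug_tweets == 1 and not s.topic_correlation_defined

    def test_counts_and_correlation(self):
        circ = circle_of(["i", "b", "c"])
        tweets = {
            "i": [
                make_ct("i", drugs={"Adderall"}, abuse={"seeking"}, tweet_id="i1"),
                make_ct("i", drugs={"Xanax"}, mentions=["b"], tweet_id="i2"),
            ],
            "b": [
                make_ct("b", drugs={"Adderall"}, abuse={"seeking", "trading_selling"}, tweet_id="b1"),
                make_ct("b", drugs={"Xanax"}, tweet_id="b2"),
                make_ct("b", mentions=["i"], tweet_id="b3"),  # non-drug mention: not counted
            ],
            "c": [make_ct("c", tweet_id="c1")],
        }
        s = summarize_circle(circ, tweets)
        assert s.drug_tweets == 4 and s.drug_tweet_users == 2
        assert s.mention_tweets == 1 and s.mention_users == 1
        assert s.abuse_ge1_users == 2 and s.abuse_ge2_users == 1
        # index vector == pooled-rest vector here, so correlation is 1
        assert s.topic_correlation == pytest.approx(1.0)

    def test_missing_members_treated_as_silent(self):
        circ = circle_of(["i", "b"])
        s = summarize_circle(circ, {"i": [make_ct("i", drugs={"Xanax"})]})
        assert s.drug_tweets == 1 and s.drug_tweet_users == 1


class TestInteractionGraph:
    def test_no_mentions_no_edges(self):
        circ = circle_of(["a", "b"])
        g = build_interaction_graph(circ, {"a": [make_ct("a", drugs={"Xanax"})], "b": []})
        assert set(g.nodes) == {"a", "b"} and g.number_of_edges() == 0
        assert g.nodes["a"]["drug_tweets"] == 1

    def test_edge_weight_counts_drug_mention_tweets(self):
        circ = circle_of(["a", "b"])
        tweets = {
            "a": [make_ct("a", drugs={"Xanax"}, mentions=["b"], tweet_id=str(i)) for i in range(3)]
            + [make_ct("a", mentions=["b"], tweet_id="nondrug")],  # not counted
            "b": [],
        }
        g = build_interaction_graph(circ, tweets)
        assert g["a"]["b"]["weight"] == 3

    def test_external_targets_flagged_or_dropped(self):
        circ = circle_of(["a", "b"])
        tweets = {"a": [make_ct("a", drugs={"Xanax"}, mentions=["zz"], tweet_id="1")], "b": []}
        g = build_interaction_graph(circ, tweets)
        assert g.nodes["zz"]["external"] and g["a"]["zz"]["weight"] == 1
        g2 = build_interaction_graph(circ, tweets, internal_only=True)
        assert "zz" not in g2


class TestAggregateSummaries:
    def test_fixture_means(self):
        agg = aggregate_summaries(load_summary_fixture())
        assert agg.column("drug_tweets") == pytest.approx(291.6, abs=0.05)
        assert agg.column("abuse_ge1_users") == pytest.approx(33.2, abs=0.05)
        assert agg.column("drug_tweet_users") == pytest.approx(53.96, abs=0.005)
        assert agg.column("drug_tweet_users", "sd") == pytest.approx(24.8, abs=0.05)
        assert agg.topic_correlation_fisher_mean == pytest.approx(0.73, abs=0.005)
        assert agg.engagement_abuse_r1.r == pytest.approx(0.85, abs=0.005)
        assert agg.engagement_abuse_r2.r == pytest.approx(0.81, abs=0.005)
        assert agg.n_undefined_correlations == 0

    def test_identical_summaries_have_zero_sd(self):
        rows = load_summary_fixture()[:1] * 2
        agg = aggregate_summaries(rows)
        assert float(agg.table.loc["sd"].max()) == 0.0

    def test_single_summary_rejected(self):
        with pytest.raises(ValueError):
            aggregate_summaries(load_summary_fixture()[:1])

    def test_percentage_identity_at_size_100(self):
        """With 100-member circles, user counts equal percentages: the published
        'range 14%-87%' is just min/max of the users column."""
        rows = load_summary_fixture()
        users = np.array([r.drug_tweet_users for r in rows])
        assert users.min() == 14 and users.max() == 87
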