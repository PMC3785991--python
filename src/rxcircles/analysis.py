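"""Circle-level statistics: topic vectors, correlations, summaries, interaction graphs.

Per circle this module computes the published-style summary row: total drug
posts, members producing them, drug posts directed at another user (mention
posts) and members producing those, per-member abuse levels (number of distinct
behavior categories across a member's posts — the severity surrogate), and the
topic correlation between the index user and the pooled rest of the circle.
Across circles it computes column means / sample SDs, a Fisher-z mean of the
topic correlations, and the engagement-vs-abuse Pearson correlations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Table4Row
from .discovery import SocialCircle
from .lexicon import DRUG_CATEGORIES, CategorizedTweet

__all__ = [
    "TopicVector",
    "PearsonResult",
    "CircleSummary",
    "AggregateResult",
    "select_index_users",
    "topic_vector",
    "pearson",
    "fisher_mean",
    "abuse_level",
    "summarize_circle",
    "build_interaction_graph",
    "aggregate_summaries",
]

FISHER_CLAMP = 1.0 - 1e-7


@dataclass(frozen=True)
class TopicVector:
    """Per-entity proportions over the 7 drug categories.

    Entry *d* is the fraction of the entity's drug posts whose categories
    include *d*; because a post may match several categories the entries need
    not sum to 1 (each entry individually is <= 1). Undefined when the entity
    has no drug posts.
    """

    proportions: tuple[float, ...]
    n_drug_tweets: int

    @property
    def defined(self) -> bool:
        return self.n_drug_tweets > 0

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int
    defined: bool = True


@dataclass
class CircleSummary:
    """One circle's computed summary (same columns as the published table)."""

    circle_id: str
    circle_size: int
    drug_tweets: int
    drug_tweet_users: int
    mention_tweets: int
    mention_users: int
    topic_correlation: float  # NaN when undefined
    topic_correlation_p: float
    abuse_ge1_users: int
    abuse_ge2_users: int
    abuse_levels: dict[str, int] = field(default_factory=dict)

    @property
    def topic_correlation_defined(self) -> bool:
        return not math.isnan(self.topic_correlation)

    def validate(self) -> None:
        as_row = Table4Row(
            network_id=1,
            drug_tweets=self.drug_tweets,
            drug_tweet_users=self.drug_tweet_users,
            mention_tweets=self.mention_tweets,
            mention_users=self.mention_users,
            topic_correlation=0.0 if not self.topic_correlation_defined else self.topic_correlation,
            abuse_ge1_users=self.abuse_ge1_users,
            abuse_ge2_users=self.abuse_ge2_users,
        )
        as_row.validate(circle_size=self.circle_size)


def select_index_users(
    tweets_by_user: Mapping[str, Sequence[CategorizedTweet]],
    min_drug: int = 10,
    max_drug: int = 100,
    require_abuse: bool = True,
) -> list[str]:
    """Users with ``min_drug <= #drug posts < max_drug`` (and, optionally, with
    at least one post matching an abuse category), sorted by id.

    The count window targets regular individuals rather than pharmacy spam or
    automated feeds, which post drug terms far more often; the abuse requirement
    is the deterministic stand-in for the study's manual screen of index users.
    """
    out = []
    for user in sorted(tweets_by_user):
        cats = tweets_by_user[user]
        n_drug = sum(1 for c in cats if c.is_drug_tweet)
        if not min_drug <= n_drug < max_drug:
            continue
        if require_abuse and not any(c.abuse_categories for c in cats):
            continue
        out.append(user)
    return out


def topic_vector(tweets: Iterable[CategorizedTweet]) -> TopicVector:
    """Proportion of the entity's drug posts matching each drug category."""
    counts = dict.fromkeys(DRUG_CATEGORIES, 0)
    n_drug = 0
    for ct in tweets:
        if not ct.is_drug_tweet:
            continue
        n_drug += 1
        for cat in ct.drug_categories:
            counts[cat] += 1
    if n_drug == 0:
        return TopicVector(proportions=(math.nan,) * len(DRUG_CATEGORIES), n_drug_tweets=0)
    return TopicVector(
        proportions=tuple(counts[c] / n_drug for c in DRUG_CATEGORIES), n_drug_tweets=n_drug
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with a two-sided t-test p-value (n-2 df).

    Degenerate inputs (length < 3, zero variance, NaNs) yield an undefined-flag
    result rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if (
        len(x) < 3
        or np.isnan(x).any()
        or np.isnan(y).any()
        or np.ptp(x) == 0
        or np.ptp(y) == 0
    ):
        return PearsonResult(r=math.nan, p=math.nan, n=len(x), defined=False)
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


def fisher_mean(rs: Sequence[float]) -> float:
    """Mean of correlation coefficients on the Fisher-z (atanh) scale.

    Values at exactly +/-1 are clamped to +/-(1 - 1e-7) with a warning, since
    atanh diverges there.
    """
    rs = np.asarray(rs, dtype=float)
    if rs.size == 0:
        raise ValueError("fisher_mean requires at least one correlation")
    if np.isnan(rs).any() or (np.abs(rs) > 1).any():
        raise ValueError("correlations must be finite and lie in [-1, 1]")
    if (np.abs(rs) >= 1).any():
        warnings.warn(
            "correlation(s) at +/-1 clamped before Fisher transform", RuntimeWarning
        )
        rs = np.clip(rs, -FISHER_CLAMP, FISHER_CLAMP)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def abuse_level(tweets: Iterable[CategorizedTweet]) -> int:
    """Number of distinct behavior categories across a user's posts."""
    cats: set[str] = set()
    for ct in tweets:
        cats |= ct.abuse_categories
    return len(cats)


def summarize_circle(
    circle: SocialCircle,
    tweets_by_member: Mapping[str, Sequence[CategorizedTweet]],
    circle_id: str | None = None,
) -> CircleSummary:
    """Compute the summary row for one circle.

    The topic correlation is the Pearson correlation, over the 7 drug
    categories, between the index user's topic vector and the topic vector of
    the pooled drug posts of all other members (one pseudo-entity, not an
    average of per-member vectors). It is NaN when either vector is undefined
    or constant.
    """
    members = circle.member_ids
    drug_tweets = 0
    mention_tweets = 0
    drug_users: set[str] = set()
    mention_users: set[str] = set()
    levels: dict[str, int] = {}
    rest_tweets: list[CategorizedTweet] = []
    for member in members:
        cats = tweets_by_member.get(member, ())
        levels[member] = abuse_level(cats)
        if member != circle.index_user:
            rest_tweets.extend(cats)
        for ct in cats:
            if not ct.is_drug_tweet:
                continue
            drug_tweets += 1
            drug_users.add(member)
            if ct.is_mention_tweet:
                mention_tweets += 1
                mention_users.add(member)

    tv_index = topic_vector(tweets_by_member.get(circle.index_user, ()))
    tv_rest = topic_vector(rest_tweets)
    if tv_index.defined and tv_rest.defined:
        res = pearson(tv_index.as_array(), tv_rest.as_array())
        r, p = (res.r, res.p) if res.defined else (math.nan, math.nan)
    else:
        r, p = math.nan, math.nan

    summary = CircleSummary(
        circle_id=circle_id if circle_id is not None else circle.index_user,
        circle_size=len(circle),
        drug_tweets=drug_tweets,
        drug_tweet_users=len(drug_users),
        mention_tweets=mention_tweets,
        mention_users=len(mention_users),
        topic_correlation=r,
        topic_correlation_p=p,
        abuse_ge1_users=sum(1 for v in levels.values() if v >= 1),
        abuse_ge2_users=sum(1 for v in levels.values() if v >= 2),
        abuse_levels=levels,
    )
    summary.validate()
    return summary


def build_interaction_graph(
    circle: SocialCircle,
    tweets_by_member: Mapping[str, Sequence[CategorizedTweet]],
    internal_only: bool = False,
) -> nx.DiGraph:
    """Directed weighted graph of drug-post mentions among circle members.

    Edge ``author -> target`` carries weight = number of the author's drug posts
    mentioning ``target``. Node attribute ``drug_tweets`` is the member's drug
    post count (node size in the usual rendering); mentioned users outside the
    circle are kept as peripheral nodes with ``external=True`` unless
    ``internal_only`` is set.
    """
    g = nx.DiGraph()
    members = circle.member_ids
    for member in members:
        n_drug = sum(1 for ct in tweets_by_member.get(member, ()) if ct.is_drug_tweet)
        g.add_node(member, drug_tweets=n_drug, external=False)
    for member in members:
        for ct in tweets_by_member.get(member, ()):
            if not ct.is_drug_tweet:
                continue
            for target in ct.mentions:
                if internal_only and target not in members:
                    continue
                if target not in g:
                    g.add_node(target, drug_tweets=0, external=True)
                w = g.get_edge_data(member, target, {}).get("weight", 0)
                g.add_edge(member, target, weight=w + 1)
    return g


_AGG_COLUMNS = (
    "drug_tweets",
    "drug_tweet_users",
    "mention_tweets",
    "mention_users",
    "topic_correlation",
    "abuse_ge1_users",
    "abuse_ge2_users",
)


@dataclass
class AggregateResult:
    """Across-circle aggregates: per-column mean/SD plus the headline correlations."""

    table: pd.DataFrame  # index: mean, sd; columns: _AGG_COLUMNS
    topic_correlation_fisher_mean: float
    engagement_abuse_r1: PearsonResult
    engagement_abuse_r2: PearsonResult
    n_circles: int
    n_undefined_correlations: int

    def column(self, name: str, stat: str = "mean") -> float:
        return float(self.table.loc[stat, name])


def aggregate_summaries(summaries: Sequence[CircleSummary | Table4Row]) -> AggregateResult:
    """Means and sample SDs (n-1) per column; the topic-correlation column is
    additionally averaged on the Fisher-z scale; engagement (mention users) is
    correlated against abuse>=1 and abuse>=2 user counts across circles.

    Undefined (NaN) per-circle topic correlations are excluded from the Fisher
    mean, with their count reported.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two circle summaries to aggregate")
    df = pd.DataFrame(
        [{c: getattr(s, c) for c in _AGG_COLUMNS} for s in summaries], dtype=float
    )
    table = pd.DataFrame(
        {c: [df[c].mean(), df[c].std(ddof=1)] for c in _AGG_COLUMNS}, index=["mean", "sd"]
    )
    rs = df["topic_correlation"].dropna().to_numpy()
    n_undef = int(df["topic_correlation"].isna().sum())
    fisher = fisher_mean(rs) if rs.size else math.nan
    return AggregateResult(
        table=table,
        topic_correlation_fisher_mean=fisher,
        engagement_abuse_r1=pearson(df["mention_users"], df["abuse_ge1_users"]),
        engagement_abuse_r2=pearson(df["mention_users"], df["abuse_ge2_users"]),
        n_circles=len(summaries),
        n_undefined_correlations=n_undef,
    )
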