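"""Synthetic follow graphs and post corpora with a ground-truth ledger.

The generator emulates the population structure the analysis assumes: a
directed stochastic block model whose dense blocks play the role of mutually
aware social circles, and per-user post streams in which drug-term posts,
behavior-keyword co-occurrence and @-mentions occur at configurable,
block-dependent rates. Every planted quantity (block membership, injected
categories, mention events) is recorded in a ledger so downstream stages can be
tested against exact ground truth.

Post text is synthesized from a neutral filler vocabulary plus verbatim lexicon
keywords chosen to be unambiguous (e.g. the Painkillers injection keyword is
"oxycontin", never "painkiller", which is also a co-ingestion keyword). A
collision linter re-categorizes every generated post and fails loudly if the
text matches anything beyond its intended categories.

Block-level heterogeneity is driven by two latent uniforms per block: the abuse
latent scales all behavior-injection probabilities, and the mention latent
scales the @-mention probability. A ``coupling`` parameter in [0, 1] mixes the
mention latent toward the abuse latent: at 0 the two are independent, at 1 they
coincide, inducing a positive engagement-abuse correlation across blocks.

A single integer seed drives everything; per-user substreams are derived from
(seed, stream, user index) so output is byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import fisher_mean, pearson, summarize_circle
from .corpus import FollowGraph, Tweet
from .discovery import SocialCircle
from .lexicon import (
    ABUSE_CATEGORIES,
    DRUG_CATEGORIES,
    AbuseLexicon,
    CategorizedTweet,
    DrugLexicon,
    categorize_tweet,
)

__all__ = [
    "BlockConfig",
    "SimConfig",
    "GroundTruthLedger",
    "simulate",
    "default_config",
    "sweep_config",
    "sweep_coupling",
    "predicted_engagement_abuse_r",
]

# One unambiguous injection keyword per drug category. "painkiller" and
# "concerta" are avoided (also co-ingestion keywords); "xanax"/"adderall" are
# safe because the co-ingestion restriction makes them inert for their own drug.
DRUG_KEYWORD: dict[str, str] = {
    "Adderall": "adderall",
    "Xanax": "xanax",
    "Klonopin": "klonopin",
    "Valium": "valium",
    "Painkillers": "oxycontin",
    "Depressants": "ativan",
    "Stimulants": "ritalin",
}

# One unambiguous injection keyword per behavior category.
ABUSE_KEYWORD: dict[str, str] = {
    "larger_doses_overdose": "overdose",
    "co_ingestion": "vodka",
    "more_frequent_doses": "popping",
    "alternative_motives_dependence": "breakfast",
    "alternative_routes": "snort",
    "legitimacy_of_obtaining": "stealing",
    "trading_selling": "sell",
    "seeking": "wish",
}

# Filler vocabulary verified (by the collision linter) to match no lexicon entry.
FILLER_WORDS: tuple[str, ...] = (
    "hello",
    "there",
    "today",
    "sunny",
    "afternoon",
    "walked",
    "around",
    "town",
    "music",
    "later",
    "again",
    "really",
    "nice",
    "quiet",
    "evening",
    "garden",
    "birds",
    "clouds",
)


def _uniform_mixture() -> tuple[float, ...]:
    return tuple([1.0 / len(DRUG_CATEGORIES)] * len(DRUG_CATEGORIES))


@dataclass(frozen=True)
class BlockConfig:
    """One block of the planted partition and its posting behavior.

    ``tweet_rate`` is the Poisson mean number of posts per user;
    ``drug_tweet_prob`` the per-post probability of mentioning a drug;
    ``drug_mixture`` the block's distribution over the 7 drug categories;
    ``abuse_probs`` per-behavior injection probabilities for a drug post;
    ``mention_prob`` the probability a drug post @-mentions a same-block user.
    """

    size: int
    intra_follow_prob: float = 0.6
    inter_follow_prob: float = 0.02
    tweet_rate: float = 60.0
    drug_tweet_prob: float = 0.25
    drug_mixture: tuple[float, ...] = field(default_factory=_uniform_mixture)
    abuse_probs: tuple[float, ...] = (0.008,) * len(ABUSE_CATEGORIES)
    mention_prob: float = 0.08

    def validate(self) -> None:
        if self.size < 1:
            raise ValueError("block size must be >= 1")
        for name in ("intra_follow_prob", "inter_follow_prob", "drug_tweet_prob", "mention_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.tweet_rate < 0:
            raise ValueError("tweet_rate must be non-negative")
        if len(self.drug_mixture) != len(DRUG_CATEGORIES):
            raise ValueError("drug_mixture must have 7 entries")
        if any(p < 0 for p in self.drug_mixture) or not math.isclose(
            sum(self.drug_mixture), 1.0, abs_tol=1e-9
        ):
            raise ValueError("drug_mixture must be a probability vector summing to 1")
        if len(self.abuse_probs) != len(ABUSE_CATEGORIES):
            raise ValueError("abuse_probs must have 8 entries")
        if any(not 0.0 <= p <= 1.0 for p in self.abuse_probs):
            raise ValueError("abuse_probs must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full simulation configuration; the seed determines the output exactly."""

    seed: int
    blocks: tuple[BlockConfig, ...]
    coupling: float = 0.0
    activity_spread: float = 0.6
    cross_block_mention_prob: float = 0.0

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("at least one block is required")
        for b in self.blocks:
            b.validate()
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if not 0.0 <= self.activity_spread < 1.0:
            raise ValueError("activity_spread must lie in [0, 1)")
        if not 0.0 <= self.cross_block_mention_prob <= 1.0:
            raise ValueError("cross_block_mention_prob must lie in [0, 1]")

    @property
    def n_users(self) -> int:
        return sum(b.size for b in self.blocks)


@dataclass
class GroundTruthLedger:
    """Planted truth recorded during simulation, consistent by construction."""

    config: SimConfig
    blocks: list[list[str]]
    block_of: dict[str, int]
    drug_counts: dict[str, int]
    tweet_drug: dict[str, frozenset[str]]
    tweet_abuse: dict[str, frozenset[str]]
    mention_events: list[tuple[str, str, str]]  # (tweet_id, author, target)
    effective_abuse_probs: list[tuple[float, ...]]
    effective_mention_probs: list[float]

    def planted_circle(self, block: int, index_user: str | None = None) -> SocialCircle:
        """The planted block as a circle (index = first member unless given)."""
        members = self.blocks[block]
        index = index_user if index_user is not None else members[0]
        steps = {index: 0}
        for i, u in enumerate(m for m in members if m != index):
            steps[u] = i + 1
        return SocialCircle(index_user=index, members=steps, target_size=len(members))

    def block_summary(self, block: int) -> dict[str, int]:
        """Planted per-block counts, computed from the ledger alone."""
        members = set(self.blocks[block])
        mention_tweets_by: dict[str, set[str]] = {}
        for tid, author, _target in self.mention_events:
            if author in members:
                mention_tweets_by.setdefault(author, set()).add(tid)
        abuse_cats: dict[str, set[str]] = {u: set() for u in members}
        drug_tweets = 0
        drug_users = set()
        for tid, cats in self.tweet_drug.items():
            author = self._author(tid)
            if author in members and cats:
                drug_tweets += 1
                drug_users.add(author)
                abuse_cats[author] |= self.tweet_abuse[tid]
        return {
            "drug_tweets": drug_tweets,
            "drug_tweet_users": len(drug_users),
            "mention_tweets": sum(len(v) for v in mention_tweets_by.values()),
            "mention_users": len(mention_tweets_by),
            "abuse_ge1_users": sum(1 for v in abuse_cats.values() if len(v) >= 1),
            "abuse_ge2_users": sum(1 for v in abuse_cats.values() if len(v) >= 2),
        }

    @staticmethod
    def _author(tweet_id: str) -> str:
        return tweet_id.split("_", 1)[0].replace("t", "u", 1)


def _latent_scale(u: float, spread: float) -> float:
    return 1.0 + spread * (2.0 * u - 1.0)


def _effective_rates(config: SimConfig, rng: np.random.Generator):
    n = len(config.blocks)
    u = rng.random(n)
    v = rng.random(n)
    m_latent = config.coupling * u + (1.0 - config.coupling) * v
    abuse = [
        tuple(
            float(np.clip(p * _latent_scale(u[i], config.activity_spread), 0.0, 1.0))
            for p in config.blocks[i].abuse_probs
        )
        for i in range(n)
    ]
    mention = [
        float(
            np.clip(
                config.blocks[i].mention_prob * _latent_scale(m_latent[i], config.activity_spread),
                0.0,
                1.0,
            )
        )
        for i in range(n)
    ]
    return abuse, mention


def _compose_text(
    rng: np.random.Generator,
    drug_cat: str | None,
    abuse_cats: Sequence[str],
    mention: str | None,
) -> str:
    words = list(rng.choice(FILLER_WORDS, size=int(rng.integers(3, 7)), replace=True))
    if drug_cat is not None:
        words.append(DRUG_KEYWORD[drug_cat])
    for cat in abuse_cats:
        words.append(ABUSE_KEYWORD[cat])
    words = [words[i] for i in rng.permutation(len(words))]
    if mention is not None:
        pos = int(rng.integers(0, len(words) + 1))
        words.insert(pos, f"@{mention}")
    return " ".join(words)


def _lint(ct: CategorizedTweet, drug_cat: str | None, abuse_cats: set[str], target: str | None):
    intended_drugs = set() if drug_cat is None else {drug_cat}
    intended_mentions = () if target is None else (target,)
    if (
        set(ct.drug_categories) != intended_drugs
        or set(ct.abuse_categories) != abuse_cats
        or ct.mentions != intended_mentions
    ):
        raise RuntimeError(
            f"collision linter: generated text {ct.tweet.text!r} categorized as "
            f"({set(ct.drug_categories)}, {set(ct.abuse_categories)}, {ct.mentions}); "
            f"intended ({intended_drugs}, {abuse_cats}, {intended_mentions})"
        )


def simulate(config: SimConfig) -> tuple[FollowGraph, list[Tweet], GroundTruthLedger]:
    """Draw a follow graph and post corpus; return them with the truth ledger."""
    config.validate()
    n = config.n_users
    users = [f"u{i:04d}" for i in range(n)]
    block_of_idx = np.concatenate(
        [np.full(b.size, bi, dtype=int) for bi, b in enumerate(config.blocks)]
    )
    blocks = [[users[i] for i in np.flatnonzero(block_of_idx == bi)] for bi in range(len(config.blocks))]

    eff_abuse, eff_mention = _effective_rates(config, np.random.default_rng([config.seed, 9]))

    graph = FollowGraph(nodes=users)
    intra = np.array([b.intra_follow_prob for b in config.blocks])
    inter = np.array([b.inter_follow_prob for b in config.blocks])
    for i in range(n):
        rng = np.random.default_rng([config.seed, 0, i])
        draws = rng.random(n)
        probs = np.where(block_of_idx == block_of_idx[i], intra[block_of_idx[i]], inter[block_of_idx[i]])
        for j in np.flatnonzero(draws < probs):
            if j != i:
                graph.add_edge(users[i], users[int(j)])

    drug_lex, abuse_lex = DrugLexicon.default(), AbuseLexicon.default()
    tweets: list[Tweet] = []
    ledger = GroundTruthLedger(
        config=config,
        blocks=blocks,
        block_of={u: int(block_of_idx[i]) for i, u in enumerate(users)},
        drug_counts={u: 0 for u in users},
        tweet_drug={},
        tweet_abuse={},
        mention_events=[],
        effective_abuse_probs=eff_abuse,
        effective_mention_probs=eff_mention,
    )
    cat_names = list(DRUG_CATEGORIES)
    for i, user in enumerate(users):
        bi = int(block_of_idx[i])
        bcfg = config.blocks[bi]
        rng = np.random.default_rng([config.seed, 1, i])
        n_posts = int(rng.poisson(bcfg.tweet_rate))
        same_block = [u for u in blocks[bi] if u != user]
        others = None  # built lazily for cross-block mentions
        for j in range(n_posts):
            tid = f"t{i:04d}_{j:04d}"
            drug_cat: str | None = None
            abuse_cats: set[str] = set()
            target: str | None = None
            if rng.random() < bcfg.drug_tweet_prob:
                drug_cat = cat_names[int(rng.choice(len(cat_names), p=bcfg.drug_mixture))]
                flags = rng.random(len(ABUSE_CATEGORIES)) < np.asarray(eff_abuse[bi])
                abuse_cats = {c for c, f in zip(ABUSE_CATEGORIES, flags) if f}
                if rng.random() < eff_mention[bi]:
                    if config.cross_block_mention_prob > 0 and rng.random() < config.cross_block_mention_prob:
                        if others is None:
                            others = [u for u in users if u != user]
                        pool = others
                    else:
                        pool = same_block
                    if pool:
                        target = pool[int(rng.integers(len(pool)))]
            text = _compose_text(rng, drug_cat, sorted(abuse_cats), target)
            tweet = Tweet(
                tweet_id=tid,
                author_id=user,
                text=text,
                created_at=f"2012-01-01T00:00:00+{i:05d}.{j:05d}",
            )
            _lint(categorize_tweet(tweet, drug_lex, abuse_lex), drug_cat, abuse_cats, target)
            tweets.append(tweet)
            ledger.tweet_drug[tid] = frozenset([drug_cat] if drug_cat else [])
            ledger.tweet_abuse[tid] = frozenset(abuse_cats)
            if drug_cat is not None:
                ledger.drug_counts[user] += 1
            if target is not None:
                ledger.mention_events.append((tid, user, target))
    return graph, tweets, ledger


def default_config(
    seed: int,
    n_blocks: int = 5,
    block_size: int = 100,
    dominant_weight: float = 0.6,
    **block_kwargs,
) -> SimConfig:
    """A paper-scale world: dense 100-user blocks, each leaning toward one drug.

    Each block's drug mixture puts ``dominant_weight`` on a rotating dominant
    category and spreads the rest uniformly, so that an index user and their
    circle discuss similar drugs (positive topic correlation).
    """
    blocks = []
    k = len(DRUG_CATEGORIES)
    for b in range(n_blocks):
        mix = np.full(k, (1.0 - dominant_weight) / (k - 1))
        mix[b % k] = dominant_weight
        blocks.append(
            BlockConfig(size=block_size, drug_mixture=tuple(float(x) for x in mix), **block_kwargs)
        )
    return SimConfig(seed=seed, blocks=tuple(blocks))


def sweep_config(
    coupling: float,
    seed: int,
    n_blocks: int = 12,
    block_size: int = 40,
    tweet_rate: float = 50.0,
    drug_tweet_prob: float = 0.3,
    mention_prob: float = 0.08,
    abuse_prob: float = 0.012,
) -> SimConfig:
    """A sweep-sized world tuned so engagement/abuse fractions sit mid-range
    (away from 0/1 saturation), which is where block-level correlation is
    measurable."""
    block = BlockConfig(
        size=block_size,
        intra_follow_prob=0.3,
        inter_follow_prob=0.02,
        tweet_rate=tweet_rate,
        drug_tweet_prob=drug_tweet_prob,
        mention_prob=mention_prob,
        abuse_probs=(abuse_prob,) * len(ABUSE_CATEGORIES),
    )
    return SimConfig(seed=seed, blocks=(block,) * n_blocks, coupling=coupling)


def predicted_engagement_abuse_r(config: SimConfig, grid: int = 201) -> float:
    """Analytic approximation of the across-block engagement-abuse correlation.

    Treats per-user drug-post counts as Poisson(rate * drug_tweet_prob), so a
    user is a mention user with probability 1 - exp(-lambda * p_mention) and an
    abuse>=1 user with probability 1 - exp(-lambda * p_abuse_tweet); block
    fractions add binomial noise with variance p(1-p)/size. Integrates over the
    two block latents on a grid.
    """
    b = config.blocks[0]
    lam = b.tweet_rate * b.drug_tweet_prob
    c, spread = config.coupling, config.activity_spread
    u = np.linspace(0.0, 1.0, grid)[:, None]
    v = np.linspace(0.0, 1.0, grid)[None, :]

    def scale(x):
        return 1.0 + spread * (2.0 * x - 1.0)

    q = np.asarray(b.abuse_probs)
    p_abuse_tweet = 1.0 - np.prod(1.0 - q[None, None, :] * scale(u)[..., None], axis=-1)
    p_a = 1.0 - np.exp(-lam * p_abuse_tweet)  # varies with u only
    m_latent = c * u + (1.0 - c) * v
    p_m = 1.0 - np.exp(-lam * np.clip(b.mention_prob * scale(m_latent), 0.0, 1.0))

    var_a = p_a.var() + (p_a * (1.0 - p_a)).mean() / b.size
    var_m = p_m.var() + (p_m * (1.0 - p_m)).mean() / b.size
    cov = ((p_a - p_a.mean()) * (p_m - p_m.mean())).mean()
    if var_a <= 0 or var_m <= 0:
        return 0.0
    return float(cov / math.sqrt(var_a * var_m))


def sweep_coupling(configs: Sequence[SimConfig], replicates: int = 8) -> pd.DataFrame:
    """Run the analysis over planted circles at several coupling levels.

    For each config, ``replicates`` independent worlds are simulated (child
    seeds derived from the config seed); each planted block is summarized as a
    circle and the across-block Pearson correlation between the engagement
    percentage (mention users) and the abuse>=1 percentage is recorded. Rows
    report the Fisher-z mean correlation with a t-based 95% CI on the z scale.
    """
    if len(configs) < 1:
        raise ValueError("at least one config is required")
    rows = []
    for cfg in configs:
        rs, eng, abu = [], [], []
        for rep in range(replicates):
            child = int(np.random.default_rng([cfg.seed, 7, rep]).integers(2**31))
            g, tweets, ledger = simulate(replace(cfg, seed=child))
            cats = [categorize_tweet(t) for t in tweets]
            by_user: dict[str, list[CategorizedTweet]] = {u: [] for u in ledger.block_of}
            for ct in cats:
                by_user[ct.tweet.author_id].append(ct)
            e_pct, a_pct = [], []
            for bi in range(len(cfg.blocks)):
                circ = ledger.planted_circle(bi)
                s = summarize_circle(circ, by_user, circle_id=f"block{bi}")
                e_pct.append(100.0 * s.mention_users / s.circle_size)
                a_pct.append(100.0 * s.abuse_ge1_users / s.circle_size)
            res = pearson(e_pct, a_pct)
            if res.defined:
                rs.append(res.r)
            eng.append(float(np.mean(e_pct)))
            abu.append(float(np.mean(a_pct)))
        zs = np.arctanh(np.clip(rs, -0.999999, 0.999999))
        z_mean = float(zs.mean())
        if len(zs) > 1:
            from scipy import stats as _st

            half = float(_st.t.ppf(0.975, len(zs) - 1) * zs.std(ddof=1) / math.sqrt(len(zs)))
        else:
            half = math.inf
        rows.append(
            {
                "coupling": cfg.coupling,
                "engagement_pct": float(np.mean(eng)),
                "abuse_pct": float(np.mean(abu)),
                "r": fisher_mean(rs) if rs else math.nan,
                "r_ci_low": math.tanh(z_mean - half),
                "r_ci_high": math.tanh(z_mean + half),
                "n_replicates": len(rs),
            }
        )
    return pd.DataFrame(rows)
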