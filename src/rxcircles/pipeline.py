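"""End-to-end pipeline: simulate -> categorize -> select -> discover -> analyze.

``run_pipeline`` executes every stage on a synthetic world and writes the
summary table (one row per circle, published-table columns), per-circle
interaction graphs (GraphML) and a manifest sufficient to reproduce the run
bit-identically. ``verify_fixture`` recomputes every published aggregate from
the packaged 25-circle summary table and reports pass/fail per quantity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .analysis import aggregate_summaries, select_index_users, summarize_circle, build_interaction_graph
from .corpus import Table4Row, load_summary_fixture, write_follow_graph, write_tweets
from .discovery import DiscountPolicy, discover_circle
from .lexicon import CategorizedTweet, categorize_corpus, write_categorized
from .simulate import BlockConfig, SimConfig, simulate

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "FixtureReport",
    "run_pipeline",
    "verify_fixture",
    "PUBLISHED_AGGREGATES",
]

log = logging.getLogger("rxcircles.pipeline")

# Published aggregate values recomputable from the packaged 25-circle table:
# (computed-quantity name, expected value, absolute tolerance). Integer sums and
# 2-decimal quantities are matched at printed precision; 1-decimal means/SDs at
# half a printed unit.
PUBLISHED_AGGREGATES: tuple[tuple[str, float, float], ...] = (
    ("sum_drug_tweets", 7290, 0.0),
    ("sum_mention_tweets", 2788, 0.0),
    ("mean_drug_tweets", 291.6, 0.05),
    ("sd_drug_tweets", 183.5, 0.05),
    ("mean_drug_tweet_users", 53.96, 0.005),
    ("sd_drug_tweet_users", 24.8, 0.05),
    ("max_drug_tweet_users", 87, 0.0),
    ("min_drug_tweet_users", 14, 0.0),
    ("mean_mention_tweets", 111.5, 0.05),
    ("mean_mention_users", 37.8, 0.05),
    # the published table truncates (rather than rounds) these two SDs:
    # sample SDs are 21.269 and 18.882, printed as 21.2 and 18.8
    ("sd_mention_users", 21.2, 0.1),
    ("mean_abuse_ge1_users", 33.2, 0.05),
    ("sd_abuse_ge1_users", 18.8, 0.1),
    ("mean_abuse_ge2_users", 16.8, 0.05),
    ("sd_abuse_ge2_users", 10.9, 0.05),
    ("fisher_mean_topic_correlation", 0.73, 0.005),
    ("sd_topic_correlation", 0.31, 0.005),
    ("r_engagement_abuse_ge1", 0.85, 0.005),
    ("r_engagement_abuse_ge2", 0.81, 0.005),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full synthetic run."""

    sim: SimConfig
    target_size: int = 100
    gamma: float = 0.95
    prune_period: int = 5
    min_drug: int = 10
    max_drug: int = 100
    require_abuse: bool = True
    max_circles: int = 25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        sim_raw = raw.pop("sim")
        blocks = tuple(
            BlockConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in b.items()
                }
            )
            for b in sim_raw.pop("blocks")
        )
        sim = SimConfig(blocks=blocks, **sim_raw)
        return cls(sim=sim, **raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StageRecord:
    name: str
    outputs: list[str]
    counts: dict[str, int]


@dataclass
class RunManifest:
    """What a run did: config hash, versions, per-stage outputs and warnings."""

    config_hash: str
    seed: int
    versions: dict[str, str]
    stages: list[StageRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    status: str = "success"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def run_pipeline(
    config: PipelineConfig | str | Path, out_dir: str | Path
) -> RunManifest:
    """Execute all stages and write outputs under ``out_dir``.

    Status is ``"success"``, ``"partial"`` (some circle could not be grown to
    the target size, or no eligible index user existed), never silently empty:
    every anomaly is recorded in the manifest warnings.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graphs_dir = out / "interaction_graphs"
    graphs_dir.mkdir(exist_ok=True)

    import numpy as _np

    manifest = RunManifest(
        config_hash=config.digest(),
        seed=config.sim.seed,
        versions={
            "rxcircles": _pkg_version,
            "numpy": _np.__version__,
            "networkx": nx.__version__,
            "pandas": pd.__version__,
        },
    )

    # stage 1: simulate
    graph, tweets, ledger = simulate(config.sim)
    write_follow_graph(graph, out / "follow_graph.edgelist")
    write_tweets(tweets, out / "corpus.jsonl")
    manifest.stages.append(
        StageRecord(
            "simulate",
            [str(out / "follow_graph.edgelist"), str(out / "corpus.jsonl")],
            {"users": len(graph), "edges": len(graph.edges), "tweets": len(tweets)},
        )
    )
    log.info("simulate: %d users, %d edges, %d tweets", len(graph), len(graph.edges), len(tweets))

    # stage 2: categorize
    cats = categorize_corpus(tweets)
    write_categorized(cats, out / "categorized.jsonl")
    by_user: dict[str, list[CategorizedTweet]] = {u: [] for u in graph.nodes}
    for ct in cats:
        by_user.setdefault(ct.tweet.author_id, []).append(ct)
    n_drug = sum(1 for c in cats if c.is_drug_tweet)
    manifest.stages.append(
        StageRecord(
            "categorize",
            [str(out / "categorized.jsonl")],
            {"tweets": len(cats), "drug_tweets": n_drug},
        )
    )
    log.info("categorize: %d/%d drug tweets", n_drug, len(cats))

    # stage 3: select index users
    index_users = select_index_users(
        by_user, config.min_drug, config.max_drug, config.require_abuse
    )[: config.max_circles]
    manifest.stages.append(StageRecord("select", [], {"index_users": len(index_users)}))
    log.info("select: %d eligible index users", len(index_users))
    if not index_users:
        manifest.warnings.append("no eligible index users; summary is empty")
        manifest.status = "partial"

    # stage 4: discover circles
    policy = DiscountPolicy(gamma=config.gamma)
    circles = []
    for user in index_users:
        circle = discover_circle(
            graph, user, config.target_size, policy, config.prune_period
        )
        if circle.exhausted:
            manifest.warnings.append(
                f"circle {user}: stopped at {len(circle)}/{config.target_size} ({circle.stop_reason})"
            )
            manifest.status = "partial"
        circles.append(circle)
    manifest.stages.append(StageRecord("discover", [], {"circles": len(circles)}))
    log.info("discover: %d circles", len(circles))

    # stage 5: analyze
    summaries = []
    for circle in circles:
        summary = summarize_circle(circle, by_user, circle_id=circle.index_user)
        if not summary.topic_correlation_defined:
            manifest.warnings.append(f"circle {circle.index_user}: undefined topic correlation")
        summaries.append(summary)
        gpath = graphs_dir / f"{circle.index_user}.graphml"
        nx.write_graphml(build_interaction_graph(circle, by_user), gpath)
    rows = [
        {
            "circle_id": s.circle_id,
            "circle_size": s.circle_size,
            "drug_tweets": s.drug_tweets,
            "drug_tweet_users": s.drug_tweet_users,
            "mention_tweets": s.mention_tweets,
            "mention_users": s.mention_users,
            "topic_correlation": s.topic_correlation,
            "abuse_ge1_users": s.abuse_ge1_users,
            "abuse_ge2_users": s.abuse_ge2_users,
        }
        for s in summaries
    ]
    summary_path = out / "summary.csv"
    pd.DataFrame(
        rows,
        columns=[
            "circle_id",
            "circle_size",
            "drug_tweets",
            "drug_tweet_users",
            "mention_tweets",
            "mention_users",
            "topic_correlation",
            "abuse_ge1_users",
            "abuse_ge2_users",
        ],
    ).to_csv(summary_path, index=False)
    outputs = [str(summary_path), str(graphs_dir)]
    if len(summaries) >= 2:
        agg = aggregate_summaries(summaries)
        agg_path = out / "aggregates.json"
        agg_path.write_text(
            json.dumps(
                {
                    "mean": agg.table.loc["mean"].to_dict(),
                    "sd": agg.table.loc["sd"].to_dict(),
                    "topic_correlation_fisher_mean": agg.topic_correlation_fisher_mean,
                    "r_engagement_abuse_ge1": agg.engagement_abuse_r1.r,
                    "r_engagement_abuse_ge2": agg.engagement_abuse_r2.r,
                },
                indent=2,
                default=float,
            )
        )
        outputs.append(str(agg_path))
    manifest.stages.append(
        StageRecord("analyze", outputs, {"summaries": len(summaries)})
    )
    log.info("analyze: %d circle summaries", len(summaries))

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


@dataclass
class FixtureCheck:
    name: str
    computed: float
    expected: float
    tolerance: float
    passed: bool


@dataclass
class FixtureReport:
    checks: list[FixtureCheck]
    warnings: list[str] = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.checks])


def compute_fixture_aggregates(rows: Sequence[Table4Row]) -> tuple[dict[str, float], list[str]]:
    """All published aggregates recomputed from a summary table."""
    caught: list[str] = []
    df = pd.DataFrame(
        [
            {
                "drug_tweets": r.drug_tweets,
                "drug_tweet_users": r.drug_tweet_users,
                "mention_tweets": r.mention_tweets,
                "mention_users": r.mention_users,
                "topic_correlation": r.topic_correlation,
                "abuse_ge1_users": r.abuse_ge1_users,
                "abuse_ge2_users": r.abuse_ge2_users,
            }
            for r in rows
        ],
        dtype=float,
    )
    agg = aggregate_summaries(rows)
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        from .analysis import fisher_mean

        fisher = fisher_mean(df["topic_correlation"].to_numpy())
    caught.extend(str(w.message) for w in wlist)
    values = {
        "sum_drug_tweets": df["drug_tweets"].sum(),
        "sum_mention_tweets": df["mention_tweets"].sum(),
        "mean_drug_tweets": agg.column("drug_tweets"),
        "sd_drug_tweets": agg.column("drug_tweets", "sd"),
        "mean_drug_tweet_users": agg.column("drug_tweet_users"),
        "sd_drug_tweet_users": agg.column("drug_tweet_users", "sd"),
        "max_drug_tweet_users": df["drug_tweet_users"].max(),
        "min_drug_tweet_users": df["drug_tweet_users"].min(),
        "mean_mention_tweets": agg.column("mention_tweets"),
        "mean_mention_users": agg.column("mention_users"),
        "sd_mention_users": agg.column("mention_users", "sd"),
        "mean_abuse_ge1_users": agg.column("abuse_ge1_users"),
        "sd_abuse_ge1_users": agg.column("abuse_ge1_users", "sd"),
        "mean_abuse_ge2_users": agg.column("abuse_ge2_users"),
        "sd_abuse_ge2_users": agg.column("abuse_ge2_users", "sd"),
        "fisher_mean_topic_correlation": fisher,
        "sd_topic_correlation": agg.column("topic_correlation", "sd"),
        "r_engagement_abuse_ge1": agg.engagement_abuse_r1.r,
        "r_engagement_abuse_ge2": agg.engagement_abuse_r2.r,
    }
    return {k: float(v) for k, v in values.items()}, caught


def verify_fixture(rows: Sequence[Table4Row] | None = None) -> FixtureReport:
    """Recompute every published aggregate from the (packaged) summary table and
    compare at printed precision; integer quantities must match exactly."""
    if rows is None:
        rows = load_summary_fixture()
    values, caught = compute_fixture_aggregates(rows)
    checks = []
    for name, expected, tol in PUBLISHED_AGGREGATES:
        computed = values[name]
        delta = abs(computed - expected)
        checks.append(
            FixtureCheck(
                name=name,
                computed=computed,
                expected=expected,
                tolerance=tol,
                passed=delta <= tol if tol > 0 else math.isclose(computed, expected),
            )
        )
    return FixtureReport(checks=checks, warnings=caught)
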