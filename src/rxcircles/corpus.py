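"""Core domain types and readers/writers for post corpora, follow graphs and fixtures.

The corpus is a JSON-lines file of short public posts ("tweets"), one record per
line with fields ``{id, user, text, created_at}``. The follow graph is a directed
graph over opaque, case-sensitive user-id strings: an edge ``x -> y`` means *x*
subscribes to (follows) *y*. Follow direction matters downstream, both for
candidate generation and for scoring during social-circle discovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

__all__ = [
    "Tweet",
    "FollowGraph",
    "UserRecord",
    "Table4Row",
    "CorpusFormatError",
    "read_tweets",
    "write_tweets",
    "read_follow_graph",
    "write_follow_graph",
    "load_summary_fixture",
    "build_user_records",
]

DEFAULT_TWEET_CAP = 3200


class CorpusFormatError(ValueError):
    """A corpus, graph or fixture file violates its format contract."""


@dataclass(frozen=True)
class Tweet:
    """One post: an author, its text, and an optional timestamp."""

    tweet_id: str
    author_id: str
    text: str
    created_at: str | None = None

    def to_record(self) -> dict:
        rec = {"id": self.tweet_id, "user": self.author_id, "text": self.text}
        if self.created_at is not None:
            rec["created_at"] = self.created_at
        return rec


class FollowGraph:
    """Directed, unweighted follow relation over user ids.

    Backed by a :class:`networkx.DiGraph`; self-loops are rejected and edges are
    simple (duplicates collapse). ``e(x, y) = 1`` iff x follows y.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        self._g = nx.DiGraph()
        self._g.add_nodes_from(nodes)
        for x, y in edges:
            self.add_edge(x, y)

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    def add_node(self, u: str) -> None:
        self._g.add_node(u)

    def add_edge(self, x: str, y: str) -> None:
        if x == y:
            raise CorpusFormatError(f"self-loop rejected: {x!r} -> {y!r}")
        self._g.add_edge(x, y)

    def e(self, x: str, y: str) -> int:
        """Edge indicator: 1 if x follows y, else 0."""
        return 1 if self._g.has_edge(x, y) else 0

    def followees(self, u: str) -> set[str]:
        """Users that *u* follows (out-neighbours)."""
        return set(self._g.successors(u)) if u in self._g else set()

    def followers(self, u: str) -> set[str]:
        """Users following *u* (in-neighbours)."""
        return set(self._g.predecessors(u)) if u in self._g else set()

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges)

    def __contains__(self, u: str) -> bool:
        return u in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FollowGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def subgraph(self, users: Iterable[str]) -> "FollowGraph":
        users = set(users)
        fg = FollowGraph(nodes=users & self.nodes)
        for x, y in self._g.subgraph(users).edges:
            fg.add_edge(x, y)
        return fg


@dataclass
class UserRecord:
    """A user's retained posts, most recent first, capped at ``tweet_cap``.

    The cap mirrors the collection constraint of public-timeline APIs that only
    expose a bounded suffix of a user's history (default 3200 posts).
    """

    user_id: str
    tweets: list[Tweet] = field(default_factory=list)
    tweet_cap: int = DEFAULT_TWEET_CAP

    def __post_init__(self) -> None:
        if self.tweet_cap <= 0:
            raise ValueError("tweet_cap must be positive")
        if len(self.tweets) > self.tweet_cap:
            self.tweets = self.tweets[: self.tweet_cap]


@dataclass(frozen=True)
class Table4Row:
    """One circle's published summary statistics (counts over a 100-member circle)."""

    network_id: int
    drug_tweets: int
    drug_tweet_users: int
    mention_tweets: int
    mention_users: int
    topic_correlation: float
    abuse_ge1_users: int
    abuse_ge2_users: int

    def validate(self, circle_size: int = 100) -> None:
        if not self.mention_tweets <= self.drug_tweets:
            raise ValueError("mention_tweets must not exceed drug_tweets")
        if not self.mention_users <= self.drug_tweet_users:
            raise ValueError("mention_users must not exceed drug_tweet_users")
        if not (self.abuse_ge2_users <= self.abuse_ge1_users <= self.drug_tweet_users):
            raise ValueError("abuse-level user counts must be nested")
        for n in (self.drug_tweet_users, self.mention_users, self.abuse_ge1_users):
            if n > circle_size:
                raise ValueError(f"user count {n} exceeds circle size {circle_size}")
        if not -1.0 <= self.topic_correlation <= 1.0:
            raise ValueError("topic_correlation must lie in [-1, 1]")


def read_tweets(path: str | Path) -> list[Tweet]:
    """Read a JSON-lines corpus; blank lines are skipped, order is preserved."""
    tweets: list[Tweet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}: line {lineno}: malformed JSON: {exc}") from exc
            if not isinstance(rec, dict):
                raise CorpusFormatError(f"{path}: line {lineno}: record is not an object")
            for key in ("user", "text"):
                if key not in rec or rec[key] is None:
                    raise CorpusFormatError(f"{path}: line {lineno}: missing field {key!r}")
            tweets.append(
                Tweet(
                    tweet_id=str(rec.get("id", f"line{lineno}")),
                    author_id=str(rec["user"]),
                    text=str(rec["text"]),
                    created_at=rec.get("created_at"),
                )
            )
    return tweets


def write_tweets(tweets: Iterable[Tweet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(json.dumps(t.to_record(), ensure_ascii=False) + "\n")


def _iter_edge_lines(path: Path) -> Iterator[tuple[int, str, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected 'follower followee', got {line!r}"
                )
            yield lineno, parts[0], parts[1]


def read_follow_graph(path: str | Path) -> FollowGraph:
    """Read a follow graph from a whitespace edge list or a GraphML file.

    GraphML is detected by the ``.graphml`` suffix. Duplicate edge lines collapse
    to one edge; a self-loop anywhere is an error.
    """
    path = Path(path)
    fg = FollowGraph()
    if path.suffix.lower() == ".graphml":
        g = nx.read_graphml(path)
        if not g.is_directed():
            raise CorpusFormatError(f"{path}: follow graph must be directed")
        fg._g.add_nodes_from(str(n) for n in g.nodes)
        for x, y in g.edges:
            fg.add_edge(str(x), str(y))
        return fg
    for lineno, x, y in _iter_edge_lines(path):
        if x == y:
            raise CorpusFormatError(f"{path}: line {lineno}: self-loop {x!r}")
        fg.add_edge(x, y)
    return fg


def write_follow_graph(graph: FollowGraph, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        nx.write_graphml(graph.graph, path)
        return
    with open(path, "w", encoding="utf-8") as fh:
        for x, y in sorted(graph.edges):
            fh.write(f"{x} {y}\n")


def load_summary_fixture(path: str | Path | None = None) -> list[Table4Row]:
    """Load the packaged 25-circle published summary table (or a CSV at *path*)."""
    if path is None:
        source = resources.files("rxcircles.data").joinpath("table4.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    expected = {f.name for f in Table4Row.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    missing = expected - set(df.columns)
    if missing:
        raise CorpusFormatError(f"summary fixture missing columns: {sorted(missing)}")
    rows = [Table4Row(**{k: rec[k] for k in expected}) for rec in df.to_dict("records")]
    if path is None and len(rows) != 25:
        raise CorpusFormatError(f"packaged fixture must have 25 rows, found {len(rows)}")
    for row in rows:
        row.validate()
    return rows


def build_user_records(
    tweets: Iterable[Tweet], tweet_cap: int = DEFAULT_TWEET_CAP
) -> dict[str, UserRecord]:
    """Group a corpus by author, most recent first, enforcing the per-user cap.

    Posts with timestamps sort by ``created_at`` descending; untimestamped
    corpora are assumed already newest-first within each author.
    """
    by_user: dict[str, list[Tweet]] = {}
    for t in tweets:
        by_user.setdefault(t.author_id, []).append(t)
    records: dict[str, UserRecord] = {}
    for user, posts in by_user.items():
        if all(p.created_at is not None for p in posts):
            posts = sorted(posts, key=lambda p: p.created_at, reverse=True)  # type: ignore[arg-type,return-value]
        records[user] = UserRecord(user_id=user, tweets=posts, tweet_cap=tweet_cap)
    return records
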