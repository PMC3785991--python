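import numpy as np
import pytest

from rxcircles.corpus import FollowGraph, Tweet
from rxcircles.lexicon import AbuseLexicon, CategorizedTweet, DrugLexicon


@pytest.fixture(scope="session")
def drug_lex() -> DrugLexicon:
    return DrugLexicon.default()


@pytest.fixture(scope="session")
def abuse_lex() -> AbuseLexicon:
    return AbuseLexicon.default()


def make_ct(user, drugs=(), abuse=(), mentions=(), tweet_id=None, text=""):
    """Hand-build a categorized post without going through the lexicon."""
    return CategorizedTweet(
        tweet=Tweet(tweet_id=tweet_id or f"{user}-{id(object())}", author_id=user, text=text),
        drug_categories=frozenset(drugs),
        abuse_categories=frozenset(abuse),
        mentions=tuple(mentions),
    )


def random_digraph(rng: np.random.Generator, n_max: int = 30, p: float | None = None):
    """A random directed graph over string node ids, for oracle comparisons."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.08, 0.5)) if p is None else p
    nodes = [f"n{i:02d}" for i in range(n)]
    g = FollowGraph(nodes=nodes)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    for i, j in zip(*np.nonzero(mask)):
        g.add_edge(nodes[int(i)], nodes[int(j)])
    return g, nodes
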