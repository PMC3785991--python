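"""Lexicon-based categorization of posts into drug and risk-behavior categories.

Posts are first categorized by the prescription drug they mention (7 categories)
and, only if they mention a drug, further categorized into 8 risk/abusive
behavior categories (overdose/larger doses, co-ingestion, more frequent doses,
alternative motives/dependence, alternative routes of admission, legitimacy of
obtaining, trading/selling, seeking).

Matching semantics
------------------
* Case-insensitive; text is tokenized on non-alphanumeric boundaries.
* A plain keyword matches a whole token; a multi-word keyword matches a
  contiguous token sequence.
* A keyword ending in ``*`` matches any token beginning with the stem
  (``painkiller*`` matches "painkillers"; ``overdose`` does NOT match
  "overdosing").

Three restrictions apply to behavior keywords:

1. The co-ingestion keywords ``xanax`` and ``adderall`` are inert when the
   post's drug categories already include Xanax resp. Adderall — a drug cannot
   be its own co-ingestant. If a Xanax post also contains the token
   "adderall", co-ingestion still fires via the other drug's keyword.
2. ``test``, ``final``, ``study``, ``studying`` fire only for Adderall posts.
3. ``skinny`` fires only for Stimulants posts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import Tweet

__all__ = [
    "DRUG_CATEGORIES",
    "ABUSE_CATEGORIES",
    "DrugLexicon",
    "AbuseLexicon",
    "CategorizedTweet",
    "match_keywords",
    "categorize_drugs",
    "categorize_abuse",
    "extract_mentions",
    "categorize_tweet",
    "categorize_corpus",
    "write_categorized",
    "read_categorized",
]

DRUG_CATEGORIES: tuple[str, ...] = (
    "Adderall",
    "Xanax",
    "Klonopin",
    "Valium",
    "Painkillers",
    "Depressants",
    "Stimulants",
)

ABUSE_CATEGORIES: tuple[str, ...] = (
    "larger_doses_overdose",
    "co_ingestion",
    "more_frequent_doses",
    "alternative_motives_dependence",
    "alternative_routes",
    "legitimacy_of_obtaining",
    "trading_selling",
    "seeking",
)

# (category, keyword) -> drug category required (True) or forbidden (False)
_RESTRICTIONS: dict[tuple[str, str], tuple[str, bool]] = {
    ("co_ingestion", "xanax"): ("Xanax", False),
    ("co_ingestion", "adderall"): ("Adderall", False),
    ("alternative_motives_dependence", "test"): ("Adderall", True),
    ("alternative_motives_dependence", "final"): ("Adderall", True),
    ("alternative_motives_dependence", "study"): ("Adderall", True),
    ("alternative_motives_dependence", "studying"): ("Adderall", True),
    ("alternative_motives_dependence", "skinny"): ("Stimulants", True),
}

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_MENTION_RE = re.compile(r"(?<![A-Za-z0-9])@([A-Za-z0-9_]{1,15})(?![A-Za-z0-9_])")


def _normalize(text: str) -> str:
    return " ".join(_TOKEN_RE.findall(text.lower()))


def _keyword_pattern(keyword: str) -> str:
    """Translate one keyword into a regex over normalized (space-joined) tokens."""
    kw = keyword.strip().lower()
    wildcard = kw.endswith("*")
    if wildcard:
        kw = kw[:-1]
    if "*" in kw:
        raise ValueError(f"only a trailing '*' wildcard is supported: {keyword!r}")
    toks = _TOKEN_RE.findall(kw)
    if not toks:
        raise ValueError(f"keyword has no alphanumeric content: {keyword!r}")
    body = " ".join(re.escape(t) for t in toks)
    suffix = r"[a-z0-9]*" if wildcard else r"\b"
    return rf"\b{body}{suffix}"


@lru_cache(maxsize=4096)
def _compile(keywords: tuple[str, ...]) -> re.Pattern[str]:
    return re.compile("|".join(_keyword_pattern(k) for k in keywords))


def match_keywords(text: str, keywords: Sequence[str]) -> bool:
    """True iff some keyword matches *text* under the token/wildcard semantics."""
    if not text or not keywords:
        return False
    return _compile(tuple(dict.fromkeys(keywords))).search(_normalize(text)) is not None


class _Lexicon:
    """Category -> keyword-list mapping with precompiled matchers."""

    expected_categories: tuple[str, ...] = ()

    def __init__(self, categories: Mapping[str, Sequence[str]]):
        if self.expected_categories and set(categories) != set(self.expected_categories):
            raise ValueError(
                f"lexicon must define exactly the categories {self.expected_categories}, "
                f"got {sorted(categories)}"
            )
        order = self.expected_categories or tuple(categories)
        # dedupe, preserving first occurrence (tables repeat a few keywords)
        self.categories: dict[str, tuple[str, ...]] = {
            c: tuple(dict.fromkeys(k.strip().lower() for k in categories[c])) for c in order
        }
        for c, kws in self.categories.items():
            _compile(kws)  # fail fast on bad wildcards

    @classmethod
    def from_file(cls, path: str | Path):
        cats: dict[str, list[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                try:
                    cat, kw = line.split("\t", 1)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 'category<TAB>keyword'"
                    ) from exc
                cats.setdefault(cat.strip(), []).append(kw.strip())
        return cls(cats)

    _default_cache: dict[type, "_Lexicon"] = {}

    @classmethod
    def default(cls):
        if cls not in _Lexicon._default_cache:
            source = resources.files("rxcircles.data").joinpath(cls._default_file)
            with resources.as_file(source) as p:
                _Lexicon._default_cache[cls] = cls.from_file(p)
        return _Lexicon._default_cache[cls]

    def match(self, text: str, category: str) -> bool:
        return match_keywords(text, self.categories[category])


class DrugLexicon(_Lexicon):
    """The 7 prescription-drug categories and their keyword lists."""

    expected_categories = DRUG_CATEGORIES
    _default_file = "drug_lexicon.tsv"


class AbuseLexicon(_Lexicon):
    """The 8 risk/abusive-behavior categories, with per-drug keyword restrictions."""

    expected_categories = ABUSE_CATEGORIES
    _default_file = "abuse_lexicon.tsv"

    def active_keywords(self, category: str, drug_categories: Iterable[str]) -> tuple[str, ...]:
        """Keywords of *category* that may fire given the post's drug categories.

        A required-type gate (``test`` etc.) needs its drug in the post's
        categories. A forbidden-type gate (the co-ingestion drug names) is
        per-drug: the keyword stays active as long as the post has at least one
        *other* drug category for which it is a legitimate co-ingestant — so a
        post in both the Xanax and Adderall categories still fires co-ingestion
        via the other drug's name.
        """
        drugs = set(drug_categories)
        out = []
        for kw in self.categories[category]:
            rule = _RESTRICTIONS.get((category, kw))
            if rule is None:
                out.append(kw)
                continue
            drug, required = rule
            active = (drug in drugs) if required else bool(drugs - {drug})
            if active:
                out.append(kw)
        return tuple(out)


@dataclass(frozen=True)
class CategorizedTweet:
    """A post together with its drug categories, behavior categories and mentions."""

    tweet: Tweet
    drug_categories: frozenset[str]
    abuse_categories: frozenset[str]
    mentions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.abuse_categories and not self.drug_categories:
            raise ValueError("behavior categories require at least one drug category")
        if len(set(self.mentions)) != len(self.mentions):
            raise ValueError("mentions must be deduplicated")

    @property
    def is_drug_tweet(self) -> bool:
        return bool(self.drug_categories)

    @property
    def is_mention_tweet(self) -> bool:
        """A drug post directed at another user via @-mention."""
        return self.is_drug_tweet and bool(self.mentions)

    def to_record(self) -> dict:
        return {
            **self.tweet.to_record(),
            "drug_categories": sorted(self.drug_categories),
            "abuse_categories": sorted(self.abuse_categories),
            "mentions": list(self.mentions),
        }


def categorize_drugs(text: str, lex: DrugLexicon | None = None) -> set[str]:
    """Every drug category with at least one keyword match (possibly several)."""
    lex = lex or DrugLexicon.default()
    return {c for c in lex.categories if lex.match(text, c)}


def categorize_abuse(
    text: str, drug_categories: Iterable[str], lex: AbuseLexicon | None = None
) -> set[str]:
    """Behavior categories of a post; empty unless the post mentions a drug."""
    drugs = set(drug_categories)
    if not drugs:
        return set()
    lex = lex or AbuseLexicon.default()
    out = set()
    for cat in lex.categories:
        active = lex.active_keywords(cat, drugs)
        if active and match_keywords(text, active):
            out.add(cat)
    return out


def extract_mentions(text: str) -> list[str]:
    """@-mentioned handles, in order of appearance, deduplicated.

    A handle is 1-15 characters of ``[A-Za-z0-9_]``; the ``@`` must not be
    preceded by an alphanumeric character (so e-mail addresses don't count).
    """
    return list(dict.fromkeys(_MENTION_RE.findall(text)))


def categorize_tweet(
    tweet: Tweet,
    drug_lex: DrugLexicon | None = None,
    abuse_lex: AbuseLexicon | None = None,
) -> CategorizedTweet:
    drugs = categorize_drugs(tweet.text, drug_lex)
    return CategorizedTweet(
        tweet=tweet,
        drug_categories=frozenset(drugs),
        abuse_categories=frozenset(categorize_abuse(tweet.text, drugs, abuse_lex)),
        mentions=tuple(extract_mentions(tweet.text)),
    )


def categorize_corpus(
    tweets: Sequence[Tweet],
    drug_lex: DrugLexicon | None = None,
    abuse_lex: AbuseLexicon | None = None,
) -> list[CategorizedTweet]:
    """Categorize every post, preserving order. Pure and deterministic."""
    drug_lex = drug_lex or DrugLexicon.default()
    abuse_lex = abuse_lex or AbuseLexicon.default()
    return [categorize_tweet(t, drug_lex, abuse_lex) for t in tweets]


def write_categorized(records: Iterable[CategorizedTweet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.to_record(), ensure_ascii=False) + "\n")


def read_categorized(path: str | Path) -> list[CategorizedTweet]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                CategorizedTweet(
                    tweet=Tweet(
                        tweet_id=str(rec["id"]),
                        author_id=str(rec["user"]),
                        text=rec["text"],
                        created_at=rec.get("created_at"),
                    ),
                    drug_categories=frozenset(rec["drug_categories"]),
                    abuse_categories=frozenset(rec["abuse_categories"]),
                    mentions=tuple(rec["mentions"]),
                )
            )
    return out
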