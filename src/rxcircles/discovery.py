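"""Local social-circle discovery on a directed follow graph.

A *social circle* is a densely connected set of mutually aware users around a
single index (seed) user. Unlike an ego network it may contain users with no
direct tie to the index, included by virtue of their many connections to the
index's alters. Discovery is a local community-search procedure: the circle is
initialized with the index user and grown one member at a time until a target
size is reached.

At each step the candidate pool is every user followed by at least one current
member (out-edges only; scoring then uses both directions). A candidate ``n``
is scored against the circle ``SC`` as::

    score(n) = min( sum_{c in SC} e(n, c) * delta(s(c)),
                    sum_{c in SC} e(c, n) * delta(s(c)) )

where ``e(x, y)`` is the follow-edge indicator, ``s(c)`` the step at which
member ``c`` was added, and ``delta`` a non-increasing discount that damps the
pull of late additions so the circle does not drift away from the index. With
``delta == 1`` this reduces to the plain min(#members followed, #members
following). Every ``prune_period`` additions the lowest-scoring non-index
member is removed, tightening cohesion.

The discount's functional form is a policy choice: the default is exponential,
``delta(s) = gamma**s`` with ``gamma = 0.95``; ``gamma = 1`` recovers the
undiscounted counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import FollowGraph

__all__ = ["DiscountPolicy", "SocialCircle", "candidate_set", "score", "discover_circle"]

DEFAULT_GAMMA = 0.95
DEFAULT_TARGET_SIZE = 100
DEFAULT_PRUNE_PERIOD = 5


@dataclass(frozen=True)
class DiscountPolicy:
    """Step discount ``delta(s) = gamma**s``; ``gamma = 1`` disables discounting."""

    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")

    def discount(self, step: int) -> float:
        if step < 0:
            raise ValueError("step must be non-negative")
        return self.gamma**step


@dataclass
class SocialCircle:
    """An ordered set of members around an index user.

    ``members`` maps each user id to the addition step at which it joined; the
    index user has step 0 and is never removed. ``stop_reason`` is
    ``"target_reached"``, ``"exhausted"`` (candidate pool ran dry) or
    ``"max_additions"`` (safety cap hit).
    """

    index_user: str
    members: dict[str, int] = field(default_factory=dict)
    target_size: int = DEFAULT_TARGET_SIZE
    stop_reason: str = "target_reached"

    def __post_init__(self) -> None:
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")
        if not self.members:
            self.members = {self.index_user: 0}
        if self.members.get(self.index_user) != 0:
            raise ValueError("index user must be a member at step 0")
        others = [s for u, s in self.members.items() if u != self.index_user]
        if len(set(others)) != len(others) or any(s <= 0 for s in others):
            raise ValueError("non-index member steps must be distinct positive integers")
        if len(self.members) > self.target_size:
            raise ValueError("circle exceeds target size")

    @property
    def exhausted(self) -> bool:
        return self.stop_reason != "target_reached"

    @property
    def member_ids(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, user: str) -> bool:
        return user in self.members


def candidate_set(graph: FollowGraph, circle: SocialCircle) -> set[str]:
    """Non-members followed by at least one circle member."""
    out: set[str] = set()
    for member in circle.members:
        out |= graph.followees(member)
    return out - circle.member_ids


def score(
    candidate: str,
    graph: FollowGraph,
    circle: SocialCircle,
    policy: DiscountPolicy | None = None,
) -> float:
    """Discounted min of (members the candidate follows, members following it)."""
    if candidate in circle:
        raise ValueError(f"candidate {candidate!r} is already a circle member")
    policy = policy or DiscountPolicy()
    follows = 0.0  # candidate -> member
    followed = 0.0  # member -> candidate
    for member, step in circle.members.items():
        d = policy.discount(step)
        if graph.e(candidate, member):
            follows += d
        if graph.e(member, candidate):
            followed += d
    return min(follows, followed)


def _member_score(
    member: str, graph: FollowGraph, circle: SocialCircle, policy: DiscountPolicy
) -> float:
    """Score of an existing member against the rest of the circle (for pruning)."""
    rest = SocialCircle(
        index_user=circle.index_user,
        members={u: s for u, s in circle.members.items() if u != member},
        target_size=circle.target_size,
        stop_reason=circle.stop_reason,
    )
    return score(member, graph, rest, policy)


def discover_circle(
    graph: FollowGraph,
    index_user: str,
    target_size: int = DEFAULT_TARGET_SIZE,
    policy: DiscountPolicy | None = None,
    prune_period: int = DEFAULT_PRUNE_PERIOD,
    max_additions: int | None = None,
) -> SocialCircle:
    """Grow a social circle of ``target_size`` members around ``index_user``.

    Each iteration adds the highest-scoring candidate (ties broken toward the
    lexicographically smallest id); after every ``prune_period`` additions the
    lowest-scoring non-index member is pruned (same tie-break). Steps count
    additions and are never reassigned; a pruned user may be re-added later with
    a new, later step. If the candidate pool empties before the target size is
    reached the partial circle is returned with ``stop_reason="exhausted"``.
    """
    if index_user not in graph:
        raise ValueError(f"index user {index_user!r} not in graph")
    if prune_period < 1:
        raise ValueError("prune_period must be >= 1")
    policy = policy or DiscountPolicy()
    if max_additions is None:
        max_additions = 50 * target_size

    circle = SocialCircle(index_user=index_user, target_size=target_size)
    additions = 0
    while len(circle) < target_size:
        candidates = candidate_set(graph, circle)
        if not candidates:
            circle.stop_reason = "exhausted"
            break
        if additions >= max_additions:
            circle.stop_reason = "max_additions"
            break
        # argmax score, ties -> lexicographically smallest id
        best = min(candidates, key=lambda u: (-score(u, graph, circle, policy), u))
        additions += 1
        circle.members[best] = additions
        if len(circle) == target_size:
            break
        if additions % prune_period == 0 and len(circle) > 1:
            victim = min(
                (u for u in circle.members if u != index_user),
                key=lambda u: (_member_score(u, graph, circle, policy), u),
            )
            del circle.members[victim]
    return circle
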