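"""Naive, literal re-implementation of social-circle discovery used as an oracle.

Works directly on an edge set and recomputes every candidate score from scratch
at every step; intentionally shares no code with the package implementation.
"""

from __future__ import annotations


def bruteforce_discover(
    edges: set[tuple[str, str]],
    index: str,
    target: int,
    gamma: float = 1.0,
    prune_period: int = 5,
    max_additions: int | None = None,
) -> tuple[dict[str, int], str]:
    """Grow-and-prune trace following the stated rules verbatim.

    Returns (members -> addition step, stop reason). Tie-breaks: smallest id.
    """
    members: dict[str, int] = {index: 0}
    additions = 0
    cap = 50 * target if max_additions is None else max_additions

    def sc(v: str, mem: dict[str, int]) -> float:
        follows = sum(gamma**s for c, s in mem.items() if (v, c) in edges)
        followed = sum(gamma**s for c, s in mem.items() if (c, v) in edges)
        return min(follows, followed)

    reason = "target_reached"
    while len(members) < target:
        candidates = {y for (x, y) in edges if x in members} - set(members)
        if not candidates:
            reason = "exhausted"
            break
        if additions >= cap:
            reason = "max_additions"
            break
        best = sorted(candidates, key=lambda v: (-sc(v, members), v))[0]
        additions += 1
        members[best] = additions
        if len(members) == target:
            break
        if additions % prune_period == 0 and len(members) > 1:
            victim = sorted(
                (v for v in members if v != index),
                key=lambda v: (sc(v, {u: s for u, s in members.items() if u != v}), v),
            )[0]
            del members[victim]
    return members, reason
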