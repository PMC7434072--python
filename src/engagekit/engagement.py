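"""Frequency-based engagement metrics and top-k user group selection.

Three engagement archetypes are defined per calendar year:

* conversation initiators — users who start the most threads,
* conversation attractors — users whose posts draw the most replies,
* frequent posters — users who post the most messages.

Selecting the top ``k`` users per group per year (the classic design is
k=3 over 16 years, i.e. 3 x 3 x 16 = 144 assignment slots) yields the
highly engaged stratum whose message content is then cross-tabulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .forum_model import AbstinenceStatus, Corpus, UserRecord

__all__ = [
    "UserGroup",
    "EngagementProfile",
    "UserGroupAssignment",
    "compute_profiles",
    "profiles_frame",
    "select_top_users",
    "select_top_groups",
    "group_summary",
    "proportion",
]


class UserGroup(Enum):
    INITIATOR = "conversation_initiator"
    ATTRACTOR = "conversation_attractor"
    FREQUENT_POSTER = "frequent_poster"

    @property
    def metric(self) -> str:
        return _GROUP_METRIC[self]


class EngagementProfile(NamedTuple):
    user_id: str
    year: int
    threads_initiated: int
    posts: int
    replies_attracted: int


@dataclass(frozen=True)
class UserGroupAssignment:
    user_id: str
    group: UserGroup
    year: int
    rank: int  # 1 = highest


_GROUP_METRIC = {
    UserGroup.INITIATOR: "threads_initiated",
    UserGroup.ATTRACTOR: "replies_attracted",
    UserGroup.FREQUENT_POSTER: "posts",
}


def compute_profiles(corpus: Corpus) -> list[EngagementProfile]:
    """Per-user per-calendar-year engagement counts.

    ``threads_initiated`` counts threads whose earliest message has this
    sender; ``posts`` counts all messages sent; ``replies_attracted``
    counts messages addressed to this user via ``recipient_id`` or — when
    the recipient is absent — posted into a thread this user rooted.
    Self-replies never count. A reply is attributed to the year it was
    posted in.
    """
    roots = corpus.thread_roots()
    counts: dict[tuple[str, int], dict[str, int]] = {}

    def bump(user_id: str, year: int, key: str) -> None:
        slot = counts.setdefault((user_id, year), {"threads_initiated": 0, "posts": 0, "replies_attracted": 0})
        slot[key] += 1

    for m in corpus.messages:
        bump(m.sender_id, m.year, "posts")
        root = roots[m.thread_id]
        if root.message_id == m.message_id:
            bump(m.sender_id, m.year, "threads_initiated")
            continue
        if m.recipient_id is not None:
            target: Optional[str] = m.recipient_id
        else:
            target = root.sender_id
        if target is not None and target != m.sender_id:
            bump(target, m.year, "replies_attracted")

    return [
        EngagementProfile(user_id=u, year=y, **slot)
        for (u, y), slot in sorted(counts.items())
    ]


def profiles_frame(profiles: Iterable[EngagementProfile]) -> pd.DataFrame:
    return pd.DataFrame(profiles, columns=EngagementProfile._fields)


def select_top_users(
    profiles: Sequence[EngagementProfile],
    metric: UserGroup | str,
    k: int,
    years: tuple[int, int],
) -> list[UserGroupAssignment]:
    """The ``k`` users with the highest group metric, per year.

    Ties are broken deterministically: higher post count first, then
    lexicographic user_id. Exact duplicate profiles are collapsed, so the
    selection is invariant to input ordering and to duplicate injection.
    Years with fewer active users than ``k`` contribute what they have,
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    group = metric if isinstance(metric, UserGroup) else UserGroup(metric)
    column = group.metric
    lo, hi = years
    out: list[UserGroupAssignment] = []
    by_year: dict[int, list[EngagementProfile]] = {}
    for p in profiles:
        by_year.setdefault(p.year, []).append(p)
    for year in range(lo, hi + 1):
        candidates = [p for p in set(by_year.get(year, [])) if p.posts > 0]
        candidates.sort(key=lambda p: (-getattr(p, column), -p.posts, p.user_id))
        if len(candidates) < k:
            warnings.warn(
                f"{group.value}, year {year}: only {len(candidates)} active user(s) "
                f"for k={k}",
                stacklevel=2,
            )
        out.extend(
            UserGroupAssignment(user_id=p.user_id, group=group, year=year, rank=r)
            for r, p in enumerate(candidates[:k], start=1)
        )
    return out


def select_top_groups(
    profiles: Sequence[EngagementProfile], k: int, years: tuple[int, int]
) -> list[UserGroupAssignment]:
    """Top-k selection for all three engagement groups."""
    out: list[UserGroupAssignment] = []
    for group in UserGroup:
        out.extend(select_top_users(profiles, group, k, years))
    return out


def proportion(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Round-half-up percentage — the shared rounding rule for reported shares.

    >>> proportion(19056, 26466, 2)
    72.0
    >>> proportion(119, 144, 1)
    82.6
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def group_summary(
    assignments: Sequence[UserGroupAssignment],
    users: Sequence[UserRecord] | Mapping[str, UserRecord],
    statuses: Mapping[tuple[str, int], AbstinenceStatus],
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-group demographic and abstinence-category summary.

    Percentages are computed over the group's distinct (user, year)
    assignment slots — a user selected in several years contributes one
    slot per year, matching how the selection itself is counted. Returns
    one row per group with slot/user counts, gender shares, mean (SD) age,
    and the share of slots in each abstinence category.
    """
    if not assignments:
        raise ValueError("assignments must be non-empty")
    user_map = users if isinstance(users, Mapping) else {u.user_id: u for u in users}
    rows = []
    for group in UserGroup:
        slots = sorted({(a.user_id, a.year) for a in assignments if a.group is group})
        if not slots:
            continue
        n = len(slots)
        records = [user_map.get(uid) for uid, _ in slots]
        genders = [(r.gender or "other/unknown") if r else "other/unknown" for r in records]
        ages = pd.Series([r.age for r in records if r and r.age is not None], dtype="float64")
        row: dict[str, object] = {
            "group": group.value,
            "n_slots": n,
            "n_distinct_users": len({uid for uid, _ in slots}),
            "pct_female": proportion(genders.count("female"), n, decimals),
            "pct_male": proportion(genders.count("male"), n, decimals),
            "mean_age": round(float(ages.mean()), decimals) if len(ages) else float("nan"),
            "sd_age": round(float(ages.std(ddof=1)), decimals) if len(ages) > 1 else float("nan"),
        }
        for status in AbstinenceStatus:
            hits = sum(
                1 for uid, yr in slots
                if statuses.get((uid, yr), AbstinenceStatus.UNKNOWN) is status
            )
            row[f"pct_{status.name.lower()}"] = proportion(hits, n, decimals)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
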