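"""Threaded-forum corpus schema, I/O, and abstinence-status inference.

The data model mirrors classic threaded health forums: every post carries a
message id, a thread id, a sender id and an optional recipient id (empty
meaning "posted to the forum at large"), plus a timestamp and free text.
Users may additionally carry event-log quit dates; where logs are missing,
abstinence status is inferred from the quit-duration signature strings that
community members conventionally embed in their messages
("////400 days smoke free ...").
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "Message",
    "UserRecord",
    "AbstinenceStatus",
    "Corpus",
    "SchemaError",
    "RowError",
    "read_corpus",
    "write_corpus",
    "read_users",
    "write_users",
    "parse_quit_duration",
    "bin_abstinence",
    "status_per_user_year",
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
]

#: Mean Gregorian month / Julian year lengths used to turn day counts into
#: the six abstinence categories. Fixed constants keep binning deterministic.
DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25

MESSAGE_FIELDS = ("message_id", "thread_id", "sender_id", "recipient_id", "timestamp", "body")
USER_FIELDS = ("user_id", "age", "gender", "quit_dates")


class SchemaError(ValueError):
    """A corpus-level invariant is violated (missing column, duplicate id)."""


class RowError(ValueError):
    """A single record is malformed; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass(frozen=True)
class Message:
    message_id: str
    thread_id: str
    sender_id: str
    recipient_id: Optional[str]
    timestamp: datetime
    body: str

    @property
    def year(self) -> int:
        return self.timestamp.year


@dataclass
class UserRecord:
    user_id: str
    age: Optional[int] = None
    gender: Optional[str] = None  # "female" | "male" | "other/unknown"
    quit_dates: list[date] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.quit_dates = sorted(self.quit_dates)


class AbstinenceStatus(Enum):
    """Quit-duration category assigned per (user, year)."""

    LT_3M = "abstinent <3 months"
    M3_TO_6M = "abstinent 3-6 months"
    M6_TO_1Y = "abstinent 6 months-1 year"
    Y1_TO_2Y = "abstinent 1-2 years"
    GT_2Y = "abstinent >2 years"
    ACTIVE_SMOKER = "active smoker"
    UNKNOWN = "unknown"


@dataclass
class Corpus:
    """A validated forum corpus: messages, users, and the inclusive year range.

    Senders without a user-table row are auto-stubbed at validation so every
    message's ``sender_id`` resolves. ``skipped_rows`` records rows rejected
    during a tolerant read (see :func:`read_corpus`); they are counted and
    reported, never silently dropped.
    """

    messages: list[Message]
    users: list[UserRecord] = field(default_factory=list)
    year_range: Optional[tuple[int, int]] = None
    skipped_rows: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for m in self.messages:
            if m.message_id in seen:
                raise SchemaError(f"duplicate message_id: {m.message_id!r}")
            seen.add(m.message_id)
            if not m.thread_id:
                raise SchemaError(f"message {m.message_id!r}: empty thread_id")
        known = {u.user_id for u in self.users}
        for m in self.messages:
            if m.sender_id not in known:
                self.users.append(UserRecord(user_id=m.sender_id))
                known.add(m.sender_id)
        if self.year_range is None and self.messages:
            years = [m.year for m in self.messages]
            self.year_range = (min(years), max(years))
        if self.year_range is not None:
            lo, hi = self.year_range
            for m in self.messages:
                if not (lo <= m.year <= hi):
                    raise SchemaError(
                        f"message {m.message_id!r}: timestamp year {m.year} "
                        f"outside corpus range {lo}-{hi}"
                    )

    @property
    def users_by_id(self) -> dict[str, UserRecord]:
        return {u.user_id: u for u in self.users}

    def thread_roots(self) -> dict[str, Message]:
        """Earliest message of each thread (ties broken by message_id)."""
        roots: dict[str, Message] = {}
        for m in self.messages:
            cur = roots.get(m.thread_id)
            if cur is None or (m.timestamp, m.message_id) < (cur.timestamp, cur.message_id):
                roots[m.thread_id] = m
        return roots

    def __len__(self) -> int:
        return len(self.messages)


# ---------------------------------------------------------------------------
# I/O — CSV and JSONL with identical keys
# ---------------------------------------------------------------------------

def _parse_timestamp(raw: str, line: int) -> datetime:
    try:
        return datetime.fromisoformat(raw)
    except ValueError:
        raise RowError(line, f"unparseable timestamp {raw!r}") from None


def _row_to_message(row: dict, line: int) -> Message:
    for key in MESSAGE_FIELDS:
        if key not in row or row[key] is None:
            if key == "recipient_id":
                continue
            raise SchemaError(f"missing required field {key!r} (line {line})")
    recipient = row.get("recipient_id") or None
    return Message(
        message_id=str(row["message_id"]),
        thread_id=str(row["thread_id"]),
        sender_id=str(row["sender_id"]),
        recipient_id=str(recipient) if recipient else None,
        timestamp=_parse_timestamp(str(row["timestamp"]), line),
        body=str(row["body"]),
    )


def read_corpus(
    path: str | Path,
    format: Optional[str] = None,
    users: Optional[list[UserRecord]] = None,
    on_bad_rows: str = "raise",
) -> Corpus:
    """Read a forum corpus from CSV or JSONL.

    Parameters
    ----------
    path : file to read. Format is inferred from the suffix unless given.
    format : "csv" or "jsonl".
    users : optional pre-loaded user table (see :func:`read_users`).
    on_bad_rows : "raise" aborts on the first malformed row (with its line
        number); "collect" skips malformed rows and records them in
        ``Corpus.skipped_rows``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("jsonl" if path.suffix in {".jsonl", ".json"} else "csv")
    if fmt not in {"csv", "jsonl"}:
        raise ValueError(f"unknown format {fmt!r}")
    if on_bad_rows not in {"raise", "collect"}:
        raise ValueError("on_bad_rows must be 'raise' or 'collect'")

    messages: list[Message] = []
    skipped: list[tuple[int, str]] = []

    def handle(row: dict, line: int) -> None:
        try:
            messages.append(_row_to_message(row, line))
        except RowError as exc:
            if on_bad_rows == "raise":
                raise
            skipped.append((line, str(exc)))

    with path.open(newline="", encoding="utf-8") as fh:
        if fmt == "csv":
            reader = csv.DictReader(fh)
            missing = set(MESSAGE_FIELDS) - set(reader.fieldnames or [])
            if missing:
                raise SchemaError(f"missing required column(s): {sorted(missing)}")
            for line, row in enumerate(reader, start=2):
                handle(row, line)
        else:
            for line, raw in enumerate(fh, start=1):
                if not raw.strip():
                    continue
                handle(json.loads(raw), line)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} malformed row(s) in {path.name}", stacklevel=2)
    return Corpus(messages=messages, users=list(users or []), skipped_rows=skipped)


def write_corpus(corpus: Corpus, path: str | Path, format: Optional[str] = None) -> None:
    """Write messages back out in the CSV/JSONL interchange schema."""
    path = Path(path)
    fmt = format or ("jsonl" if path.suffix in {".jsonl", ".json"} else "csv")
    rows = (
        {
            "message_id": m.message_id,
            "thread_id": m.thread_id,
            "sender_id": m.sender_id,
            "recipient_id": m.recipient_id or "",
            "timestamp": m.timestamp.isoformat(),
            "body": m.body,
        }
        for m in corpus.messages
    )
    with path.open("w", newline="", encoding="utf-8") as fh:
        if fmt == "csv":
            writer = csv.DictWriter(fh, fieldnames=MESSAGE_FIELDS)
            writer.writeheader()
            writer.writerows(rows)
        else:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def read_users(path: str | Path) -> list[UserRecord]:
    """User table CSV: user_id,age,gender,quit_dates (semicolon-separated ISO dates)."""
    users: list[UserRecord] = []
    seen: set[str] = set()
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(USER_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"missing required column(s): {sorted(missing)}")
        for line, row in enumerate(reader, start=2):
            uid = str(row["user_id"])
            if uid in seen:
                raise SchemaError(f"duplicate user_id {uid!r} (line {line})")
            seen.add(uid)
            quit_dates = [
                date.fromisoformat(tok)
                for tok in str(row.get("quit_dates") or "").split(";")
                if tok.strip()
            ]
            age = row.get("age")
            users.append(
                UserRecord(
                    user_id=uid,
                    age=int(age) if age not in (None, "") else None,
                    gender=(row.get("gender") or None),
                    quit_dates=quit_dates,
                )
            )
    return users


def write_users(users: Iterable[UserRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=USER_FIELDS)
        writer.writeheader()
        for u in users:
            writer.writerow(
                {
                    "user_id": u.user_id,
                    "age": "" if u.age is None else u.age,
                    "gender": u.gender or "",
                    "quit_dates": ";".join(d.isoformat() for d in u.quit_dates),
                }
            )


# ---------------------------------------------------------------------------
# Quit-duration signatures and abstinence binning
# ---------------------------------------------------------------------------

# Community signature convention: "<N> days[, <H> hours[, <M> minutes
# [ and <S> seconds]]] smoke free", case-insensitive, possibly decorated
# with leading slashes. Only whole days count.
_SIGNATURE_RE = re.compile(
    r"(\d+)\s*days?"
    r"(?:\s*,?\s*(\d+)\s*hours?)?"
    r"(?:\s*,?\s*(\d+)\s*minutes?)?"
    r"(?:\s*,?\s*(?:and\s+)?(\d+)\s*seconds?)?"
    r"[\s,.]*smoke[\s-]*free",
    re.IGNORECASE,
)


def parse_quit_duration(body: str) -> Optional[int]:
    """Extract the first quit-duration signature from a message body.

    Returns the stated elapsed time in whole days, or None when no
    signature is present. Sub-day components never round a count up.
    """
    match = _SIGNATURE_RE.search(body)
    if match is None:
        return None
    return int(match.group(1))


_BIN_EDGES = (
    (3 * DAYS_PER_MONTH, AbstinenceStatus.LT_3M),
    (6 * DAYS_PER_MONTH, AbstinenceStatus.M3_TO_6M),
    (DAYS_PER_YEAR, AbstinenceStatus.M6_TO_1Y),
    (2 * DAYS_PER_YEAR, AbstinenceStatus.Y1_TO_2Y),
)


def bin_abstinence(
    days: Optional[float] = None, is_smoking_flag: Optional[bool] = None
) -> AbstinenceStatus:
    """Map a quit duration (days) and/or self-reported smoking flag to a category.

    Half-open bins [lower, upper) with 1 month := 30.44 days and
    1 year := 365.25 days. An explicit smoking flag wins; with neither
    input the status is UNKNOWN.
    """
    if is_smoking_flag:
        return AbstinenceStatus.ACTIVE_SMOKER
    if days is None:
        return AbstinenceStatus.UNKNOWN
    if days < 0:
        raise ValueError(f"negative quit duration: {days}")
    for upper, status in _BIN_EDGES:
        if days < upper:
            return status
    return AbstinenceStatus.GT_2Y


def status_per_user_year(
    corpus: Corpus,
    anchor_month_day: tuple[int, int] = (12, 31),
) -> dict[tuple[str, int], AbstinenceStatus]:
    """Estimate abstinence status for every (user, year) with any evidence.

    Event-log quit dates take precedence: days abstinent = year-end anchor
    minus the latest quit date on or before the anchor. Users without a
    usable log fall back to their messages' quit-duration signatures in
    that year: each signature is a time-stamped observation of elapsed
    smoke-free days, so it is extrapolated to the anchor
    (parsed days + days from message to anchor) and the maximum such
    estimate is binned — keeping the fallback on the same assessment
    anchor as the log rule. With neither source the status is UNKNOWN.
    """
    users = corpus.users_by_id
    lo, hi = corpus.year_range if corpus.year_range else (0, -1)

    active: dict[tuple[str, int], list[Message]] = {}
    for m in corpus.messages:
        active.setdefault((m.sender_id, m.year), []).append(m)

    out: dict[tuple[str, int], AbstinenceStatus] = {}
    keys = set(active)
    for u in users.values():
        if u.quit_dates:
            keys.update((u.user_id, y) for y in range(lo, hi + 1))
    for user_id, year in sorted(keys):
        anchor = date(year, *anchor_month_day)
        record = users.get(user_id)
        status = AbstinenceStatus.UNKNOWN
        if record is not None and record.quit_dates:
            eligible = [d for d in record.quit_dates if d <= anchor]
            if eligible:
                status = bin_abstinence((anchor - eligible[-1]).days)
        if status is AbstinenceStatus.UNKNOWN:
            durations = [
                d + max(0, (anchor - m.timestamp.date()).days)
                for m in active.get((user_id, year), [])
                if (d := parse_quit_duration(m.body)) is not None
            ]
            if durations:
                status = bin_abstinence(max(durations))
        out[(user_id, year)] = status
    return out
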