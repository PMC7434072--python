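"""Lexicon-based sentiment scoring and three-way direction classification.

A message's score is the difference between its positive- and
negative-lexicon token counts divided by its total token count, giving a
value in [-1, 1]; the direction is simply the sign (zero maps to neutral).
The lexicon is pluggable: any pair of plain word lists works, and a small
general-purpose list ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd

from .embeddings import tokenize
from .engagement import UserGroup, UserGroupAssignment, proportion
from .forum_model import Corpus

__all__ = [
    "SentimentDirection",
    "SentimentLexicon",
    "SentimentResult",
    "load_lexicon",
    "default_lexicon",
    "score_message",
    "score_corpus",
    "sentiment_by_group",
]


class SentimentDirection(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class SentimentLexicon:
    positive_terms: frozenset[str]
    negative_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive_terms or not self.negative_terms:
            raise ValueError("both lexicon sides must be non-empty")
        overlap = self.positive_terms & self.negative_terms
        if overlap:
            raise ValueError(f"lexicon sides overlap: {sorted(overlap)[:5]}")

    def swapped(self) -> "SentimentLexicon":
        return SentimentLexicon(self.negative_terms, self.positive_terms)


@dataclass(frozen=True)
class SentimentResult:
    message_id: Optional[str]
    score: float
    direction: SentimentDirection


def _read_wordlist(text: str) -> frozenset[str]:
    return frozenset(
        line.strip().lower() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_lexicon(positive_path: str | Path, negative_path: str | Path) -> SentimentLexicon:
    """Load a lexicon from two plain-text files, one token per line."""
    return SentimentLexicon(
        _read_wordlist(Path(positive_path).read_text(encoding="utf-8")),
        _read_wordlist(Path(negative_path).read_text(encoding="utf-8")),
    )


def default_lexicon() -> SentimentLexicon:
    """The small general-purpose word list bundled with the package."""
    pkg = resources.files("engagekit.data")
    return SentimentLexicon(
        _read_wordlist((pkg / "lexicon_positive.txt").read_text(encoding="utf-8")),
        _read_wordlist((pkg / "lexicon_negative.txt").read_text(encoding="utf-8")),
    )


def score_message(
    body: str,
    lexicon: SentimentLexicon,
    message_id: Optional[str] = None,
    tokenizer: Callable[[str], list[str]] = tokenize,
) -> SentimentResult:
    """Score one message: (positive hits - negative hits) / total tokens.

    Empty messages and messages without lexicon tokens score 0 (neutral).
    """
    tokens = tokenizer(body)
    if not tokens:
        return SentimentResult(message_id, 0.0, SentimentDirection.NEUTRAL)
    pos = sum(1 for t in tokens if t in lexicon.positive_terms)
    neg = sum(1 for t in tokens if t in lexicon.negative_terms)
    score = (pos - neg) / len(tokens)
    if score > 0:
        direction = SentimentDirection.POSITIVE
    elif score < 0:
        direction = SentimentDirection.NEGATIVE
    else:
        direction = SentimentDirection.NEUTRAL
    return SentimentResult(message_id, score, direction)


def score_corpus(
    corpus: Corpus,
    lexicon: Optional[SentimentLexicon] = None,
    tokenizer: Callable[[str], list[str]] = tokenize,
) -> dict[str, SentimentResult]:
    lexicon = lexicon or default_lexicon()
    return {
        m.message_id: score_message(m.body, lexicon, m.message_id, tokenizer)
        for m in corpus.messages
    }


def sentiment_by_group(
    results: Mapping[str, SentimentResult],
    assignments: Sequence[UserGroupAssignment],
    corpus: Corpus,
    decimals: int = 2,
) -> pd.DataFrame:
    """Positive/negative/neutral shares of each group's messages.

    Denominators are each group's selected-slot messages (same rule as the
    theme prevalence table); the three shares sum to 100 up to rounding.
    """
    slot_index: dict[UserGroup, set[tuple[str, int]]] = {g: set() for g in UserGroup}
    for a in assignments:
        slot_index[a.group].add((a.user_id, a.year))
    rows = []
    for group in UserGroup:
        msgs = [m for m in corpus.messages if (m.sender_id, m.year) in slot_index[group]]
        if not msgs:
            continue
        n = len(msgs)
        tally = {d: 0 for d in SentimentDirection}
        for m in msgs:
            res = results.get(m.message_id)
            if res is not None:
                tally[res.direction] += 1
        rows.append(
            {
                "group": group.value,
                "n_messages": n,
                "positive": proportion(tally[SentimentDirection.POSITIVE], n, decimals),
                "negative": proportion(tally[SentimentDirection.NEGATIVE], n, decimals),
                "neutral": proportion(tally[SentimentDirection.NEUTRAL], n, decimals),
            }
        )
    return pd.DataFrame(rows).set_index("group")
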