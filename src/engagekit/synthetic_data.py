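"""Synthetic forum and background corpora with full ground truth.

The generator emulates the structure of a long-running threaded
smoking-cessation community so that every pipeline stage can be tested
against known truth:

* three engagement archetypes (initiators, attractors, frequent posters)
  plus a background population, with distinct posting/thread/reply rates;
* theme-bearing vocabulary: each of the 16 taxonomy themes owns a small
  token set planted in the messages that truly carry the theme (8 themes
  are rich, 8 deliberately sparse, to exercise the insufficient-positives
  filter);
* community neologisms that never appear in the background corpus but
  co-occur with their theme's anchor tokens in forum messages;
* sentiment-bearing words injected at a configurable
  positive/negative/neutral mixture;
* per-user quit trajectories realized both as event-log quit dates
  (for a configurable fraction of users) and as in-message quit-duration
  signature strings.

Token planting is explicit rather than free language modeling: the point
is exact ground truth and sharp recovery tests, not linguistic realism.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .classification import DEFAULT_TAXONOMY
from .forum_model import (
    AbstinenceStatus,
    Corpus,
    Message,
    UserRecord,
    bin_abstinence,
)

__all__ = [
    "ArchetypeSpec",
    "GeneratorConfig",
    "SyntheticGroundTruth",
    "StudyFixture",
    "generate_background",
    "generate_forum",
    "default_study_fixture",
    "theme_tokens",
    "neologism_token",
    "fit_zipf_exponent",
]

#: The 8 themes the classic study retained (rich) — the rest are sparse.
RICH_THEMES = (
    "goals_and_planning",
    "feedback_and_monitoring",
    "social_support",
    "natural_consequences",
    "comparison_of_behavior",
    "comparison_of_outcomes",
    "rewards_and_threat",
    "self_belief",
)

# Sentiment-bearing words injected into messages; all are present in the
# bundled lexicon, and no theme/filler token ever collides with them.
POSITIVE_INJECT = ("great", "happy", "wonderful", "proud", "congratulations", "hope", "support", "glad")
NEGATIVE_INJECT = ("sad", "struggle", "awful", "worried", "miserable", "tough", "relapse", "fear")

_LETTERS = string.ascii_lowercase


def theme_tokens(theme: str, n_tokens: int = 12) -> list[str]:
    """The synthetic vocabulary owned by one theme."""
    i = DEFAULT_TAXONOMY.index(theme)
    return [f"th{i:02d}{_LETTERS[j]}x" for j in range(n_tokens)]


def neologism_token(theme: str) -> str:
    """The community coinage anchored to one rich theme (absent from background)."""
    return f"neo{DEFAULT_TAXONOMY.index(theme):02d}ism"


@dataclass(frozen=True)
class ArchetypeSpec:
    """Behavioral parameters of one user archetype.

    ``posts_per_year`` is a Poisson rate; ``init_prob`` is the chance a
    post opens a new thread; ``attract_weight`` multiplies the chance
    that other users' replies land on this user's threads;
    ``theme_probs`` gives per-message Bernoulli probabilities for the
    rich themes; ``quit_profile`` weights (veteran, recent, never-quit).
    """

    fraction: float
    posts_per_year: float
    init_prob: float
    attract_weight: float
    theme_probs: dict[str, float]
    quit_profile: tuple[float, float, float] = (0.45, 0.45, 0.10)
    female_prob: float = 0.83
    mean_age: float = 49.0
    sd_age: float = 9.4


def _default_archetypes() -> dict[str, ArchetypeSpec]:
    base = {t: 0.2 for t in RICH_THEMES}
    return {
        "initiator": ArchetypeSpec(
            fraction=0.10, posts_per_year=70.0, init_prob=0.60, attract_weight=1.0,
            theme_probs={**base, "rewards_and_threat": 0.63, "social_support": 0.48,
                         "goals_and_planning": 0.30, "comparison_of_behavior": 0.25,
                         "self_belief": 0.25},
            quit_profile=(0.80, 0.15, 0.05),
        ),
        "attractor": ArchetypeSpec(
            fraction=0.10, posts_per_year=50.0, init_prob=0.25, attract_weight=8.0,
            theme_probs={**base, "goals_and_planning": 0.72, "comparison_of_outcomes": 0.41,
                         "natural_consequences": 0.30, "social_support": 0.25},
            quit_profile=(0.10, 0.80, 0.10),
        ),
        "poster": ArchetypeSpec(
            fraction=0.10, posts_per_year=150.0, init_prob=0.05, attract_weight=1.0,
            theme_probs={**base, "feedback_and_monitoring": 0.74, "goals_and_planning": 0.49,
                         "rewards_and_threat": 0.30, "social_support": 0.25},
            quit_profile=(0.40, 0.45, 0.15),
        ),
        "background": ArchetypeSpec(
            fraction=0.70, posts_per_year=12.0, init_prob=0.15, attract_weight=1.0,
            theme_probs={t: 0.25 for t in RICH_THEMES},
            quit_profile=(0.40, 0.50, 0.10),
        ),
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic community."""

    seed: int = 0
    n_users: int = 50
    years: tuple[int, int] = (2013, 2014)
    archetypes: dict[str, ArchetypeSpec] = field(default_factory=_default_archetypes)
    # vocabulary
    tokens_per_theme: int = 12
    n_filler: int = 300
    zipf_exponent: float = 1.1
    filler_tokens_mean: float = 10.0
    theme_tokens_range: tuple[int, int] = (3, 6)
    sparse_theme_prob: float = 0.015
    neologism_prob: float = 0.15
    # sentiment
    sentiment_mix: tuple[float, float, float] = (0.70, 0.20, 0.10)
    sentiment_tokens: int = 2
    # quit trajectories
    log_coverage: float = 0.576  # share of users whose quit dates reach the event log
    signature_rate: float = 0.90  # per-message chance of the smoke-free signature
    # reply behaviour
    recipient_prob: float = 0.70
    # background corpus
    background_docs: int = 5000
    background_doc_len: float = 40.0
    background_theme_share: float = 0.60

    def __post_init__(self) -> None:
        total = sum(a.fraction for a in self.archetypes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions must sum to 1 (got {total})")
        if self.n_users < 1 or self.tokens_per_theme < 1 or self.n_filler < 1:
            raise ValueError("n_users, tokens_per_theme and n_filler must be positive")
        if abs(sum(self.sentiment_mix) - 1.0) > 1e-9:
            raise ValueError("sentiment_mix must sum to 1")

    # -- vocabulary views ---------------------------------------------------
    def tokens_of(self, theme: str) -> list[str]:
        return theme_tokens(theme, self.tokens_per_theme)

    def filler_vocab(self) -> list[str]:
        return [f"fill{j:03d}" for j in range(self.n_filler)]

    def neologisms(self) -> dict[str, str]:
        return {t: neologism_token(t) for t in RICH_THEMES}

    def paraphrase_pairs(self) -> list[tuple[str, str]]:
        """Within-theme token pairs planted to co-occur in the background."""
        pairs = []
        for theme in DEFAULT_TAXONOMY:
            toks = self.tokens_of(theme)
            pairs.extend((toks[i], toks[i + 1]) for i in range(0, len(toks) - 1, 2))
        return pairs

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False), encoding="utf-8")


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    message_themes: dict[str, set[str]]
    message_sentiment: dict[str, str]  # positive | negative | neutral
    user_archetype: dict[str, str]
    user_status: dict[tuple[str, int], AbstinenceStatus]
    user_has_log: dict[str, bool]

    def theme_prevalence(self) -> dict[str, float]:
        """True percent of messages carrying each theme."""
        n = len(self.message_themes)
        out: dict[str, float] = {}
        for theme in DEFAULT_TAXONOMY:
            hits = sum(1 for ts in self.message_themes.values() if theme in ts)
            out[theme] = 100.0 * hits / n if n else 0.0
        return out

    def sentiment_shares(self) -> dict[str, float]:
        n = len(self.message_sentiment)
        return {
            d: 100.0 * sum(1 for v in self.message_sentiment.values() if v == d) / n
            for d in ("positive", "negative", "neutral")
        }

    def write_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for mid in sorted(self.message_themes):
                fh.write(json.dumps({
                    "message_id": mid,
                    "themes": sorted(self.message_themes[mid]),
                    "sentiment": self.message_sentiment[mid],
                }) + "\n")
            for uid in sorted(self.user_archetype):
                fh.write(json.dumps({
                    "user_id": uid,
                    "archetype": self.user_archetype[uid],
                    "has_log": self.user_has_log[uid],
                    "status": {
                        str(y): s.name
                        for (u, y), s in sorted(self.user_status.items()) if u == uid
                    },
                }) + "\n")


# ---------------------------------------------------------------------------
# Background corpus
# ---------------------------------------------------------------------------

def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=np.float64)
    p = ranks ** (-exponent)
    return p / p.sum()


def generate_background(config: GeneratorConfig) -> list[str]:
    """One document per list item; theme tokens co-occur within documents.

    Each document draws a single theme; ~``background_theme_share`` of its
    tokens come from that theme's token set and the rest from the shared
    Zipf-distributed filler vocabulary. Neologisms never occur here.
    """
    rng = np.random.default_rng(config.seed + 1)
    filler = config.filler_vocab()
    fprobs = _zipf_probs(config.n_filler, config.zipf_exponent)
    theme_vocab = [config.tokens_of(t) for t in DEFAULT_TAXONOMY]
    docs: list[str] = []
    for _ in range(config.background_docs):
        theme = rng.integers(len(theme_vocab))
        length = max(4, rng.poisson(config.background_doc_len))
        from_theme = rng.random(length) < config.background_theme_share
        toks = [
            theme_vocab[theme][rng.integers(config.tokens_per_theme)]
            if is_theme
            else filler[rng.choice(config.n_filler, p=fprobs)]
            for is_theme in from_theme
        ]
        docs.append(" ".join(toks))
    return docs


def fit_zipf_exponent(counts: dict[str, int], min_count: int = 30) -> float:
    """Rank-frequency regression slope magnitude over well-sampled ranks."""
    freqs = np.array(sorted(counts.values(), reverse=True), dtype=np.float64)
    freqs = freqs[freqs >= min_count]
    if len(freqs) < 5:
        raise ValueError("too few well-sampled tokens for a Zipf fit")
    ranks = np.arange(1, len(freqs) + 1, dtype=np.float64)
    slope = np.polyfit(np.log(ranks), np.log(freqs), 1)[0]
    return float(-slope)


# ---------------------------------------------------------------------------
# Forum corpus
# ---------------------------------------------------------------------------

@dataclass
class _UserState:
    user_id: str
    archetype: str
    spec: ArchetypeSpec
    record: UserRecord
    quit_date: Optional[date]
    has_log: bool


def _make_users(config: GeneratorConfig, rng: np.random.Generator) -> list[_UserState]:
    lo, _hi = config.years
    corpus_start = date(lo, 1, 1)
    corpus_end = date(config.years[1], 12, 31)
    names = sorted(config.archetypes)
    fractions = np.array([config.archetypes[n].fraction for n in names])
    counts = np.floor(fractions * config.n_users).astype(int)
    while counts.sum() < config.n_users:  # distribute the remainder
        counts[int(np.argmax(fractions * config.n_users - counts))] += 1
    users: list[_UserState] = []
    i = 0
    for name, count in zip(names, counts):
        spec = config.archetypes[name]
        for _ in range(count):
            uid = f"u{i:04d}"
            i += 1
            kind = rng.choice(3, p=np.array(spec.quit_profile) / sum(spec.quit_profile))
            quit_date: Optional[date] = None
            if kind == 0:  # veteran: abstinent well over 2 years at corpus start
                quit_date = corpus_start - timedelta(days=int(rng.integers(800, 2500)))
            elif kind == 1:  # recent: quit within the corpus window (or just before)
                span = (corpus_end - timedelta(days=90)) - (corpus_start - timedelta(days=80))
                quit_date = corpus_start - timedelta(days=80) + timedelta(days=int(rng.integers(span.days)))
            has_log = bool(quit_date is not None and rng.random() < config.log_coverage)
            gender = "female" if rng.random() < spec.female_prob else "male"
            age = int(np.clip(rng.normal(spec.mean_age, spec.sd_age), 21, 80))
            record = UserRecord(
                user_id=uid, age=age, gender=gender,
                quit_dates=[quit_date] if has_log and quit_date else [],
            )
            users.append(_UserState(uid, name, spec, record, quit_date, has_log))
    return users


def _signature(days: int, rng: np.random.Generator) -> str:
    h, m, s = rng.integers(24), rng.integers(60), rng.integers(60)
    return f"////{days} days, {h} hours, {m} minutes and {s} seconds smoke free."


def _message_body(
    user: _UserState,
    ts: datetime,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[str, set[str], str]:
    spec = user.spec
    themes: set[str] = {
        t for t in RICH_THEMES if rng.random() < spec.theme_probs.get(t, 0.0)
    }
    if not themes:
        probs = np.array([spec.theme_probs.get(t, 0.0) for t in RICH_THEMES])
        themes.add(RICH_THEMES[rng.choice(len(RICH_THEMES), p=probs / probs.sum())])
    sparse = [t for t in DEFAULT_TAXONOMY if t not in RICH_THEMES]
    themes.update(t for t in sparse if rng.random() < config.sparse_theme_prob)

    lo, hi = config.theme_tokens_range
    tokens: list[str] = []
    for theme in sorted(themes):
        pool = config.tokens_of(theme)
        k = int(rng.integers(lo, hi + 1))
        tokens.extend(pool[j] for j in rng.choice(len(pool), size=k, replace=False))
        if theme in RICH_THEMES and rng.random() < config.neologism_prob:
            tokens.append(neologism_token(theme))

    filler = config.filler_vocab()
    fprobs = _zipf_probs(config.n_filler, config.zipf_exponent)
    n_fill = int(rng.poisson(config.filler_tokens_mean))
    tokens.extend(filler[j] for j in rng.choice(config.n_filler, size=n_fill, p=fprobs))

    direction = ("positive", "negative", "neutral")[
        int(rng.choice(3, p=np.asarray(config.sentiment_mix)))
    ]
    if direction == "positive":
        tokens.extend(rng.choice(POSITIVE_INJECT, size=config.sentiment_tokens))
    elif direction == "negative":
        tokens.extend(rng.choice(NEGATIVE_INJECT, size=config.sentiment_tokens))

    rng.shuffle(tokens)
    body = " ".join(tokens)
    if user.quit_date is not None and user.quit_date <= ts.date():
        if rng.random() < config.signature_rate:
            days = (ts.date() - user.quit_date).days
            body = _signature(days, rng) + " " + body
    return body, themes, direction


def generate_forum(config: GeneratorConfig) -> tuple[Corpus, SyntheticGroundTruth]:
    """Generate a threaded forum corpus plus its ground truth.

    Posts are laid out chronologically within each year. Each post either
    opens a thread (per the sender's initiation propensity) or replies to
    an earlier same-year thread chosen with probability proportional to the
    root author's attraction weight; replies address the root author with
    probability ``recipient_prob`` and the forum at large otherwise.
    """
    if config.tokens_per_theme > len(_LETTERS):
        raise ValueError("tokens_per_theme exceeds vocabulary template")
    rng = np.random.default_rng(config.seed + 2)
    users = _make_users(config, rng)
    lo, hi = config.years

    messages: list[Message] = []
    gt_themes: dict[str, set[str]] = {}
    gt_sent: dict[str, str] = {}
    mid_counter = 0
    tid_counter = 0

    for year in range(lo, hi + 1):
        year_start = datetime(year, 1, 1)
        seconds_in_year = int((datetime(year + 1, 1, 1) - year_start).total_seconds())
        events: list[tuple[int, _UserState]] = []
        for u in users:
            n_posts = rng.poisson(u.spec.posts_per_year)
            offsets = rng.integers(seconds_in_year, size=n_posts)
            events.extend((int(off), u) for off in offsets)
        events.sort(key=lambda e: e[0])

        threads: list[tuple[str, _UserState]] = []  # (thread_id, root author)
        weights: list[float] = []
        for off, u in events:
            ts = year_start + timedelta(seconds=off)
            mid = f"m{mid_counter:07d}"
            mid_counter += 1
            new_thread = (not threads) or (rng.random() < u.spec.init_prob)
            if new_thread:
                tid = f"t{tid_counter:06d}"
                tid_counter += 1
                threads.append((tid, u))
                weights.append(u.spec.attract_weight)
                recipient = None
            else:
                w = np.asarray(weights)
                pick = int(rng.choice(len(threads), p=w / w.sum()))
                tid, root_author = threads[pick]
                recipient = (
                    root_author.user_id if rng.random() < config.recipient_prob else None
                )
            body, themes, direction = _message_body(u, ts, config, rng)
            messages.append(
                Message(
                    message_id=mid, thread_id=tid, sender_id=u.user_id,
                    recipient_id=recipient, timestamp=ts, body=body,
                )
            )
            gt_themes[mid] = themes
            gt_sent[mid] = direction

    if not messages:
        raise ValueError("infeasible config: no messages generated")

    statuses: dict[tuple[str, int], AbstinenceStatus] = {}
    for u in users:
        for year in range(lo, hi + 1):
            anchor = date(year, 12, 31)
            if u.quit_date is not None and u.quit_date <= anchor:
                statuses[(u.user_id, year)] = bin_abstinence((anchor - u.quit_date).days)
            else:
                statuses[(u.user_id, year)] = AbstinenceStatus.UNKNOWN

    corpus = Corpus(
        messages=messages,
        users=[u.record for u in users],
        year_range=(lo, hi),
    )
    truth = SyntheticGroundTruth(
        message_themes=gt_themes,
        message_sentiment=gt_sent,
        user_archetype={u.user_id: u.archetype for u in users},
        user_status=statuses,
        user_has_log={u.user_id: u.has_log for u in users},
    )
    return corpus, truth


# ---------------------------------------------------------------------------
# End-to-end study fixture
# ---------------------------------------------------------------------------

@dataclass
class StudyFixture:
    """A small end-to-end bundle: corpus, truth, annotations, background."""

    config: GeneratorConfig
    background_docs: list[str]
    corpus: Corpus
    ground_truth: SyntheticGroundTruth
    annotations: dict[str, set[str]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .classification import write_annotations
        from .forum_model import write_corpus, write_users

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "corpus": outdir / "corpus.jsonl",
            "users": outdir / "users.csv",
            "background": outdir / "background.txt",
            "annotations": outdir / "annotations.csv",
            "ground_truth": outdir / "ground_truth.jsonl",
            "config": outdir / "generator.yaml",
        }
        write_corpus(self.corpus, paths["corpus"])
        write_users(self.corpus.users, paths["users"])
        paths["background"].write_text("\n".join(self.background_docs) + "\n", encoding="utf-8")
        write_annotations(self.annotations, paths["annotations"])
        self.ground_truth.write_jsonl(paths["ground_truth"])
        self.config.to_yaml(paths["config"])
        return paths


def default_study_fixture(
    seed: int = 0, n_annotations: int = 200, config: Optional[GeneratorConfig] = None
) -> StudyFixture:
    """The default study conditions: ~3,000-message corpus over 2 years,
    16 themes (8 rich, 8 sparse), a 200-message annotated subset coded from
    ground truth, and a ~200k-token background corpus."""
    config = config or GeneratorConfig(seed=seed)
    background = generate_background(config)
    corpus, truth = generate_forum(config)
    rng = np.random.default_rng(config.seed + 3)
    ids = sorted(truth.message_themes)
    chosen = rng.choice(len(ids), size=min(n_annotations, len(ids)), replace=False)
    annotations = {ids[i]: set(truth.message_themes[ids[i]]) for i in sorted(chosen)}
    return StudyFixture(
        config=config,
        background_docs=background,
        corpus=corpus,
        ground_truth=truth,
        annotations=annotations,
    )
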