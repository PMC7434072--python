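"""Distributional term and message vectors via skip-gram and superposition.

The representation pipeline has four stages:

1. ``train_background`` — skip-gram with negative sampling (SGNS) over a
   large general-purpose background corpus yields one vector per background
   vocabulary term. SGNS trains a shallow network to score observed
   (center, context) term pairs above randomly sampled negative pairs, so
   terms used in similar contexts end up with similar vectors.
2. ``stage1_message_vectors`` — each forum message is represented by the
   superposition (sum) of the background vectors of its in-vocabulary
   tokens, counting multiplicity, then unit-normalized.
3. ``corpus_term_vectors`` — each forum term (including community
   neologisms absent from the background vocabulary) is the superposition
   of the stage-1 vectors of the messages it occurs in (presence, not
   multiplicity), unit-normalized. This is the mechanism by which
   coinages like "nicodemon" inherit meaning from the background model
   through their forum co-occurrence contexts.
4. ``stage2_message_vectors`` — final message vectors superpose the
   corpus-adapted term vectors (multiplicity counted) and feed the theme
   classifiers.

Superposition is plain vector addition, so every stage is bag-of-words
symmetric and additive over disjoint token multisets (before
normalization). Normalization after each stage stops vector magnitude from
tracking raw message length or term frequency.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .forum_model import Corpus

__all__ = [
    "tokenize",
    "SgnsConfig",
    "VectorStore",
    "train_background",
    "stage1_message_vectors",
    "corpus_term_vectors",
    "stage2_message_vectors",
    "cosine",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str, stopwords: frozenset[str] = frozenset()) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop 1-char tokens and stopwords."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if len(t) >= 2 and t not in stopwords]


@dataclass(frozen=True)
class SgnsConfig:
    """Skip-gram-with-negative-sampling hyperparameters.

    ``dimension`` defaults to the classic 500 used with billion-word
    background corpora; tests and the bundled fixture use 50 for speed.
    The remaining defaults follow word2vec conventions.
    """

    dimension: int = 500
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    min_count: int = 5
    subsample: float = 1e-3
    learning_rate: float = 0.025
    seed: int = 0
    batch_size: int = 2048

    def __post_init__(self) -> None:
        for name in ("dimension", "window", "negatives", "epochs", "min_count", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.subsample <= 0 or self.learning_rate <= 0:
            raise ValueError("subsample and learning_rate must be positive")


class VectorStore:
    """A fixed-dimension mapping from token or message id to a real vector.

    ``provenance`` records which pipeline stage produced the store
    (BACKGROUND_TERMS, STAGE1_MESSAGES, CORPUS_TERMS or STAGE2_MESSAGES).
    ``flagged`` lists ids whose vector is identically zero (e.g. messages
    with no in-vocabulary token); such entries are exempt from the
    unit-norm invariant and receive no downstream labels.
    """

    PROVENANCES = ("BACKGROUND_TERMS", "STAGE1_MESSAGES", "CORPUS_TERMS", "STAGE2_MESSAGES")

    def __init__(
        self,
        ids: Sequence[str],
        matrix: np.ndarray,
        provenance: str,
        config: Optional[SgnsConfig] = None,
        flagged: Optional[set[str]] = None,
    ):
        if provenance not in self.PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[0] != len(ids):
            raise ValueError("matrix must be (len(ids), dimension)")
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in store")
        self.matrix = matrix
        self.provenance = provenance
        self.config = config
        self.flagged = set(flagged or ())
        self._index = {t: i for i, t in enumerate(self.ids)}

    # -- mapping interface -------------------------------------------------
    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def __getitem__(self, key: str) -> np.ndarray:
        return self.matrix[self._index[key]]

    def normalize(self) -> "VectorStore":
        """Scale every non-zero vector to unit Euclidean norm (idempotent)."""
        norms = np.linalg.norm(self.matrix, axis=1, keepdims=True)
        safe = np.where(norms > 0, norms, 1.0)
        self.matrix = self.matrix / safe
        return self

    def cosine(self, a: str, b: str) -> float:
        return cosine(self[a], self[b])

    def most_similar(self, key: str, n: int = 10) -> list[tuple[str, float]]:
        v = self[key]
        norms = np.linalg.norm(self.matrix, axis=1)
        sims = self.matrix @ v / (np.where(norms > 0, norms, 1.0) * max(np.linalg.norm(v), 1e-12))
        order = np.argsort(-sims)
        out = []
        for i in order:
            if self.ids[i] != key:
                out.append((self.ids[i], float(sims[i])))
            if len(out) == n:
                break
        return out

    # -- persistence: word2vec-style text + JSON sidecar -------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.ids)} {self.dimension}\n")
            for i, token in enumerate(self.ids):
                vec = " ".join(repr(float(x)) for x in self.matrix[i])
                fh.write(f"{token} {vec}\n")
        sidecar = {
            "provenance": self.provenance,
            "config": asdict(self.config) if self.config else None,
            "flagged": sorted(self.flagged),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "VectorStore":
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            ids, rows = [], np.empty((n, dim))
            for i in range(n):
                parts = fh.readline().rstrip("\n").split(" ")
                ids.append(parts[0])
                rows[i] = [float(x) for x in parts[1 : dim + 1]]
        sidecar_path = path.with_suffix(path.suffix + ".json")
        provenance, config, flagged = "BACKGROUND_TERMS", None, set()
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
            provenance = sidecar.get("provenance", provenance)
            if sidecar.get("config"):
                config = SgnsConfig(**sidecar["config"])
            flagged = set(sidecar.get("flagged", ()))
        return cls(ids, rows, provenance, config=config, flagged=flagged)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# SGNS training
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _as_token_docs(
    background_corpus: Iterable[str] | Iterable[list[str]],
    tokenizer: Callable[[str], list[str]],
) -> list[list[str]]:
    docs: list[list[str]] = []
    for doc in background_corpus:
        docs.append(tokenizer(doc) if isinstance(doc, str) else list(doc))
    return docs


def train_background(
    background_corpus: Iterable[str] | Iterable[list[str]],
    config: SgnsConfig,
    tokenizer: Callable[[str], list[str]] = tokenize,
) -> VectorStore:
    """Train SGNS term vectors on a background corpus (one document per item).

    Documents may be raw strings (tokenized with ``tokenizer``) or
    pre-tokenized lists. Training is single-threaded minibatch SGD with a
    linearly decaying learning rate, dynamic context windows, frequent-word
    subsampling and unigram^0.75 negative sampling, and is fully
    deterministic given ``config.seed``.
    """
    docs = _as_token_docs(background_corpus, tokenizer)
    counts: dict[str, int] = {}
    for doc in docs:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= config.min_count)
    if not vocab:
        raise ValueError("empty vocabulary after min_count filtering")
    index = {t: i for i, t in enumerate(vocab)}
    freq = np.array([counts[t] for t in vocab], dtype=np.float64)
    total = freq.sum()

    # keep-probability for frequent-word subsampling (word2vec style)
    ratio = config.subsample / (freq / total)
    keep = np.minimum(1.0, np.sqrt(ratio) + ratio)

    noise = freq ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(config.seed)
    dim = config.dimension
    w_in = (rng.random((len(vocab), dim)) - 0.5) / dim
    w_out = np.zeros((len(vocab), dim))

    encoded = [np.array([index[t] for t in doc if t in index], dtype=np.int64) for doc in docs]
    encoded = [e for e in encoded if len(e) >= 2]

    # precompute total pair estimate for the learning-rate schedule
    est_pairs = max(1, sum(len(e) for e in encoded) * config.window)
    total_steps = est_pairs * config.epochs
    step = 0
    lr_min = 1e-4

    for _epoch in range(config.epochs):
        centers_all: list[np.ndarray] = []
        contexts_all: list[np.ndarray] = []
        for enc in encoded:
            kept = enc[rng.random(len(enc)) < keep[enc]]
            n = len(kept)
            if n < 2:
                continue
            spans = rng.integers(1, config.window + 1, size=n)
            for i in range(n):
                lo, hi = max(0, i - spans[i]), min(n, i + spans[i] + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers_all.append(kept[i])
                        contexts_all.append(kept[j])
        if not centers_all:
            continue
        centers = np.array(centers_all, dtype=np.int64)
        contexts = np.array(contexts_all, dtype=np.int64)
        order = rng.permutation(len(centers))
        centers, contexts = centers[order], contexts[order]

        for start in range(0, len(centers), config.batch_size):
            c = centers[start : start + config.batch_size]
            o = contexts[start : start + config.batch_size]
            b = len(c)
            lr = max(lr_min, config.learning_rate * (1 - step / total_steps))
            step += b

            neg = rng.choice(len(vocab), size=(b, config.negatives), p=noise)
            h = w_in[c]  # (b, d)
            u_pos = w_out[o]  # (b, d)
            u_neg = w_out[neg]  # (b, k, d)

            s_pos = _sigmoid(np.einsum("bd,bd->b", h, u_pos))
            s_neg = _sigmoid(np.einsum("bd,bkd->bk", h, u_neg))

            g_pos = (s_pos - 1.0)[:, None]  # (b, 1)
            g_neg = s_neg[:, :, None]  # (b, k, 1)

            grad_h = g_pos * u_pos + np.einsum("bko,bkd->bd", g_neg, u_neg)
            grad_pos = g_pos * h
            grad_neg = g_neg * h[:, None, :]

            np.add.at(w_in, c, -lr * grad_h)
            np.add.at(w_out, o, -lr * grad_pos)
            np.add.at(w_out, neg.ravel(), -lr * grad_neg.reshape(-1, dim))

    return VectorStore(vocab, w_in, "BACKGROUND_TERMS", config=config).normalize()


# ---------------------------------------------------------------------------
# Superposition stages
# ---------------------------------------------------------------------------

def _count_matrix(
    token_docs: Sequence[list[str]], index: dict[str, int], binary: bool = False
) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    for r, doc in enumerate(token_docs):
        seen: dict[int, int] = {}
        for tok in doc:
            i = index.get(tok)
            if i is not None:
                seen[i] = seen.get(i, 0) + 1
        for i, c in seen.items():
            rows.append(r)
            cols.append(i)
            vals.append(1 if binary else c)
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(token_docs), len(index)), dtype=np.float64
    )


def _message_tokens(
    corpus: Corpus, tokenizer: Callable[[str], list[str]]
) -> tuple[list[str], list[list[str]]]:
    ids = [m.message_id for m in corpus.messages]
    return ids, [tokenizer(m.body) for m in corpus.messages]


def stage1_message_vectors(
    background: VectorStore,
    corpus: Corpus,
    tokenizer: Callable[[str], list[str]] = tokenize,
) -> VectorStore:
    """Message vectors as sums of background term vectors (multiplicity counted).

    Tokens outside the background vocabulary are skipped; messages with no
    in-vocabulary token get a zero vector and are flagged.
    """
    ids, docs = _message_tokens(corpus, tokenizer)
    counts = _count_matrix(docs, background._index, binary=False)
    mat = counts @ background.matrix
    flagged = {ids[i] for i in np.flatnonzero(np.linalg.norm(mat, axis=1) == 0)}
    return VectorStore(ids, mat, "STAGE1_MESSAGES", config=background.config, flagged=flagged).normalize()


def corpus_term_vectors(
    stage1: VectorStore,
    corpus: Corpus,
    min_count: int = 1,
    tokenizer: Callable[[str], list[str]] = tokenize,
) -> VectorStore:
    """Forum term vectors as sums of the stage-1 vectors of containing messages.

    Presence semantics: a message contributes once per term it contains,
    however often the term repeats. Covers every forum token whose total
    corpus frequency is at least ``min_count`` — including neologisms that
    the background model has never seen.
    """
    ids, docs = _message_tokens(corpus, tokenizer)
    if ids != stage1.ids:
        raise ValueError("stage1 store does not match corpus message ids")
    counts: dict[str, int] = {}
    for doc in docs:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    terms = sorted(t for t, c in counts.items() if c >= min_count)
    index = {t: i for i, t in enumerate(terms)}
    presence = _count_matrix(docs, index, binary=True)  # (messages, terms)
    mat = presence.T @ stage1.matrix
    flagged = {terms[i] for i in np.flatnonzero(np.linalg.norm(mat, axis=1) == 0)}
    return VectorStore(terms, mat, "CORPUS_TERMS", config=stage1.config, flagged=flagged).normalize()


def stage2_message_vectors(
    corpus_terms: VectorStore,
    corpus: Corpus,
    tokenizer: Callable[[str], list[str]] = tokenize,
) -> VectorStore:
    """Final message vectors as sums of corpus term vectors (multiplicity counted).

    These are the classifier features. Messages whose tokens are all below
    the term-stage frequency floor get a zero vector and are flagged.
    """
    ids, docs = _message_tokens(corpus, tokenizer)
    counts = _count_matrix(docs, corpus_terms._index, binary=False)
    mat = counts @ corpus_terms.matrix
    flagged = {ids[i] for i in np.flatnonzero(np.linalg.norm(mat, axis=1) == 0)}
    return VectorStore(ids, mat, "STAGE2_MESSAGES", config=corpus_terms.config, flagged=flagged).normalize()
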