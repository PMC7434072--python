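"""Per-theme binary classification of messages over embedding features.

Each behavior-change-technique theme (the 16-category taxonomy level) gets
its own binary probabilistic classifier over the stage-2 message vectors.
Themes with too few positive training examples are dropped up front;
retained themes are evaluated with stratified 10-fold cross-validation
whose precision/recall/F are pooled from the summed held-out confusion
matrix, then applied to the whole corpus for multi-label annotation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import KBinsDiscretizer

from .engagement import UserGroup, UserGroupAssignment, proportion
from .forum_model import Corpus
from .embeddings import VectorStore

__all__ = [
    "DEFAULT_TAXONOMY",
    "ThemeModelReport",
    "read_annotations",
    "write_annotations",
    "filter_themes",
    "train_theme_classifier",
    "cross_validate",
    "label_corpus",
    "theme_prevalence_by_group",
    "cohen_kappa",
]

#: The 16 thematic categories of the behavior change technique taxonomy.
DEFAULT_TAXONOMY = (
    "goals_and_planning",
    "feedback_and_monitoring",
    "social_support",
    "shaping_knowledge",
    "natural_consequences",
    "comparison_of_behavior",
    "associations",
    "repetition_and_substitution",
    "comparison_of_outcomes",
    "rewards_and_threat",
    "regulation",
    "antecedents",
    "identity",
    "scheduled_consequences",
    "self_belief",
    "covert_learning",
)


@dataclass
class ThemeModelReport:
    """Cross-validation report for one theme's binary classifier."""

    theme: str
    n_positive: int
    retained: bool
    precision: float = float("nan")
    recall: float = float("nan")
    f_measure: float = float("nan")
    folds_used: int = 0
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # tn, fp, fn, tp


# ---------------------------------------------------------------------------
# Annotation I/O: CSV message_id, pipe-separated theme names
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            themes = {t for t in str(row.get("themes", "")).split("|") if t}
            out[str(row["message_id"])] = themes
    return out


def write_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["message_id", "themes"])
        for mid in sorted(annotations):
            writer.writerow([mid, "|".join(sorted(annotations[mid]))])


def filter_themes(
    annotations: Mapping[str, set[str]],
    taxonomy: Sequence[str] = DEFAULT_TAXONOMY,
    min_positives: int = 30,
) -> tuple[list[str], pd.DataFrame]:
    """Drop themes with fewer than ``min_positives`` positive examples.

    Returns the retained theme list plus a report with each theme's
    positive count and retention flag (both retained and dropped listed).
    """
    if not annotations:
        raise ValueError("annotations must be non-empty")
    unknown = {t for themes in annotations.values() for t in themes} - set(taxonomy)
    if unknown:
        raise ValueError(f"annotation themes outside taxonomy: {sorted(unknown)}")
    counts = {theme: 0 for theme in taxonomy}
    for themes in annotations.values():
        for t in themes:
            counts[t] += 1
    retained = [t for t in taxonomy if counts[t] >= min_positives]
    if not retained:
        raise ValueError(f"no theme has >= {min_positives} positive examples")
    report = pd.DataFrame(
        {
            "theme": list(taxonomy),
            "n_positive": [counts[t] for t in taxonomy],
            "retained": [t in retained for t in taxonomy],
        }
    )
    return retained, report


# ---------------------------------------------------------------------------
# Training / cross-validation
# ---------------------------------------------------------------------------

def _design(
    features: VectorStore, annotations: Mapping[str, set[str]], theme: str
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Feature matrix and binary target for one theme, in canonical id order.

    Sorting by message_id makes every downstream fold assignment invariant
    to the order annotations arrived in. Flagged (zero-vector) messages are
    excluded from training.
    """
    ids = sorted(m for m in annotations if m in features and m not in features.flagged)
    if not ids:
        raise ValueError("no annotated messages with usable feature vectors")
    x = np.stack([features[m] for m in ids])
    y = np.array([theme in annotations[m] for m in ids], dtype=int)
    return ids, x, y


def _make_estimator(event_model: str, seed: int = 0):
    """'gaussian' NB over raw vector components, or 'multinomial'-style NB
    over discretized components (quantile bins) as a config alternative."""
    if event_model == "gaussian":
        return GaussianNB()
    if event_model == "discretized":
        from sklearn.pipeline import make_pipeline
        from sklearn.naive_bayes import CategoricalNB

        return make_pipeline(
            KBinsDiscretizer(n_bins=4, encode="ordinal", strategy="quantile",
                             quantile_method="averaged_inverted_cdf"),
            CategoricalNB(min_categories=4),
        )
    raise ValueError(f"unknown event_model {event_model!r}")


def train_theme_classifier(
    features: VectorStore,
    annotations: Mapping[str, set[str]],
    theme: str,
    event_model: str = "gaussian",
):
    """Fit one theme's binary classifier on all annotated messages.

    Decision threshold is 0.5 on the posterior (the estimator's
    ``predict``). Raises when the training labels are single-class.
    """
    _, x, y = _design(features, annotations, theme)
    if len(np.unique(y)) < 2:
        raise ValueError(f"theme {theme!r}: training set has a single class")
    clf = _make_estimator(event_model)
    clf.fit(x, y)
    return clf


def cross_validate(
    features: VectorStore,
    annotations: Mapping[str, set[str]],
    theme: str,
    folds: int = 10,
    seed: int = 0,
    event_model: str = "gaussian",
) -> ThemeModelReport:
    """Stratified k-fold cross-validation with pooled (micro) metrics.

    Held-out predictions from all folds are pooled into one confusion
    matrix from which precision, recall and F are computed, so the report
    is exactly reconstructable from ``report.confusion``. When the
    positive class has fewer members than ``folds``, the fold count is
    reduced automatically (never below 2), with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ids, x, y = _design(features, annotations, theme)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError(f"theme {theme!r}: training set has a single class")
    n_min = min(n_pos, len(y) - n_pos)
    used = folds
    if n_min < folds:
        used = max(2, n_min)
        warnings.warn(
            f"theme {theme!r}: only {n_min} minority examples; reducing folds "
            f"{folds} -> {used}",
            stacklevel=2,
        )
    splitter = StratifiedKFold(n_splits=used, shuffle=True, random_state=seed)
    y_hat = np.empty_like(y)
    for train_idx, test_idx in splitter.split(x, y):
        clf = _make_estimator(event_model)
        clf.fit(x[train_idx], y[train_idx])
        y_hat[test_idx] = clf.predict(x[test_idx])
    tp = int(np.sum((y == 1) & (y_hat == 1)))
    fp = int(np.sum((y == 0) & (y_hat == 1)))
    fn = int(np.sum((y == 1) & (y_hat == 0)))
    tn = int(np.sum((y == 0) & (y_hat == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ThemeModelReport(
        theme=theme,
        n_positive=n_pos,
        retained=True,
        precision=precision,
        recall=recall,
        f_measure=f,
        folds_used=used,
        confusion=(tn, fp, fn, tp),
    )


def label_corpus(
    classifiers: Mapping[str, object], features: VectorStore
) -> dict[str, set[str]]:
    """Independent binary decision per theme per message, corpus-wide.

    Flagged (zero-vector) messages receive no labels. Theme decisions are
    independent: each classifier sees only its own targets, so adding or
    removing one theme never changes another theme's labels.
    """
    labels: dict[str, set[str]] = {mid: set() for mid in features.ids}
    if not features.ids:
        return labels
    usable = [i for i, mid in enumerate(features.ids) if mid not in features.flagged]
    if not usable:
        return labels
    x = features.matrix[usable]
    for theme in sorted(classifiers):
        pred = np.asarray(classifiers[theme].predict(x)).astype(bool)
        for j, i in enumerate(usable):
            if pred[j]:
                labels[features.ids[i]].add(theme)
    return labels


def theme_prevalence_by_group(
    labels: Mapping[str, set[str]],
    assignments: Sequence[UserGroupAssignment],
    corpus: Corpus,
    themes: Optional[Sequence[str]] = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Percent of each group's messages carrying each theme.

    The denominator for a group is every message sent by one of its
    selected (user, year) slots during the selected year; the numerator is
    the subset labeled with the theme. Rows are unconstrained (multi-label)
    but every cell lies in [0, 100].
    """
    if themes is None:
        themes = sorted({t for ts in labels.values() for t in ts})
    slot_index: dict[UserGroup, set[tuple[str, int]]] = {g: set() for g in UserGroup}
    for a in assignments:
        slot_index[a.group].add((a.user_id, a.year))
    rows = []
    for group in UserGroup:
        msgs = [
            m for m in corpus.messages if (m.sender_id, m.year) in slot_index[group]
        ]
        if not msgs:
            warnings.warn(f"group {group.value}: no messages; skipped", stacklevel=2)
            continue
        n = len(msgs)
        row: dict[str, object] = {"group": group.value, "n_messages": n}
        for theme in themes:
            hits = sum(1 for m in msgs if theme in labels.get(m.message_id, ()))
            row[theme] = proportion(hits, n, decimals)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa: chance-corrected agreement between two label sequences.

    kappa = (p_o - p_e) / (1 - p_e), where p_o is observed agreement and
    p_e the agreement expected from the two raters' marginal frequencies.
    Returns 1.0 when both raters agree perfectly (even with one category).
    """
    a, b = list(labels_a), list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty label sequences")
    n = len(a)
    cats = sorted(set(a) | set(b), key=repr)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1 - p_e))
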