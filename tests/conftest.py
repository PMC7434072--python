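"""Shared fixtures: the default synthetic study bundle, computed once.

The session-scoped ``bundle`` runs the whole representation/classification
stack on the default study fixture (background SGNS training included), so
individual tests assert against one consistent end-to-end state instead of
retraining per test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from engagekit.classification import (
    cross_validate,
    filter_themes,
    label_corpus,
    train_theme_classifier,
)
from engagekit.embeddings import (
    SgnsConfig,
    VectorStore,
    corpus_term_vectors,
    stage1_message_vectors,
    stage2_message_vectors,
    train_background,
)
from engagekit.synthetic_data import (
    GeneratorConfig,
    StudyFixture,
    default_study_fixture,
    generate_forum,
)

FIXTURE_SEED = 0
SGNS_SEED = 1
CV_SEED = 7


@dataclass
class Bundle:
    fixture: StudyFixture
    background: VectorStore
    stage1: VectorStore
    terms: VectorStore
    stage2: VectorStore
    retained: list
    theme_report: object
    cv_reports: dict
    classifiers: dict
    labels: dict


@pytest.fixture(scope="session")
def bundle() -> Bundle:
    fixture = default_study_fixture(seed=FIXTURE_SEED)
    background = train_background(
        fixture.background_docs, SgnsConfig(dimension=50, seed=SGNS_SEED)
    )
    stage1 = stage1_message_vectors(background, fixture.corpus)
    terms = corpus_term_vectors(stage1, fixture.corpus)
    stage2 = stage2_message_vectors(terms, fixture.corpus)
    retained, theme_report = filter_themes(fixture.annotations)
    cv_reports = {
        theme: cross_validate(stage2, fixture.annotations, theme, folds=10, seed=CV_SEED)
        for theme in retained
    }
    classifiers = {
        theme: train_theme_classifier(stage2, fixture.annotations, theme)
        for theme in retained
    }
    labels = label_corpus(classifiers, stage2)
    return Bundle(
        fixture=fixture,
        background=background,
        stage1=stage1,
        terms=terms,
        stage2=stage2,
        retained=retained,
        theme_report=theme_report,
        cv_reports=cv_reports,
        classifiers=classifiers,
        labels=labels,
    )


@pytest.fixture(scope="session")
def sixteen_year_forum():
    """A lighter corpus spanning 16 calendar years for selection arithmetic."""
    config = GeneratorConfig(seed=FIXTURE_SEED, n_users=30, years=(2000, 2015))
    corpus, truth = generate_forum(config)
    return config, corpus, truth
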