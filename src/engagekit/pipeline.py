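"""End-to-end orchestration: ingest -> engagement -> embeddings -> labels -> reports.

``run_all`` executes the whole content-plus-frequency analysis from a
:class:`PipelineConfig` and writes tidy CSV report tables plus a JSON run
manifest (config hash, seeds, stage wall times and counts) sufficient to
reproduce the run bit-for-bit. Stage outputs are cached by config-section
hash so that changing only reporting parameters never retrains embeddings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import classification, embeddings, engagement, sentiment
from .embeddings import SgnsConfig, VectorStore
from .forum_model import Corpus, read_corpus, read_users, status_per_user_year

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

logger = logging.getLogger("engagekit.pipeline")

#: The report artifacts every successful run emits.
ARTIFACTS = (
    "group_demographics.csv",
    "theme_prevalence.csv",
    "sentiment_shares.csv",
    "theme_model_reports.csv",
    "engagement_profiles.csv",
    "message_labels.csv",
    "manifest.json",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    corpus_path: str
    background_path: str
    annotations_path: str
    output_dir: str
    users_path: Optional[str] = None
    lexicon_positive_path: Optional[str] = None
    lexicon_negative_path: Optional[str] = None
    # engagement
    top_k: int = 3
    years: Optional[tuple[int, int]] = None  # default: corpus year range
    # embeddings
    sgns: SgnsConfig = field(default_factory=lambda: SgnsConfig(dimension=50))
    term_min_count: int = 1
    # classification
    min_positives: int = 30
    folds: int = 10
    seed: int = 7
    decimals: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "sgns" in raw and isinstance(raw["sgns"], dict):
            raw["sgns"] = SgnsConfig(**raw["sgns"])
        if raw.get("years") is not None:
            raw["years"] = tuple(raw["years"])
        return cls(**raw)

    def section_hash(self, *fields: str) -> str:
        payload = {f: _jsonable(getattr(self, f)) for f in fields}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _jsonable(value):
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return dataclasses.asdict(value)
    if isinstance(value, tuple):
        return list(value)
    return value


def _check_paths(config: PipelineConfig) -> None:
    required = {
        "corpus_path": config.corpus_path,
        "background_path": config.background_path,
        "annotations_path": config.annotations_path,
    }
    for name in ("users_path", "lexicon_positive_path", "lexicon_negative_path"):
        if getattr(config, name) is not None:
            required[name] = getattr(config, name)
    for name, p in required.items():
        if not Path(p).exists():
            raise PipelineError("configure", f"{name} does not exist: {p}")


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name] = {"seconds": round(dt, 3)}
            if exc_type is not None:
                manifest["stages"][name]["failed"] = True
                logger.error("stage %s: FAILED after %.1fs", name, dt)
                if not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
            else:
                logger.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Timer()


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk).

    Fails fast — all configured input paths are checked before any stage
    runs, and any stage failure aborts with a stage-named error. Embedding
    stores are cached in ``<output_dir>/cache`` keyed by the hash of the
    inputs and embedding parameters.
    """
    _check_paths(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = outdir / "cache"
    cache.mkdir(exist_ok=True)

    manifest: dict = {
        "config": {f.name: _jsonable(getattr(config, f.name)) for f in dataclasses.fields(config)},
        "config_hash": config.section_hash(*[f.name for f in dataclasses.fields(config)]),
        "stages": {},
        "counts": {},
    }

    with _stage(manifest, "ingest"):
        users = read_users(config.users_path) if config.users_path else None
        corpus = read_corpus(config.corpus_path, users=users)
        annotations = classification.read_annotations(config.annotations_path)
        missing = set(annotations) - {m.message_id for m in corpus.messages}
        if missing:
            raise ValueError(f"{len(missing)} annotated message_id(s) not in corpus")
        manifest["counts"]["messages"] = len(corpus)
        manifest["counts"]["users"] = len(corpus.users)
        manifest["counts"]["annotated"] = len(annotations)

    with _stage(manifest, "engagement"):
        profiles = engagement.compute_profiles(corpus)
        years = config.years or corpus.year_range
        assignments = engagement.select_top_groups(profiles, config.top_k, years)
        statuses = status_per_user_year(corpus)
        demographics = engagement.group_summary(
            assignments, corpus.users, statuses, decimals=config.decimals
        )
        engagement.profiles_frame(profiles).to_csv(outdir / "engagement_profiles.csv", index=False)
        demographics.to_csv(outdir / "group_demographics.csv")
        manifest["counts"]["assignment_slots"] = len(assignments)

    with _stage(manifest, "embeddings"):
        emb_hash = config.section_hash("background_path", "corpus_path", "sgns", "term_min_count")
        cached = cache / f"stage2-{emb_hash}.vec"
        if cached.exists():
            logger.info("embeddings: cache hit (%s)", cached.name)
            stage2 = VectorStore.load(cached)
        else:
            docs = Path(config.background_path).read_text(encoding="utf-8").splitlines()
            background = embeddings.train_background([d for d in docs if d.strip()], config.sgns)
            stage1 = embeddings.stage1_message_vectors(background, corpus)
            terms = embeddings.corpus_term_vectors(stage1, corpus, min_count=config.term_min_count)
            stage2 = embeddings.stage2_message_vectors(terms, corpus)
            stage2.save(cached)
        manifest["counts"]["stage2_vectors"] = len(stage2)
        manifest["counts"]["zero_vector_messages"] = len(stage2.flagged)
        manifest["embedding_cache"] = cached.name

    with _stage(manifest, "classification"):
        retained, theme_report = classification.filter_themes(
            annotations, min_positives=config.min_positives
        )
        reports = []
        classifiers = {}
        for theme in retained:
            rep = classification.cross_validate(
                stage2, annotations, theme, folds=config.folds, seed=config.seed
            )
            reports.append(rep)
            classifiers[theme] = classification.train_theme_classifier(stage2, annotations, theme)
        labels = classification.label_corpus(classifiers, stage2)
        prevalence = classification.theme_prevalence_by_group(
            labels, assignments, corpus, themes=retained, decimals=config.decimals
        )
        cv = {r.theme: r for r in reports}
        theme_report["precision"] = [
            cv[t].precision if t in cv else float("nan") for t in theme_report["theme"]
        ]
        theme_report["recall"] = [
            cv[t].recall if t in cv else float("nan") for t in theme_report["theme"]
        ]
        theme_report["f_measure"] = [
            cv[t].f_measure if t in cv else float("nan") for t in theme_report["theme"]
        ]
        theme_report.to_csv(outdir / "theme_model_reports.csv", index=False)
        prevalence.to_csv(outdir / "theme_prevalence.csv")
        classification.write_annotations(labels, outdir / "message_labels.csv")
        manifest["counts"]["themes_retained"] = len(retained)

    with _stage(manifest, "sentiment"):
        if config.lexicon_positive_path and config.lexicon_negative_path:
            lexicon = sentiment.load_lexicon(
                config.lexicon_positive_path, config.lexicon_negative_path
            )
        else:
            lexicon = sentiment.default_lexicon()
        results = sentiment.score_corpus(corpus, lexicon)
        shares = sentiment.sentiment_by_group(
            results, assignments, corpus, decimals=config.decimals
        )
        shares.to_csv(outdir / "sentiment_shares.csv")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest
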