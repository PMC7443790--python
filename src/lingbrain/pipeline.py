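"""End-to-end study orchestration.

A study is described by a single YAML config naming the input paths and the
analyses to run; :func:`run_study` executes transcripts → linguistic features,
time series → connectivity, morphometry ingestion, ComBat site harmonization
of the imaging blocks, and one sparse CCA per configured analysis (by default
the three the pipeline is built around: language–clinical within the CHR
subgroup, and language+diagnosis against connectivity and against morphometry
in the whole sample). Every subject exclusion at a join or filter is logged
with a reason, and a run manifest (config hash, seeds, subject counts) makes
two identical runs byte-comparable.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brainfeat import (NetworkAtlas, TimeSeriesPanel, assemble_connectivity_matrix,
                        connectivity_vector, read_morphometry_table)
from .errors import AlignmentError, ConfigError
from .harmonize import harmonize
from .lingfeat import assemble_linguistic_matrix, extract_linguistic_features
from .matrix import FeatureMatrix
from .scca import SccaResult, run_scca_analysis
from .semantic import DEFAULT_K, DEFAULT_WEIGHTING, build_semantic_space
from .text import segment_sentences

log = logging.getLogger("lingbrain")


@dataclass
class AnalysisConfig:
    name: str
    block_y: str                          # "clinical" | "connectivity" | "morphometry"
    subset: dict = field(default_factory=dict)        # e.g. {"diagnosis": "CHR"}
    indicators: list[str] = field(default_factory=list)
    n_perm: int = 10000
    k_max: int = 2
    seed: int = 0
    grid_size: int = 10


@dataclass
class StudyConfig:
    transcripts: str
    metadata: str
    timeseries: str | None = None
    morphometry: str | None = None
    atlas: str | None = None
    out_dir: str = "results"
    semantic_k: int = DEFAULT_K
    semantic_weighting: str = DEFAULT_WEIGHTING
    degenerate_threshold: float = 0.5
    harmonize_enabled: bool = True
    site_column: str = "site"
    covariate_columns: list[str] = field(default_factory=list)
    clinical_prefix: str = "clin_"
    analyses: list[AnalysisConfig] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        analyses = [AnalysisConfig(**a) for a in raw.pop("analyses", [])]
        try:
            cfg = cls(analyses=analyses, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        names = [a.name for a in cfg.analyses]
        if len(names) != len(set(names)):
            raise ConfigError("analysis names must be unique")
        return cfg

    def content_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, default=lambda o: o.__dict__, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_analyses(n_perm: int = 10000, seed: int = 0) -> list[AnalysisConfig]:
    """The three standard analyses: clinical within CHR, imaging in everyone."""
    return [
        AnalysisConfig(name="language_clinical", block_y="clinical",
                       subset={"diagnosis": "CHR"}, n_perm=n_perm, seed=seed),
        AnalysisConfig(name="language_connectivity", block_y="connectivity",
                       indicators=["diagnosis", "handedness"], n_perm=n_perm, seed=seed),
        AnalysisConfig(name="language_morphometry", block_y="morphometry",
                       indicators=["diagnosis", "handedness"], n_perm=n_perm, seed=seed),
    ]


# --------------------------------------------------------------------------- #
# stage runners
# --------------------------------------------------------------------------- #

def load_transcripts(source) -> dict[str, str]:
    """subject_id → raw text, from a directory of .txt or a two-column TSV."""
    src = Path(source)
    texts: dict[str, str] = {}
    if src.is_dir():
        for f in sorted(src.glob("*.txt")):
            texts[f.stem] = f.read_text(encoding="utf-8")
    else:
        table = pd.read_csv(src, sep="\t", dtype=str)
        if table.shape[1] < 2:
            raise ConfigError("transcript TSV needs subject_id and path columns")
        for _, row in table.iterrows():
            texts[str(row.iloc[0])] = Path(row.iloc[1]).read_text(encoding="utf-8")
    if not texts:
        raise ConfigError(f"no transcripts found at {source}")
    return texts


def language_features(texts: dict[str, str], k: int = DEFAULT_K,
                      weighting: str = DEFAULT_WEIGHTING) -> FeatureMatrix:
    """Transcripts → raw language feature matrix (semantic space from the corpus)."""
    transcripts = [segment_sentences(t, subject_id=sid) for sid, t in texts.items()]
    space = build_semantic_space(transcripts, k=k, weighting_scheme=weighting)
    log.info("semantic space: %d tokens, k=%d, corpus hash %s",
             len(space.vocabulary), space.k, space.corpus_hash[:12])
    vectors = [extract_linguistic_features(t, space) for t in transcripts]
    return assemble_linguistic_matrix(vectors)


def connectivity_features(ts_dir, atlas: NetworkAtlas) -> FeatureMatrix:
    """Per-subject time-series TSVs → connectivity measure matrix."""
    vectors = {}
    for f in sorted(Path(ts_dir).glob("*.tsv")):
        panel = TimeSeriesPanel.from_tsv(f)
        vectors[panel.subject_id] = connectivity_vector(panel, atlas)
    if not vectors:
        raise ConfigError(f"no time-series files found at {ts_dir}")
    return assemble_connectivity_matrix(vectors, atlas)


def _align(blocks: dict[str, FeatureMatrix], meta: pd.DataFrame,
           exclusions: list[dict]) -> tuple[dict[str, FeatureMatrix], pd.DataFrame]:
    """Inner-join all sources on subject id, logging every exclusion."""
    sources = {"metadata": set(meta.index)}
    sources.update({name: set(m.subjects) for name, m in blocks.items()})
    shared = set.intersection(*sources.values())
    order = [s for s in meta.index if s in shared]
    everyone = set.union(*sources.values())
    for s in sorted(everyone - shared):
        missing_from = sorted(name for name, ids in sources.items() if s not in ids)
        exclusions.append({"subject_id": s,
                           "reason": f"absent from join (missing in: "
                                     f"{', '.join(missing_from)})"})
    if len(order) < 4:
        raise AlignmentError(f"only {len(order)} subjects shared across sources")
    return {k: m.subset(order) for k, m in blocks.items()}, meta.loc[order]


def _indicator_frame(meta: pd.DataFrame, columns: list[str]) -> pd.DataFrame | None:
    if not columns:
        return None
    out = {}
    for col in columns:
        if col not in meta.columns:
            raise ConfigError(f"indicator column {col!r} missing from metadata")
        series = meta[col]
        if series.dtype == object:
            levels = sorted(series.unique())
            if len(levels) != 2:
                raise ConfigError(f"indicator {col!r} must be binary, got {levels}")
            # first level alphabetically codes 1 (CHR=1 / HI=0 under default labels)
            out[col] = (series == levels[0]).astype(float)
        else:
            out[col] = series.astype(float)
    return pd.DataFrame(out, index=meta.index)


def run_study(config: StudyConfig) -> dict:
    """Execute every stage and analysis; write results under config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exclusions: list[dict] = []

    meta = pd.read_csv(config.metadata, sep="\t", index_col="subject_id")
    meta.index = meta.index.astype(str)

    blocks: dict[str, FeatureMatrix] = {}
    blocks["language"] = language_features(load_transcripts(config.transcripts),
                                           k=config.semantic_k,
                                           weighting=config.semantic_weighting)
    needed = {a.block_y for a in config.analyses} or {"clinical", "connectivity",
                                                      "morphometry"}
    if "connectivity" in needed:
        if not (config.timeseries and config.atlas):
            raise ConfigError("connectivity analysis needs timeseries and atlas paths")
        blocks["connectivity"] = connectivity_features(
            config.timeseries, NetworkAtlas.from_json(config.atlas))
    if "morphometry" in needed:
        if not config.morphometry:
            raise ConfigError("morphometry analysis needs a morphometry path")
        blocks["morphometry"] = read_morphometry_table(config.morphometry)

    blocks, meta = _align(blocks, meta, exclusions)
    clin_cols = [c for c in meta.columns if c.startswith(config.clinical_prefix)]
    if "clinical" in needed:
        if not clin_cols:
            raise ConfigError(f"no metadata columns with prefix {config.clinical_prefix!r}")
        blocks["clinical"] = FeatureMatrix(meta[clin_cols].astype(float),
                                           provenance="clinical")

    if config.harmonize_enabled:
        if config.site_column not in meta.columns:
            raise ConfigError(f"harmonization enabled but metadata lacks "
                              f"{config.site_column!r} column")
        covars = (meta[config.covariate_columns].astype(float)
                  if config.covariate_columns else None)
        for name in ("connectivity", "morphometry"):
            if name in blocks:
                blocks[name], model = harmonize(blocks[name], meta[config.site_column],
                                                covars)
                with open(out / f"combat_{name}.json", "w", encoding="utf-8") as fh:
                    json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
                log.info("harmonized %s over batches %s", name, model.batch_levels)

    analyses = config.analyses or default_analyses(seed=config.seed)
    results: dict[str, SccaResult] = {}
    for a in analyses:
        sub_meta = meta
        for col, val in a.subset.items():
            before = set(sub_meta.index)
            sub_meta = sub_meta[sub_meta[col] == val]
            for s in sorted(before - set(sub_meta.index)):
                exclusions.append({"subject_id": s,
                                   "reason": f"{a.name}: filtered {col} != {val!r}"})
        ids = list(sub_meta.index)
        log.info("analysis %s: %d subjects", a.name, len(ids))
        bx = blocks["language"].subset(ids)
        by = blocks[a.block_y].subset(ids)
        indicators = _indicator_frame(sub_meta, a.indicators)
        res = run_scca_analysis(bx, by, analysis=a.name, indicators=indicators,
                                degenerate_threshold=config.degenerate_threshold,
                                n_perm=a.n_perm, k_max=a.k_max, seed=a.seed,
                                allow_few=a.n_perm < 100)
        res.to_json(out / f"{a.name}.json")
        for side in ("x", "y"):
            res.sorted_weights(side).to_csv(out / f"{a.name}_weights_{side}.tsv",
                                            sep="\t", index=False)
        results[a.name] = res

    manifest = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_subjects": {name: len(blocks[name].subjects) for name in blocks},
        "analyses": {a.name: {"n_perm": a.n_perm, "seed": a.seed,
                              "subset": a.subset} for a in analyses},
        "exclusions": exclusions,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"results": results, "manifest": manifest, "blocks": blocks}


def report_weights(result: SccaResult, top_k: int | None = None,
                   side: str = "x", mode: int = 0) -> pd.DataFrame:
    """Features sorted by |weight| descending (ties by name), truncated to top_k."""
    table = result.sorted_weights(side=side, mode=mode)
    if top_k is not None:
        table = table.head(top_k)
    return table
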