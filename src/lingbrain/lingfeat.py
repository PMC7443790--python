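"""Per-subject linguistic feature vectors and the cohort-level feature matrix.

Three feature families are extracted from each transcript:

* amount of speech — min / max / mean / sd of words per sentence;
* semantics — min / max / mean / sd of the LSA coherence between consecutive
  sentences;
* syntax — relative frequency of each Penn Treebank word-level tag.

Standard deviations use the sample (n − 1) convention and are 0 for length-1
series. Tag frequencies are computed over all tokens (the ``other`` pool
included, so they sum to 1), but ``other`` is excluded from the analysis
feature set. Cohort-wide, features where more than a configurable share of
subjects have the identical value are dropped as degenerate before modelling.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (AllFeaturesDropped, EmptyTranscript, InconsistentFeatureSets,
                     InsufficientSubjects)
from .matrix import FeatureMatrix
from .postag import OTHER_TAG, PTB_WORD_TAGS, RuleBasedTagger, get_tagger
from .semantic import SemanticSpace, coherence_series
from .text import Transcript

#: Documented column order of the assembled language block.
STAT_FEATURES = ("sentlen_min", "sentlen_max", "sentlen_mean", "sentlen_sd",
                 "coh_min", "coh_max", "coh_mean", "coh_sd")


def _four_stats(values) -> tuple[float, float, float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.min()), float(arr.max()), float(arr.mean()), sd


def sentence_length_stats(t: Transcript) -> tuple[float, float, float, float]:
    """(min, max, mean, sample sd) of words per sentence."""
    if t.n_sentences < 1:
        raise EmptyTranscript(f"subject {t.subject_id!r}: no sentences")
    return _four_stats([len(s) for s in t.sentences])


def coherence_stats(series: list[float]) -> tuple[float, float, float, float]:
    """(min, max, mean, sample sd) of an inter-sentence coherence series."""
    if len(series) < 1:
        raise EmptyTranscript("empty coherence series")
    return _four_stats(series)


def pos_tag_frequencies(t: Transcript, tagset: str = "ptb",
                        tagger: RuleBasedTagger | None = None) -> dict[str, float]:
    """Relative frequency of each configured tag, plus the ``other`` pool.

    Every configured tag is present in the output (0 when absent); frequencies
    sum to 1 over tags + ``other``.
    """
    if t.n_tokens < 1:
        raise EmptyTranscript(f"subject {t.subject_id!r}: no tokens")
    tagger = tagger or get_tagger(tagset)
    counts = Counter(tag for _, tag in tagger.tag_transcript(t))
    total = sum(counts.values())
    freqs = {tag: counts.get(tag, 0) / total for tag in tagger.tagset}
    freqs[OTHER_TAG] = counts.get(OTHER_TAG, 0) / total
    return freqs


@dataclass
class LinguisticFeatureVector:
    subject_id: str
    sentlen_min: float
    sentlen_max: float
    sentlen_mean: float
    sentlen_sd: float
    coh_min: float
    coh_max: float
    coh_mean: float
    coh_sd: float
    pos_freq: dict[str, float] = field(default_factory=dict)

    def as_series(self, include_other: bool = False) -> pd.Series:
        data = {name: getattr(self, name) for name in STAT_FEATURES}
        tags = list(PTB_WORD_TAGS) + ([OTHER_TAG] if include_other else [])
        for tag in tags:
            data[f"pos_{tag}"] = self.pos_freq.get(tag, 0.0)
        return pd.Series(data, name=self.subject_id)


def extract_linguistic_features(t: Transcript, space: SemanticSpace,
                                tagger: RuleBasedTagger | None = None) -> LinguisticFeatureVector:
    """Full per-subject feature vector (amount of speech, coherence, POS)."""
    sl = sentence_length_stats(t)
    series, _ = coherence_series(t, space)
    co = coherence_stats(series)
    freqs = pos_tag_frequencies(t, tagger=tagger)
    return LinguisticFeatureVector(
        subject_id=t.subject_id,
        sentlen_min=sl[0], sentlen_max=sl[1], sentlen_mean=sl[2], sentlen_sd=sl[3],
        coh_min=co[0], coh_max=co[1], coh_mean=co[2], coh_sd=co[3],
        pos_freq=freqs,
    )


def assemble_linguistic_matrix(vectors: list[LinguisticFeatureVector]) -> FeatureMatrix:
    """Stack per-subject vectors into a raw subjects × features matrix.

    Column order is fixed: the 8 summary statistics then ``pos_<TAG>`` in
    Penn Treebank order; the ``other`` pool is not part of the analysis set.
    """
    if len(vectors) < 2:
        raise InsufficientSubjects("need at least 2 subjects")
    rows = [v.as_series() for v in vectors]
    names = [tuple(r.index) for r in rows]
    if len(set(names)) != 1:
        raise InconsistentFeatureSets("subjects carry different feature sets")
    df = pd.DataFrame(rows)
    df.index = [v.subject_id for v in vectors]
    return FeatureMatrix(df, provenance="language", state="raw")


def drop_degenerate_features(m: FeatureMatrix, threshold: float = 0.5
                             ) -> tuple[FeatureMatrix, list[str]]:
    """Drop features where one value's share strictly exceeds ``threshold``.

    A feature is degenerate when more than ``threshold`` of the sample achieved
    the same score (the modal value). A modal share exactly equal to the
    threshold is retained. Idempotent; preserves column order.
    """
    if m.state != "raw":
        raise ValueError("degenerate filter runs on raw matrices")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    n = len(m.data)
    dropped: list[str] = []
    keep: list[str] = []
    for col in m.data.columns:
        mode_share = m.data[col].value_counts().iloc[0] / n
        (dropped if mode_share > threshold else keep).append(col)
    if not keep:
        raise AllFeaturesDropped("every feature is degenerate at this threshold")
    return m.with_data(m.data[keep]), dropped
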