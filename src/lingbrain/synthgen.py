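"""Synthetic study generator with known ground truth.

Every pipeline stage is testable without clinical data: this module generates
(1) interview-like transcripts from part-of-speech-templated grammars over a
topic-partitioned synthetic vocabulary, (2) paired feature blocks sharing a
planted sparse canonical mode at a chosen latent correlation, (3) node × time
resting-state panels from per-network one-factor models calibrated to target
within- and between-network correlations, (4) morphometry tables with
plausible per-feature scales, and (5) subject metadata (diagnosis, site,
handedness, clinical item scores). All generators are pure functions of their
parameters and a seed.

Content words carry unambiguous morphology (stems, ``-ed``, ``-ing``, ``-ly``,
``-ful`` forms) so the rule tagger resolves them deterministically; function
words are real English closed-class items. Consecutive sentences share a topic
with probability 1 − drift, which is what moves inter-sentence LSA coherence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brainfeat import (NetworkAtlas, TimeSeriesPanel, default_morphometry_schema)
from .errors import (DimensionError, InvalidCorrelationSpec, InvalidSettings,
                     SchemaViolation)
from .matrix import FeatureMatrix
from .text import Transcript

# --------------------------------------------------------------------------- #
# ground truth containers
# --------------------------------------------------------------------------- #


@dataclass
class SyntheticTruth:
    """Everything planted by the generators, the target of recovery tests."""
    w_x: np.ndarray | None = None
    w_y: np.ndarray | None = None
    support_x: list[int] = field(default_factory=list)
    support_y: list[int] = field(default_factory=list)
    rho: float = 0.0
    signal_amplitude: float = 1.0
    batch_gamma: dict = field(default_factory=dict)     # batch -> location shift
    batch_delta: dict = field(default_factory=dict)     # batch -> scale factor
    group_effect: float = 0.0
    transcript_params: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "w_x": None if self.w_x is None else self.w_x.tolist(),
            "w_y": None if self.w_y is None else self.w_y.tolist(),
            "support_x": self.support_x, "support_y": self.support_y,
            "rho": self.rho, "signal_amplitude": self.signal_amplitude,
            "batch_gamma": self.batch_gamma,
            "batch_delta": self.batch_delta, "group_effect": self.group_effect,
            "transcript_params": self.transcript_params, "seed": self.seed,
        }


# --------------------------------------------------------------------------- #
# transcripts
# --------------------------------------------------------------------------- #

@dataclass
class TranscriptSettings:
    n_sentences: int = 40
    mean_sentence_length: float = 8.0
    drift: float = 0.3               # probability of switching topic between sentences
    n_topics: int = 6
    stems_per_topic: int = 12

    def validate(self) -> None:
        if self.n_sentences < 2 or self.mean_sentence_length < 3:
            raise InvalidSettings("need >= 2 sentences of >= 3 words on average")
        if not 0.0 <= self.drift <= 1.0:
            raise InvalidSettings("drift must lie in [0, 1]")
        if self.n_topics < 2 or self.stems_per_topic < 4:
            raise InvalidSettings("need >= 2 topics of >= 4 stems")


_ONSETS = ("bl", "fl", "gr", "sn", "tr", "pl", "cr", "dr", "sk", "br")
_NUCLEI = ("ab", "eb", "ib", "ob", "ub", "am", "em", "im", "om", "um")
_CODAS = ("ick", "orn", "ust", "eld", "ard", "int", "osk", "urn", "aft", "ilt")

_DET = ("the", "a", "this", "that")
_PRON = ("he", "she", "it", "they", "we")
_PREP = ("in", "on", "under", "near", "behind")
_CONJ = ("and", "but", "or")
_SUBORD = ("because", "although", "while", "if")
_INTERJ = ("oh", "well", "um", "yeah")
_WH = ("why", "when", "how", "where")


def _topic_vocab(settings: TranscriptSettings, rng: np.random.Generator) -> list[dict]:
    """Per-topic pseudo-word stems with morphology the tagger resolves."""
    combos = [o + n + c for o in _ONSETS for n in _NUCLEI for c in _CODAS]
    need = settings.n_topics * settings.stems_per_topic
    if need > len(combos):
        raise InvalidSettings("too many stems requested for the synthetic lexicon")
    stems = rng.choice(len(combos), size=need, replace=False)
    topics = []
    for t in range(settings.n_topics):
        block = [combos[i] for i in stems[t * settings.stems_per_topic:
                                          (t + 1) * settings.stems_per_topic]]
        third = max(1, len(block) // 3)
        topics.append({
            "nouns": block[:third * 2],
            "verbs": [s + "ed" for s in block[third * 2:]],
            "adjs": [s + "ful" for s in block[:third]],
            "advs": [s + "ly" for s in block[third:third * 2]],
        })
    return topics


def _build_sentence(topic: dict, template: int, length: int,
                    rng: np.random.Generator) -> list[str]:
    pick = lambda seq: seq[rng.integers(len(seq))]
    noun = lambda: pick(topic["nouns"])
    verb = lambda: pick(topic["verbs"])
    adj = lambda: pick(topic["adjs"])
    adv = lambda: pick(topic["advs"])
    if template == 0:       # declarative
        words = [pick(_DET), noun(), verb(), pick(_PREP), pick(_DET), noun()]
    elif template == 1:     # question
        words = [pick(_WH), "did", pick(_PRON), "see", pick(_DET), noun()]
    elif template == 2:     # fragment
        words = [pick(_DET), adj(), noun()]
    elif template == 3:     # conjunctive
        words = [pick(_CONJ), pick(_PRON), verb(), pick(_DET), noun()]
    elif template == 4:     # subordinate
        words = [pick(_SUBORD), pick(_PRON), verb(), pick(_DET), noun(),
                 pick(_PRON), verb()]
    else:                   # interjection-initial
        words = [pick(_INTERJ), pick(_PRON), verb(), pick(_DET), noun()]
    # pad with adverb/adjective/prepositional material toward the target length
    while len(words) < length:
        kind = rng.integers(3)
        if kind == 0:
            words.append(adv())
        elif kind == 1:
            words.extend(["very", adj()])
        else:
            words.extend([pick(_PREP), pick(_DET), noun()])
    return words[:max(length, 3)]


def generate_transcripts(n_subjects: int, settings: TranscriptSettings | None = None,
                         seed: int = 0) -> tuple[list[Transcript], pd.DataFrame]:
    """Transcripts plus the per-subject true parameters (drift, mean length)."""
    settings = settings or TranscriptSettings()
    settings.validate()
    rng = np.random.default_rng(seed)
    topics = _topic_vocab(settings, np.random.default_rng(seed + 1))
    transcripts: list[Transcript] = []
    rows = []
    for i in range(n_subjects):
        sid = f"sub{i:03d}"
        topic = int(rng.integers(settings.n_topics))
        sentences: list[list[str]] = []
        for _ in range(settings.n_sentences):
            if rng.random() < settings.drift:
                topic = int(rng.integers(settings.n_topics))
            template = int(rng.integers(6))
            length = max(3, int(rng.poisson(settings.mean_sentence_length)))
            sentences.append(_build_sentence(topics[topic], template, length, rng))
        raw = ". ".join(" ".join(s) for s in sentences) + "."
        transcripts.append(Transcript(subject_id=sid, sentences=sentences,
                                      raw_text=raw))
        rows.append({"subject_id": sid, "drift": settings.drift,
                     "mean_sentence_length": settings.mean_sentence_length})
    return transcripts, pd.DataFrame(rows).set_index("subject_id")


# --------------------------------------------------------------------------- #
# linked feature blocks with a planted sparse mode
# --------------------------------------------------------------------------- #

def make_planted_truth(p1: int, p2: int, k_active: int = 10, rho: float = 0.7,
                       seed: int = 0,
                       signal_amplitude: float | None = None) -> SyntheticTruth:
    """Unit weight vectors with k_active equal-magnitude entries per side.

    ``signal_amplitude`` scales the latent score before it multiplies the
    weight vector; the default sqrt(k_active) puts each active feature's
    signal standard deviation at the noise level (per-feature SNR 1), the
    regime recovery tests are calibrated for. Amplitudes well below
    sqrt(k_active) push the planted mode under the noise spectral edge of the
    cross-product matrix, where no estimator can find it.
    """
    if k_active > min(p1, p2):
        raise DimensionError("active set larger than block dimension")
    if signal_amplitude is None:
        signal_amplitude = float(np.sqrt(k_active))
    rng = np.random.default_rng(seed)
    sx = sorted(rng.choice(p1, size=k_active, replace=False).tolist())
    sy = sorted(rng.choice(p2, size=k_active, replace=False).tolist())
    w_x = np.zeros(p1)
    w_y = np.zeros(p2)
    w_x[sx] = rng.choice([-1.0, 1.0], size=k_active) / np.sqrt(k_active)
    w_y[sy] = rng.choice([-1.0, 1.0], size=k_active) / np.sqrt(k_active)
    return SyntheticTruth(w_x=w_x, w_y=w_y, support_x=sx, support_y=sy,
                          rho=rho, signal_amplitude=signal_amplitude, seed=seed)


def generate_linked_blocks(n: int, p1: int, p2: int,
                           truth: SyntheticTruth | None = None, seed: int = 0,
                           batch: pd.Series | None = None,
                           group: pd.Series | None = None,
                           subject_ids: list[str] | None = None,
                           noise_on_support: bool = True
                           ) -> tuple[FeatureMatrix, FeatureMatrix, SyntheticTruth]:
    """Two blocks sharing one sparse canonical mode at latent correlation rho.

    X = a·s·w_x' + noise and Y = a·t·w_y' + noise with corr(s, t) = rho, unit
    Gaussian noise, and signal amplitude a from the truth (default sqrt(k)
    for a k-sparse truth: per-active-feature SNR 1). With
    ``noise_on_support=False`` the noise is projected off the planted weight
    directions, so the mode's canonical correlation equals rho exactly rather
    than being attenuated by within-support noise. Optional per-batch
    location/scale effects and a group mean shift (on Y) are applied
    afterwards and recorded in the returned truth.
    """
    if n < 10:
        raise DimensionError("need n >= 10")
    truth = truth or make_planted_truth(
        p1, p2, k_active=min(10, max(1, min(p1, p2) // 2)), seed=seed)
    if len(truth.w_x) != p1 or len(truth.w_y) != p2:
        raise DimensionError("truth weight vectors do not match block dimensions")
    rng = np.random.default_rng(seed)
    s = rng.standard_normal(n)
    t = truth.rho * s + np.sqrt(1 - truth.rho ** 2) * rng.standard_normal(n)
    Ex = rng.standard_normal((n, p1))
    Ey = rng.standard_normal((n, p2))
    if not noise_on_support:
        Ex -= np.outer(Ex @ truth.w_x, truth.w_x)
        Ey -= np.outer(Ey @ truth.w_y, truth.w_y)
    a = truth.signal_amplitude
    X = a * np.outer(s, truth.w_x) + Ex
    Y = a * np.outer(t, truth.w_y) + Ey
    ids = subject_ids or [f"sub{i:03d}" for i in range(n)]
    if batch is not None:
        batch = pd.Series(batch).reindex(ids) if not isinstance(batch, pd.Series) else batch.reindex(ids)
        for lv in batch.unique():
            if lv not in truth.batch_gamma:
                truth.batch_gamma[lv] = float(rng.normal(0, 1))
                truth.batch_delta[lv] = float(rng.uniform(0.8, 1.25))
            mask = (batch == lv).to_numpy()
            X[mask] = X[mask] * truth.batch_delta[lv] + truth.batch_gamma[lv]
            Y[mask] = Y[mask] * truth.batch_delta[lv] + truth.batch_gamma[lv]
    if group is not None and truth.group_effect:
        g = pd.Series(group).reindex(ids).to_numpy(float)
        Y = Y + truth.group_effect * g[:, None]
    bx = FeatureMatrix(pd.DataFrame(X, index=ids,
                                    columns=[f"x{j:03d}" for j in range(p1)]))
    by = FeatureMatrix(pd.DataFrame(Y, index=ids,
                                    columns=[f"y{j:03d}" for j in range(p2)]))
    return bx, by, truth


# --------------------------------------------------------------------------- #
# resting-state time-series panels
# --------------------------------------------------------------------------- #

def default_atlas(nodes_per_network: int = 20, hub: str = "LAN") -> NetworkAtlas:
    """Six named networks with disjoint synthetic node ids."""
    from .brainfeat import NETWORK_NAMES
    networks = {net: frozenset(f"{net}_{i:02d}" for i in range(nodes_per_network))
                for net in NETWORK_NAMES}
    return NetworkAtlas(networks=networks, hub_network=hub)


def generate_timeseries_panels(n_subjects: int, atlas: NetworkAtlas,
                               within_r: float = 0.5, between_r: float = 0.2,
                               T: int = 200, seed: int = 0,
                               subject_ids: list[str] | None = None
                               ) -> tuple[list[TimeSeriesPanel], SyntheticTruth]:
    """One-factor-per-network panels hitting the target correlations.

    Node series = sqrt(within_r)·f_net + sqrt(1−within_r)·noise, so the
    expected within-network pair correlation is within_r. Non-hub network
    factors are correlated with the hub factor at a level calibrated so the
    hub-to-network mean-series correlation is approximately between_r
    (the factor correlation is deflated by the node-noise attenuation of the
    averaged series).
    """
    if not 0.0 <= between_r <= within_r < 1.0:
        raise InvalidCorrelationSpec("need 0 <= between_r <= within_r < 1")
    if T < 50:
        raise InvalidCorrelationSpec("need T >= 50")
    w = within_r
    rng = np.random.default_rng(seed)
    hub = atlas.hub_network
    sizes = {net: len(nodes) for net, nodes in atlas.networks.items()}

    if between_r > 0 and w > 0:
        atten = {net: w / (w + (1 - w) / sizes[net]) for net in atlas.names}
        rho_f = {net: between_r / np.sqrt(atten[hub] * atten[net])
                 for net in atlas.names if net != hub}
        bad = [net for net, r in rho_f.items() if r > 0.999]
        if bad:
            raise InvalidCorrelationSpec(
                f"between_r = {between_r} unreachable for networks {bad} at "
                f"within_r = {within_r} and these network sizes")
    else:
        rho_f = {net: 0.0 for net in atlas.names if net != hub}

    panels = []
    for i in range(n_subjects):
        sid = (subject_ids[i] if subject_ids else f"sub{i:03d}")
        f_hub = rng.standard_normal(T)
        factors = {hub: f_hub}
        for net in atlas.names:
            if net != hub:
                r = rho_f[net]
                factors[net] = r * f_hub + np.sqrt(1 - r ** 2) * rng.standard_normal(T)
        series = {}
        for net, nodes in atlas.networks.items():
            for node in sorted(nodes):
                noise = rng.standard_normal(T)
                series[node] = np.sqrt(w) * factors[net] + np.sqrt(1 - w) * noise
        panels.append(TimeSeriesPanel(subject_id=sid, series=series))
    truth = SyntheticTruth(seed=seed, transcript_params={
        "within_r": within_r, "between_r": between_r, "T": T})
    return panels, truth


# --------------------------------------------------------------------------- #
# morphometry
# --------------------------------------------------------------------------- #

#: per-structure typical volumes (mm^3), one hemisphere
_VOLUME_MEANS = {
    "Thalamus-Proper": 7000.0, "Caudate": 3500.0, "Putamen": 4800.0,
    "Pallidum": 1500.0, "Hippocampus": 4000.0, "Amygdala": 1600.0,
    "Accumbens-area": 600.0, "VentralDC": 3800.0, "Lateral-Ventricle": 7500.0,
    "Cerebellum-Cortex": 50000.0,
}
_THICKNESS_MEAN = 2.5    # mm
_THICKNESS_SD = 0.15
_VOLUME_CV = 0.08


def generate_morphometry(n_subjects: int, schema: dict[str, str] | None = None,
                         effects: dict | None = None, seed: int = 0,
                         subject_ids: list[str] | None = None) -> FeatureMatrix:
    """Positive thickness/volume table; optional planted latent covariation.

    ``effects`` may carry ``latent`` (per-subject scores), ``features`` (names)
    and ``loading`` (effect in units of that feature's sd). Values are floored
    at 10% of the feature mean, so the table is positive by construction.
    """
    schema = schema if schema is not None else default_morphometry_schema()
    rng = np.random.default_rng(seed)
    ids = subject_ids or [f"sub{i:03d}" for i in range(n_subjects)]
    cols = {}
    for name, role in schema.items():
        if role == "cortical_thickness":
            mean, sd = _THICKNESS_MEAN, _THICKNESS_SD
        elif role == "subcortical_volume":
            structure = name.split("-", 1)[1] if "-" in name else name
            mean = _VOLUME_MEANS.get(structure, 3000.0)
            sd = mean * _VOLUME_CV
        else:
            raise SchemaViolation(f"unknown role {role!r} for feature {name!r}")
        cols[name] = rng.normal(mean, sd, size=n_subjects)
    df = pd.DataFrame(cols, index=ids)
    if effects:
        latent = np.asarray(effects["latent"], dtype=float)
        if len(latent) != n_subjects:
            raise DimensionError("latent scores must match subject count")
        loading = float(effects.get("loading", 0.5))
        for name in effects["features"]:
            if name not in df.columns:
                raise SchemaViolation(f"planted feature {name!r} not in schema")
            df[name] = df[name] + loading * df[name].std() * latent
    floor = {name: (0.1 * _THICKNESS_MEAN if role == "cortical_thickness"
                    else 0.1 * _VOLUME_MEANS.get(
                        name.split("-", 1)[1] if "-" in name else name, 3000.0))
             for name, role in schema.items()}
    df = df.clip(lower=pd.Series(floor), axis=1)
    return FeatureMatrix(df, provenance="morphometry", state="raw")


# --------------------------------------------------------------------------- #
# metadata and whole-study fixture
# --------------------------------------------------------------------------- #

N_CHR_DEFAULT = 46
N_HI_DEFAULT = 22
CLINICAL_ITEMS = tuple(
    [f"clin_P{i}" for i in range(1, 6)] + [f"clin_N{i}" for i in range(1, 7)]
    + [f"clin_D{i}" for i in range(1, 5)] + [f"clin_G{i}" for i in range(1, 5)]
)


def generate_metadata(n_chr: int = N_CHR_DEFAULT, n_hi: int = N_HI_DEFAULT,
                      sites: tuple[str, ...] = ("siteA", "siteB"),
                      seed: int = 0) -> pd.DataFrame:
    """Diagnosis, site, handedness and clinical item scores per subject.

    Clinical items follow a prodromal-symptom instrument layout (5 positive,
    6 negative, 4 disorganized, 4 general items, ordinal 0–6); the CHR group
    scores higher on average.
    """
    rng = np.random.default_rng(seed)
    n = n_chr + n_hi
    ids = [f"sub{i:03d}" for i in range(n)]
    diagnosis = ["CHR"] * n_chr + ["HI"] * n_hi
    site = [sites[i % len(sites)] for i in range(n)]
    handedness = rng.integers(-100, 101, size=n)
    df = pd.DataFrame({"diagnosis": diagnosis, "site": site,
                       "handedness": handedness}, index=pd.Index(ids, name="subject_id"))
    severity = np.where(np.array(diagnosis) == "CHR", 2.5, 0.6)
    for item in CLINICAL_ITEMS:
        lam = severity * rng.uniform(0.6, 1.4)
        df[item] = np.clip(rng.poisson(lam), 0, 6)
    return df


def write_study(out_dir, n_chr: int = N_CHR_DEFAULT, n_hi: int = N_HI_DEFAULT,
                seed: int = 0, settings: TranscriptSettings | None = None,
                atlas: NetworkAtlas | None = None, within_r: float = 0.5,
                between_r: float = 0.2, T: int = 200) -> dict:
    """Write a complete fixture study to disk; returns the truth manifest."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    (out / "transcripts").mkdir(parents=True, exist_ok=True)
    (out / "timeseries").mkdir(exist_ok=True)
    atlas = atlas or default_atlas()
    settings = settings or TranscriptSettings()
    meta = generate_metadata(n_chr, n_hi, seed=seed)
    ids = list(meta.index)
    n = len(ids)
    transcripts, _ = generate_transcripts(n, settings, seed=seed + 1)
    for t, sid in zip(transcripts, ids):
        (out / "transcripts" / f"{sid}.txt").write_text(t.raw_text, encoding="utf-8")
    panels, p_truth = generate_timeseries_panels(
        n, atlas, within_r=within_r, between_r=between_r, T=T,
        seed=seed + 2, subject_ids=ids)
    for panel in panels:
        panel.to_tsv(out / "timeseries" / f"{panel.subject_id}.tsv")
    morph = generate_morphometry(n, seed=seed + 3, subject_ids=ids)
    morph.to_tsv(out / "morphometry.tsv")
    meta.to_csv(out / "metadata.tsv", sep="\t")
    atlas.to_json(out / "atlas.json")
    truth = {"seed": seed, "n_chr": n_chr, "n_hi": n_hi,
             "timeseries": p_truth.to_dict()["transcript_params"],
             "transcript_params": {
                 "n_sentences": settings.n_sentences,
                 "mean_sentence_length": settings.mean_sentence_length,
                 "drift": settings.drift, "n_topics": settings.n_topics}}
    (out / "truth.json").write_text(json.dumps(truth, indent=2), encoding="utf-8")
    return truth
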