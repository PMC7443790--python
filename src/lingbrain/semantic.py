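"""Latent semantic analysis: word vectors and inter-sentence coherence.

A semantic space is the truncated singular value decomposition of a weighted
term-passage matrix, where a passage is a single sentence of the background
corpus. Word vectors are the rows of ``U_k * S_k``; a sentence vector is the
mean of its in-vocabulary word vectors; semantic coherence is the cosine of
consecutive sentence vectors. By default the space is built from the analyzed
corpus itself with log-entropy weighting and k = 50, and can be persisted
(vocabulary + vectors + manifest) so coherence features are reproducible.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .errors import AllPairsSkipped, EmptyTranscript, VocabularyTooSmall
from .text import Transcript

WEIGHTING_SCHEMES = ("tf", "tfidf", "log_entropy")

DEFAULT_K = 50
DEFAULT_WEIGHTING = "log_entropy"


@dataclass
class SemanticSpace:
    vocabulary: dict[str, int]          # token -> row index
    vectors: np.ndarray                 # |V| x k
    k: int
    weighting_scheme: str
    corpus_hash: str = ""

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.vocabulary[token]]

    # -- persistence -----------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        order = sorted(self.vocabulary, key=self.vocabulary.get)
        (d / "vocabulary.txt").write_text("\n".join(order) + "\n", encoding="utf-8")
        np.savetxt(d / "vectors.tsv", self.vectors, delimiter="\t")
        manifest = {"k": self.k, "weighting_scheme": self.weighting_scheme,
                    "corpus_hash": self.corpus_hash, "vocabulary_size": len(order)}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, directory) -> "SemanticSpace":
        d = Path(directory)
        tokens = (d / "vocabulary.txt").read_text(encoding="utf-8").split()
        vectors = np.loadtxt(d / "vectors.tsv", delimiter="\t", ndmin=2)
        manifest = json.loads((d / "manifest.json").read_text(encoding="utf-8"))
        return cls(vocabulary={t: i for i, t in enumerate(tokens)}, vectors=vectors,
                   k=manifest["k"], weighting_scheme=manifest["weighting_scheme"],
                   corpus_hash=manifest.get("corpus_hash", ""))


def _corpus_hash(passages: list[list[str]]) -> str:
    h = hashlib.sha256()
    for p in passages:
        h.update(" ".join(p).encode("utf-8"))
        h.update(b"\n")
    return h.hexdigest()


def _weight(counts: sp.csr_matrix, scheme: str) -> sp.csr_matrix:
    """Apply the local/global weighting to a |V| x |P| count matrix."""
    if scheme == "tf":
        return counts.astype(float)
    if scheme == "tfidf":
        n_passages = counts.shape[1]
        df = np.asarray((counts > 0).sum(axis=1)).ravel()
        idf = np.log(n_passages / np.maximum(df, 1))
        return sp.diags(idf) @ counts.astype(float)
    if scheme == "log_entropy":
        n_passages = counts.shape[1]
        gf = np.asarray(counts.sum(axis=1)).ravel()        # global term frequency
        c = counts.tocoo()
        p = c.data / gf[c.row]                              # p_ij = tf_ij / gf_i
        ent = np.zeros(counts.shape[0])
        np.add.at(ent, c.row, p * np.log(p))
        # global weight in [0, 1]: 1 + sum_j p log p / log(P)
        g = 1.0 + ent / max(np.log(n_passages), 1e-12)
        local = counts.copy().astype(float)
        local.data = np.log1p(local.data)
        return sp.diags(g) @ local
    raise ValueError(f"unknown weighting scheme {scheme!r}; one of {WEIGHTING_SCHEMES}")


def build_semantic_space(corpus: list[Transcript], k: int = DEFAULT_K,
                         weighting_scheme: str = DEFAULT_WEIGHTING) -> SemanticSpace:
    """Build a k-dimensional space from the sentences of ``corpus``.

    The decomposition is deterministic: dense LAPACK SVD for small problems, a
    Lanczos solver with a fixed start vector otherwise. If the weighted matrix
    has fewer than ``k`` numerically nonzero singular values, k is reduced with
    a warning rather than padding with noise directions.

    Raises
    ------
    VocabularyTooSmall
        If the corpus has fewer than ``k`` distinct tokens.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    passages: list[list[str]] = [s for t in corpus for s in t.sentences]
    vocab: dict[str, int] = {}
    for p in passages:
        for tok in p:
            if tok not in vocab:
                vocab[tok] = len(vocab)
    if len(vocab) < k:
        raise VocabularyTooSmall(f"{len(vocab)} distinct tokens < k = {k}")

    rows, cols, vals = [], [], []
    for j, p in enumerate(passages):
        for tok in p:
            rows.append(vocab[tok])
            cols.append(j)
            vals.append(1.0)
    counts = sp.csr_matrix((vals, (rows, cols)), shape=(len(vocab), len(passages)))
    weighted = _weight(counts, weighting_scheme)

    min_dim = min(weighted.shape)
    if min_dim <= 400 or k >= min_dim - 1:
        dense = weighted.toarray()
        u, s, _ = np.linalg.svd(dense, full_matrices=False)
    else:
        v0 = np.full(weighted.shape[1], 1.0 / np.sqrt(weighted.shape[1]))
        u, s, _ = svds(weighted.tocsc(), k=min(k, min_dim - 1), v0=v0)
        order = np.argsort(s)[::-1]
        u, s = u[:, order], s[order]

    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    k_eff = min(k, rank)
    if k_eff < k:
        warnings.warn(f"rank deficient: reducing k from {k} to {k_eff}", stacklevel=2)
    vectors = u[:, :k_eff] * s[:k_eff]
    return SemanticSpace(vocabulary=vocab, vectors=vectors, k=k_eff,
                         weighting_scheme=weighting_scheme,
                         corpus_hash=_corpus_hash(passages))


def sentence_vector(sentence: list[str], space: SemanticSpace) -> tuple[np.ndarray, bool]:
    """Mean of in-vocabulary token vectors; ``(zero vector, True)`` if all OOV."""
    idx = [space.vocabulary[t] for t in sentence if t in space.vocabulary]
    if not idx:
        return np.zeros(space.vectors.shape[1]), True
    return space.vectors[idx].mean(axis=0), False


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def coherence_series(t: Transcript, space: SemanticSpace) -> tuple[list[float], int]:
    """Cosine similarity between consecutive sentence vectors.

    Pairs where either sentence vector is zero (all tokens out of vocabulary,
    where the cosine is undefined) are skipped; the skip count is returned
    alongside the series.

    Raises
    ------
    EmptyTranscript
        Fewer than 2 sentences.
    AllPairsSkipped
        Every consecutive pair involved a zero vector.
    """
    if t.n_sentences < 2:
        raise EmptyTranscript(f"subject {t.subject_id!r}: coherence needs >= 2 sentences")
    vecs, flags = zip(*(sentence_vector(s, space) for s in t.sentences))
    series: list[float] = []
    skipped = 0
    for i in range(len(vecs) - 1):
        if flags[i] or flags[i + 1] or not np.linalg.norm(vecs[i]) or not np.linalg.norm(vecs[i + 1]):
            skipped += 1
            continue
        series.append(_cosine(vecs[i], vecs[i + 1]))
    if not series:
        raise AllPairsSkipped(f"subject {t.subject_id!r}: all {skipped} pairs skipped")
    return series, skipped
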