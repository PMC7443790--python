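"""Transcript segmentation and tokenization.

Interview transcripts arrive as plain UTF-8 text, one document per subject,
already restricted to participant speech. Sentences are split on terminal
punctuation (``.``, ``!``, ``?``) with a guard list of common abbreviations;
runs of terminators (ellipses, ``?!``) collapse to a single boundary. Tokens
are whitespace-delimited with punctuation stripped from their edges. Two token
views are kept per sentence: lowercased (for the semantic space) and original
casing (for the POS tagger, where casing is informative).
"""
from __future__ import annotations

import re
import string
from dataclasses import dataclass, field

from .errors import EmptyTranscript

# Common abbreviations whose trailing period does not end a sentence.
ABBREVIATIONS = frozenset({
    "mr", "mrs", "ms", "dr", "prof", "st", "jr", "sr", "vs", "etc",
    "e.g", "i.e", "approx", "dept", "est", "inc", "no", "vol",
})

_EDGE_PUNCT = string.punctuation + "‘’“”…"
_TERMINATOR = re.compile(r"[.!?]+(?=\s|$)")
_ABBREV_MARK = ""  # private-use sentinel, restored to "." after splitting


@dataclass
class Transcript:
    """Ordered sentences of tokens for one subject.

    ``sentences`` holds lowercased tokens (semantic analysis); ``sentences_cased``
    the same tokens with original casing (POS tagging). Sentence order follows
    the source text.
    """
    subject_id: str
    sentences: list[list[str]]
    sentences_cased: list[list[str]] = field(default_factory=list)
    raw_text: str = ""

    def __post_init__(self) -> None:
        if not self.sentences_cased:
            self.sentences_cased = [list(s) for s in self.sentences]

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


def tokenize(sentence_text: str) -> list[str]:
    """Whitespace tokens with punctuation stripped from the edges; empties dropped."""
    out = []
    for raw in sentence_text.split():
        tok = raw.strip(_EDGE_PUNCT)
        if tok:
            out.append(tok)
    return out


def _protect_abbreviations(text: str) -> str:
    def guard(m: re.Match) -> str:
        return m.group(0).replace(".", _ABBREV_MARK)

    pattern = re.compile(
        r"\b(" + "|".join(re.escape(a) for a in sorted(ABBREVIATIONS, key=len, reverse=True)) + r")\.",
        re.IGNORECASE,
    )
    return pattern.sub(guard, text)


def strip_speaker_prefixes(text: str, prefixes: tuple[str, ...] = ("I:", "P:")) -> str:
    """Optionally drop interviewer turns from a two-speaker transcript.

    Lines starting with the first prefix (interviewer) are removed entirely;
    the remaining prefixes are stripped but their line kept. Off by default in
    the pipeline: transcripts are assumed pre-filtered to participant speech.
    """
    interviewer, *kept = prefixes
    lines = []
    for line in text.splitlines():
        stripped = line.lstrip()
        if stripped.startswith(interviewer):
            continue
        for p in kept:
            if stripped.startswith(p):
                stripped = stripped[len(p):].lstrip()
        lines.append(stripped)
    return "\n".join(lines)


def segment_sentences(raw_text: str, subject_id: str = "") -> Transcript:
    """Split raw text into a :class:`Transcript`.

    Raises
    ------
    EmptyTranscript
        If no sentence with at least one token survives.
    """
    if not raw_text or not raw_text.strip():
        raise EmptyTranscript(f"subject {subject_id!r}: empty text")

    protected = _protect_abbreviations(raw_text)
    pieces = _TERMINATOR.split(protected)

    sentences_cased: list[list[str]] = []
    for piece in pieces:
        piece = piece.replace(_ABBREV_MARK, ".")
        toks = tokenize(piece)
        if toks:
            sentences_cased.append(toks)

    if not sentences_cased:
        raise EmptyTranscript(f"subject {subject_id!r}: no tokens after segmentation")

    sentences = [[t.lower() for t in s] for s in sentences_cased]
    return Transcript(subject_id=subject_id, sentences=sentences,
                      sentences_cased=sentences_cased, raw_text=raw_text)
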