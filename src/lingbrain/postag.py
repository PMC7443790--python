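"""Lightweight rule-based Penn Treebank part-of-speech tagger.

Tag relative frequencies serve as syntactic-complexity features, so what
matters here is a deterministic, self-contained tagger covering the 36
word-level Penn Treebank tags: closed-class words come from an explicit
lexicon, open-class words from ordered morphology rules (numerals, casing,
derivational suffixes), with a small amount of left context (a base verb after
``to`` or a modal is an infinitive). Tokens it cannot place in the word-level
tagset (symbols, stray punctuation) pool into the ``other`` bucket, which is
reported but excluded from the analysis feature set.
"""
from __future__ import annotations

import re

from .errors import TaggerUnavailable
from .text import Transcript

#: The 36 word-level Penn Treebank tags, in conventional order.
PTB_WORD_TAGS: tuple[str, ...] = (
    "CC", "CD", "DT", "EX", "FW", "IN", "JJ", "JJR", "JJS", "LS", "MD",
    "NN", "NNS", "NNP", "NNPS", "PDT", "POS", "PRP", "PRP$", "RB", "RBR",
    "RBS", "RP", "SYM", "TO", "UH", "VB", "VBD", "VBG", "VBN", "VBP",
    "VBZ", "WDT", "WP", "WP$", "WRB",
)

#: Pool for tokens outside the word-level tagset.
OTHER_TAG = "other"

_LEXICON: dict[str, str] = {}
_LEX_SOURCES = {
    "CC": "and or but nor plus minus",
    "DT": "the a an this that these those each every either neither some "
          "any no all both another such",
    "EX": "there",
    "IN": "in on at by with from of for about against between into through "
          "during before after above below under over because although "
          "while if since unless until whereas though as near across "
          "behind beyond despite inside outside toward upon within without",
    "MD": "can could may might must shall should will would",
    "PDT": "half quite",
    "PRP": "i you he she it we they me him her us them myself yourself "
           "himself herself itself ourselves yourselves themselves mine "
           "yours hers ours theirs",
    "PRP$": "my your his its our their",
    "RB": "not never always often sometimes very too quite rather really "
          "just also still yet again soon now then here maybe perhaps "
          "almost already enough else instead even well",
    "RBR": "more less further earlier later longer sooner",
    "RBS": "most least",
    "JJR": "better worse bigger smaller larger older newer higher lower "
           "greater fewer",
    "JJS": "best worst biggest smallest largest oldest newest highest lowest",
    "TO": "to",
    "UH": "oh ah um uh er hmm mm wow yeah hey ouch huh ooh oops alas gosh "
          "hm okay",
    "WDT": "which whichever whatever",
    "WP": "who whom what whoever",
    "WP$": "whose",
    "WRB": "when where why how whenever wherever however",
}
for _tag, _words in _LEX_SOURCES.items():
    for _w in _words.split():
        _LEXICON[_w] = _tag

# Forms of be/have/do and frequent irregular verbs.
_VERB_FORMS = {
    "be": "VB", "am": "VBP", "are": "VBP", "is": "VBZ", "was": "VBD",
    "were": "VBD", "been": "VBN", "being": "VBG",
    "have": "VBP", "has": "VBZ", "had": "VBD", "having": "VBG",
    "do": "VBP", "does": "VBZ", "did": "VBD", "doing": "VBG", "done": "VBN",
}
_IRREGULAR_PAST = set(
    "went sat said saw got made took came knew thought felt told became "
    "left kept began brought ran ate spoke stood heard let meant met paid "
    "found gave held wrote read lost sent built spent drove fell grew "
    "chose slept woke threw broke flew drank sang swam rose led won".split()
)
_BASE_VERBS = set(
    "go see make want need like feel think know say look come take use "
    "find give tell work call try ask seem help play move live believe "
    "happen write sit stand lose meet pay run eat speak hear stay talk "
    "walk remember start stop keep turn begin bring hold put mean read "
    "wonder guess suppose hope worry sleep dream laugh cry".split()
)

_CONTRACTIONS = {
    "don't": "VBP", "doesn't": "VBZ", "didn't": "VBD", "can't": "MD",
    "won't": "MD", "couldn't": "MD", "wouldn't": "MD", "shouldn't": "MD",
    "mustn't": "MD", "isn't": "VBZ", "aren't": "VBP", "wasn't": "VBD",
    "weren't": "VBD", "haven't": "VBP", "hasn't": "VBZ", "hadn't": "VBD",
    "it's": "PRP", "i'm": "PRP", "i've": "PRP", "i'll": "PRP", "i'd": "PRP",
    "you're": "PRP", "you've": "PRP", "we're": "PRP", "we've": "PRP",
    "they're": "PRP", "they've": "PRP", "he's": "PRP", "she's": "PRP",
    "that's": "DT", "there's": "EX", "what's": "WP", "let's": "VB",
}

_NUMERIC = re.compile(r"^[+-]?(\d[\d,]*\.?\d*|\.\d+)$")
_NUMBER_WORDS = set(
    "zero one two three four five six seven eight nine ten eleven twelve "
    "thirteen fourteen fifteen sixteen seventeen eighteen nineteen twenty "
    "thirty forty fifty sixty seventy eighty ninety hundred thousand "
    "million billion".split()
)
_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "ish", "less", "ic", "al")
_WORDLIKE = re.compile(r"[A-Za-z]")


class RuleBasedTagger:
    """Deterministic tagger: lexicon first, then morphology, minimal context."""

    tagset = PTB_WORD_TAGS

    def tag(self, tokens: list[str], sentence_initial: bool = True) -> list[str]:
        tags: list[str] = []
        prev = ""
        for pos, token in enumerate(tokens):
            tag = self._tag_one(token, prev, initial=(pos == 0 and sentence_initial))
            tags.append(tag)
            prev = tag
        return tags

    def tag_transcript(self, t: Transcript) -> list[tuple[str, str]]:
        pairs: list[tuple[str, str]] = []
        for sent in t.sentences_cased:
            for token, tag in zip(sent, self.tag(sent)):
                pairs.append((token, tag))
        return pairs

    def _tag_one(self, token: str, prev: str, initial: bool) -> str:
        low = token.lower()
        if not _WORDLIKE.search(token):
            return "CD" if _NUMERIC.match(token) else OTHER_TAG
        if low in _CONTRACTIONS:
            return _CONTRACTIONS[low]
        if low == "'s":
            return "POS"
        if _NUMERIC.match(token) or low in _NUMBER_WORDS:
            return "CD"
        if low in _VERB_FORMS:
            tag = _VERB_FORMS[low]
            return "VB" if prev in ("TO", "MD") and tag in ("VBP",) else tag
        if low in _IRREGULAR_PAST:
            return "VBD"
        if low in _LEXICON:
            return _LEXICON[low]
        if low in _BASE_VERBS:
            return "VB" if prev in ("TO", "MD") else "VBP"
        # proper noun: capitalized off sentence start
        if token[0].isupper() and not initial:
            return "NNPS" if low.endswith("s") and not low.endswith("ss") else "NNP"
        # morphology, most specific first
        if low.endswith("ly") and len(low) > 3:
            return "RB"
        if low.endswith("ing") and len(low) > 4:
            return "VBG"
        if low.endswith("ed") and len(low) > 3:
            return "VBD"
        if low.endswith("est") and len(low) > 4:
            return "JJS"
        if low.endswith(_ADJ_SUFFIXES) and len(low) > 4:
            return "JJ"
        if low.endswith("s") and not low.endswith(("ss", "us", "is")) and len(low) > 2:
            stem = low[:-1]
            if stem in _BASE_VERBS:
                return "VBZ"
            return "NNS"
        return "NN"


def get_tagger(tagset: str = "ptb") -> RuleBasedTagger:
    """Return a tagger for the configured tagset.

    Raises
    ------
    TaggerUnavailable
        If no tagger is registered for ``tagset``.
    """
    if tagset.lower() in ("ptb", "penn", "penn-treebank"):
        return RuleBasedTagger()
    raise TaggerUnavailable(f"no tagger for tagset {tagset!r}")
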