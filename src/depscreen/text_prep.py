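"""Utterance cleaning and tokenization.

Transcripts of wizard-of-oz clinical interviews carry annotation spans that
were never spoken ("[laughter]", "<sync>", "(clears throat)") alongside the
dialogue itself.  Cleaning strips those spans first, then deletes basic
punctuation characters, lowercases, and normalizes whitespace.  Stop words
are *kept* by default: filler-word frequency is itself a downstream feature,
and removing stop words was found to hurt rather than help classification.

Cleaning is idempotent: ``clean_utterance(clean_utterance(t)) ==
clean_utterance(t)`` for any input under fixed rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["CleaningRules", "clean_utterance", "tokenize", "DEFAULT_RULES"]

#: Annotation spans: square brackets, angle brackets, parentheses.
_DEFAULT_MARKER_PATTERNS = (r"\[[^\]]*\]", r"<[^>]*>", r"\([^)]*\)")

#: Basic punctuation deleted character-wise (apostrophes are kept so that
#: contractions like "what's" remain single words).
_DEFAULT_PUNCTUATION = ",.[]()<>?!;:\""


@dataclass(frozen=True)
class CleaningRules:
    """Configuration for :func:`clean_utterance`.

    Attributes
    ----------
    lowercase:
        Convert to lower case (on by default).
    punctuation_chars:
        Characters deleted from the text (character deletion, not token
        splitting).  Must contain at least ``, . [ ]``.
    marker_patterns:
        Regex patterns whose whole match is removed before punctuation
        deletion; defaults cover bracketed annotation spans.
    stopword_removal:
        Optional removal of ``stopwords`` after cleaning (off by default).
    """

    lowercase: bool = True
    punctuation_chars: str = _DEFAULT_PUNCTUATION
    marker_patterns: tuple[str, ...] = _DEFAULT_MARKER_PATTERNS
    stopword_removal: bool = False
    stopwords: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = {",", ".", "[", "]"} - set(self.punctuation_chars)
        if missing:
            raise ValueError(
                f"punctuation_chars must include basic punctuation; missing {sorted(missing)}"
            )


DEFAULT_RULES = CleaningRules()


def clean_utterance(text: str, rules: CleaningRules = DEFAULT_RULES) -> str:
    """Clean one utterance: strip markers, delete punctuation, lowercase.

    Order matters: marker spans are removed first (so "[laughter]" disappears
    wholesale rather than degrading to "laughter"), punctuation characters
    are then deleted, the text is lowercased, and whitespace runs collapse to
    single spaces.  Empty input yields empty output.
    """
    for pat in rules.marker_patterns:
        text = re.sub(pat, " ", text)
    text = text.translate({ord(c): None for c in rules.punctuation_chars})
    if rules.lowercase:
        text = text.lower()
    if rules.stopword_removal and rules.stopwords:
        text = " ".join(t for t in text.split() if t not in rules.stopwords)
    return " ".join(text.split())


def tokenize(cleaned: str) -> list[str]:
    """Split cleaned text on runs of whitespace, preserving order.

    A word is a maximal non-whitespace run; no empty tokens are produced.
    """
    return cleaned.split()
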