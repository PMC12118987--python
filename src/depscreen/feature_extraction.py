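"""Per-session NLP feature bank for depression screening.

Each interview session is summarized by 30 named features: 19 *answer
sentiment* features — the lexicon polarity of the participant's answer to
each question in a canonical pool, with 0 imputed when the question was not
asked (or drew no answer) — plus 11 *global* features describing the whole
conversation:

=====================  =====================================================
avg_sentiment          polarity of all participant speech pooled together
avg_response_time      mean latency (s) between a bot turn and the reply
speech_speed           mean words/second over participant turns
avg_unique_frequency   mean per-comment fraction of distinct words
avg_sw_frequency       mean per-comment fraction of filler words (uh/um/mm)
avg_characters         mean per-comment characters-per-word
avg_nouns .. avg_adv   mean per-comment POS-role fractions (4 features)
fp_avg                 mean per-comment fraction of first-person words
=====================  =====================================================

A "comment" is one participant turn.  Per-comment features are unweighted
means of per-comment ratios, so duplicating or permuting comments leaves
them unchanged.  The sentiment scorer and POS tagger are injectable: the
defaults are a small deterministic polarity lexicon and dictionary tagger
covering the closed vocabulary of the synthetic corpus generator, and any
production engine satisfying the same contracts can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd

from .corpus_io import BOT, PARTICIPANT, LabelRecord, Session
from .text_prep import CleaningRules, DEFAULT_RULES, clean_utterance, tokenize

__all__ = [
    "FeatureSpec",
    "FeatureVector",
    "DictTagger",
    "DEFAULT_SPEC",
    "DEFAULT_QUESTION_POOL",
    "GLOBAL_FEATURES",
    "sentiment_score",
    "match_question",
    "answer_sentiment_features",
    "avg_sentiment",
    "avg_response_time",
    "speech_speed",
    "per_comment_ratio",
    "avg_unique_frequency",
    "avg_sw_frequency",
    "avg_characters",
    "pos_frequencies",
    "fp_avg",
    "extract_features",
    "extract_corpus",
    "write_features",
    "read_features",
]

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Closed default vocabulary.
#
# Partitioned into sentiment-bearing, first-person, filler and neutral
# words so that every feature above is analytically checkable; the synthetic
# corpus generator draws utterances from exactly these lists.
# --------------------------------------------------------------------------

POSITIVE_WORDS: dict[str, float] = {
    "good": 1.0, "great": 1.0, "happy": 1.0, "glad": 1.0,
    "fine": 0.5, "hopeful": 0.5, "calm": 0.5, "relaxed": 0.5,
}
NEGATIVE_WORDS: dict[str, float] = {
    "bad": -1.0, "sad": -1.0, "awful": -1.0, "lonely": -1.0,
    "miserable": -1.0, "tired": -0.5, "worried": -0.5, "empty": -0.5,
}
FIRST_PERSON_WORDS = ("i", "we", "us", "me", "my", "our", "mine", "myself")
FILLER_WORDS = ("uh", "um", "mm", "hmm", "er")
NEUTRAL_NOUNS = ("day", "work", "thing", "place", "family", "job", "time",
                 "people", "home", "school")
NEUTRAL_VERBS = ("go", "think", "know", "want", "see", "make", "take",
                 "talk", "stay", "sleep")
NEUTRAL_ADJECTIVES = ("big", "small", "old", "new", "long", "busy")
NEUTRAL_ADVERBS = ("really", "very", "quite", "often", "sometimes", "usually")

DEFAULT_SENTIMENT_LEXICON: dict[str, float] = {**POSITIVE_WORDS, **NEGATIVE_WORDS}

#: Word → POS role over the closed vocabulary (sentiment words behave as
#: adjectives; pronouns and fillers are "other").
DEFAULT_POS_LEXICON: dict[str, str] = {
    **{w: "noun" for w in NEUTRAL_NOUNS},
    **{w: "verb" for w in NEUTRAL_VERBS},
    **{w: "adjective" for w in NEUTRAL_ADJECTIVES},
    **{w: "adjective" for w in DEFAULT_SENTIMENT_LEXICON},
    **{w: "adverb" for w in NEUTRAL_ADVERBS},
}

#: Canonical question pool: nine questions attested in published
#: top-feature tables for this corpus style, padded with ten synthetic
#: interview questions to reach the 19 answer-sentiment slots.
DEFAULT_QUESTION_POOL: tuple[str, ...] = (
    "what's your dream job",
    "do you consider yourself an introvert",
    "how are you at controlling your temper",
    "when was the last time you argued with someone and what was it about",
    "what do you do to relax",
    "how close are you to your family",
    "is there anything you regret",
    "what's one of your most memorable experiences",
    "when was the last time you felt really happy",
    # synthetic placeholders
    "how have you been feeling lately",
    "what are you most proud of",
    "how easy is it for you to get a good night's sleep",
    "who's someone that's been a positive influence in your life",
    "what would you say are some of your best qualities",
    "how often do you go out and socialize",
    "what's something you wish you could change about yourself",
    "tell me about the last time you traveled somewhere",
    "what do you enjoy doing in your free time",
    "how do you like your current living situation",
)

GLOBAL_FEATURES: tuple[str, ...] = (
    "avg_sentiment",
    "avg_response_time",
    "speech_speed",
    "avg_unique_frequency",
    "avg_sw_frequency",
    "avg_characters",
    "avg_nouns",
    "avg_verbs",
    "adj_freq",
    "avg_adv",
    "fp_avg",
)


class DictTagger:
    """Deterministic dictionary POS tagger: word → role, unknown → other."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping = dict(mapping)

    def __call__(self, token: str) -> str:
        return self.mapping.get(token, "other")


@dataclass(frozen=True)
class FeatureSpec:
    """Everything :func:`extract_features` needs, with injectable engines."""

    question_pool: tuple[str, ...] = DEFAULT_QUESTION_POOL
    filler_words: frozenset[str] = frozenset(FILLER_WORDS)
    fp_words: frozenset[str] = frozenset(FIRST_PERSON_WORDS)
    lexicon: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SENTIMENT_LEXICON))
    tagger: Callable[[str], str] = field(
        default_factory=lambda: DictTagger(DEFAULT_POS_LEXICON))
    #: optional external scorer(text) -> polarity in [-1, 1]; None uses the
    #: lexicon-mean scorer
    sentiment_scorer: Callable[[str], float] | None = None
    #: score the whole interview as one text (default) or average
    #: per-comment scores
    whole_interview_sentiment: bool = True
    cleaning_rules: CleaningRules = DEFAULT_RULES

    def __post_init__(self) -> None:
        names = self.feature_names
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.question_pool + GLOBAL_FEATURES

    def score(self, cleaned_text: str) -> float:
        if self.sentiment_scorer is not None:
            return float(self.sentiment_scorer(cleaned_text))
        return sentiment_score(cleaned_text, self.lexicon)


DEFAULT_SPEC = FeatureSpec()


@dataclass(frozen=True)
class FeatureVector:
    session_id: str
    values: dict[str, float]


# --------------------------------------------------------------------------
# Elementary scorers
# --------------------------------------------------------------------------

def sentiment_score(text: str, lexicon: Mapping[str, float]) -> float:
    """Mean lexicon polarity over tokens with entries; 0 if none match."""
    matched = [lexicon[t] for t in tokenize(text) if t in lexicon]
    return float(sum(matched) / len(matched)) if matched else 0.0


def match_question(
    bot_text: str,
    question_pool: tuple[str, ...],
    rules: CleaningRules = DEFAULT_RULES,
) -> str | None:
    """First pool question whose cleaned form is contained in the bot turn."""
    cleaned = clean_utterance(bot_text, rules)
    matches = [q for q in question_pool if clean_utterance(q, rules) in cleaned]
    if len(matches) > 1:
        logger.info("bot turn matches %d pool questions; keeping %r",
                    len(matches), matches[0])
    return matches[0] if matches else None


# --------------------------------------------------------------------------
# Session-level helpers
# --------------------------------------------------------------------------

def _comments(session: Session, rules: CleaningRules) -> list[list[str]]:
    """Cleaned token lists of the participant turns, in time order."""
    return [tokenize(clean_utterance(t.text, rules))
            for t in session.turns if t.speaker == PARTICIPANT]


def answer_sentiment_features(
    session: Session, spec: FeatureSpec = DEFAULT_SPEC
) -> dict[str, float]:
    """Sentiment of the answer to each pool question; absent question → 0.

    The answer span is every participant turn between the bot turn that
    asked the question and the next bot turn.  Only the first occurrence of
    a question counts; a question asked but never answered also scores 0.
    """
    rules = spec.cleaning_rules
    answers: dict[str, list[str]] = {}
    current: str | None = None
    for turn in session.turns:
        if turn.speaker == BOT:
            q = match_question(turn.text, spec.question_pool, rules)
            current = q if (q is not None and q not in answers) else None
            if current is not None:
                answers[current] = []
        elif current is not None:
            answers[current].append(clean_utterance(turn.text, rules))
    out: dict[str, float] = {}
    for q in spec.question_pool:
        text = " ".join(answers.get(q, []))
        if not text:
            if q in answers:
                logger.info("session %s: question %r drew no answer",
                            session.session_id, q)
            out[q] = 0.0
        else:
            out[q] = spec.score(text)
    return out


def avg_sentiment(session: Session, spec: FeatureSpec = DEFAULT_SPEC) -> float:
    """Polarity of all participant speech in the session."""
    comments = _comments(session, spec.cleaning_rules)
    if not comments:
        raise ValueError(f"session {session.session_id} has no participant turns")
    if spec.whole_interview_sentiment:
        return spec.score(" ".join(" ".join(c) for c in comments))
    scores = [spec.score(" ".join(c)) for c in comments if c]
    return float(sum(scores) / len(scores)) if scores else 0.0


def avg_response_time(session: Session) -> float:
    """Mean gap (s) between a bot turn and the participant turn right after.

    Negative gaps (overlapping speech) clamp to 0.  Sessions with no
    bot→participant adjacency score 0.
    """
    gaps: list[float] = []
    for prev, cur in zip(session.turns, session.turns[1:]):
        if prev.speaker == BOT and cur.speaker == PARTICIPANT:
            gaps.append(max(0.0, cur.start_time - prev.stop_time))
    if not gaps:
        logger.info("session %s: no bot→participant adjacency", session.session_id)
        return 0.0
    return float(sum(gaps) / len(gaps))


def speech_speed(session: Session, rules: CleaningRules = DEFAULT_RULES) -> float:
    """Unweighted mean of per-comment words/second.

    Zero-duration or empty (after cleaning) comments are excluded.
    """
    rates: list[float] = []
    for t in session.turns:
        if t.speaker != PARTICIPANT:
            continue
        dur = t.stop_time - t.start_time
        n = len(tokenize(clean_utterance(t.text, rules)))
        if dur <= 0.0 or n == 0:
            if dur <= 0.0 and n:
                logger.info("session %s: zero-duration comment skipped",
                            session.session_id)
            continue
        rates.append(n / dur)
    if not rates:
        return 0.0
    return float(sum(rates) / len(rates))


def per_comment_ratio(
    session: Session,
    numerator_predicate: Callable[[str], bool],
    rules: CleaningRules = DEFAULT_RULES,
) -> float:
    """Mean over non-empty comments of (tokens satisfying predicate)/(tokens)."""
    ratios = [sum(map(numerator_predicate, c)) / len(c)
              for c in _comments(session, rules) if c]
    return float(sum(ratios) / len(ratios)) if ratios else 0.0


def avg_unique_frequency(session: Session,
                         rules: CleaningRules = DEFAULT_RULES) -> float:
    """Mean per-comment fraction of distinct words."""
    ratios = [len(set(c)) / len(c) for c in _comments(session, rules) if c]
    return float(sum(ratios) / len(ratios)) if ratios else 0.0


def avg_sw_frequency(session: Session, filler_words: frozenset[str],
                     rules: CleaningRules = DEFAULT_RULES) -> float:
    """Mean per-comment fraction of filler (non-expressive) words."""
    return per_comment_ratio(session, lambda t: t in filler_words, rules)


def avg_characters(session: Session,
                   rules: CleaningRules = DEFAULT_RULES) -> float:
    """Mean per-comment characters-per-word (whitespace not counted)."""
    ratios = [sum(len(t) for t in c) / len(c)
              for c in _comments(session, rules) if c]
    return float(sum(ratios) / len(ratios)) if ratios else 0.0


def pos_frequencies(session: Session, tagger: Callable[[str], str],
                    rules: CleaningRules = DEFAULT_RULES) -> dict[str, float]:
    """Mean per-comment fractions of nouns, verbs, adjectives, adverbs."""
    roles = {"avg_nouns": "noun", "avg_verbs": "verb",
             "adj_freq": "adjective", "avg_adv": "adverb"}
    return {name: per_comment_ratio(session, lambda t, r=role: tagger(t) == r, rules)
            for name, role in roles.items()}


def fp_avg(session: Session, fp_words: frozenset[str],
           rules: CleaningRules = DEFAULT_RULES) -> float:
    """Mean per-comment fraction of first-person words."""
    return per_comment_ratio(session, lambda t: t in fp_words, rules)


# --------------------------------------------------------------------------
# Full vector and corpus matrix
# --------------------------------------------------------------------------

def extract_features(session: Session,
                     spec: FeatureSpec = DEFAULT_SPEC) -> FeatureVector:
    """All 30 features for one session; a failing sub-computation logs a
    warning and contributes 0 rather than aborting a corpus run."""
    rules = spec.cleaning_rules
    values: dict[str, float] = {}

    def safe(name: str, fn: Callable[[], float]) -> None:
        try:
            values[name] = float(fn())
        except Exception as exc:  # degrade, never abort a corpus run
            logger.warning("session %s: feature %r failed (%s); set to 0",
                           session.session_id, name, exc)
            values[name] = 0.0

    values.update(answer_sentiment_features(session, spec))
    safe("avg_sentiment", lambda: avg_sentiment(session, spec))
    safe("avg_response_time", lambda: avg_response_time(session))
    safe("speech_speed", lambda: speech_speed(session, rules))
    safe("avg_unique_frequency", lambda: avg_unique_frequency(session, rules))
    safe("avg_sw_frequency",
         lambda: avg_sw_frequency(session, spec.filler_words, rules))
    safe("avg_characters", lambda: avg_characters(session, rules))
    for name, val in pos_frequencies(session, spec.tagger, rules).items():
        values[name] = val
    safe("fp_avg", lambda: fp_avg(session, spec.fp_words, rules))
    return FeatureVector(session_id=session.session_id, values=values)


def extract_corpus(
    sessions: list[Session],
    labels: list[LabelRecord] | None = None,
    spec: FeatureSpec = DEFAULT_SPEC,
) -> pd.DataFrame:
    """Feature matrix: one row per session, 30 named columns, optionally
    joined with the label table (PHQ8_Binary / PHQ8_Score / Gender)."""
    rows = [extract_features(s, spec).values for s in sessions]
    df = pd.DataFrame(rows, index=pd.Index(
        [s.session_id for s in sessions], name="session_id"))
    df = df[list(spec.feature_names)]
    if labels is not None:
        lab = pd.DataFrame(
            {"PHQ8_Binary": [r.phq8_binary for r in labels],
             "PHQ8_Score": [r.phq8_score for r in labels],
             "Gender": [r.gender for r in labels]},
            index=pd.Index([r.participant_id for r in labels],
                           name="session_id"))
        df = df.join(lab, how="left")
    return df


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    # %.17g guarantees the parsed floats equal the in-memory ones
    df.to_csv(path, float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="session_id",
                       float_precision="round_trip").rename(index=str)
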