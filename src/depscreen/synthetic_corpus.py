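"""Synthetic wizard-of-oz interview corpus with known statistical structure.

The real screening corpus this pipeline targets is access-restricted, so
every downstream stage is exercised on generated sessions that emulate its
*shape*: tab-separated timed turns between a virtual interviewer ("Ellie")
and a participant, a PHQ-8 label table with a 56/188 depressed/total
imbalance, bot questions drawn from a canonical pool where no question is
guaranteed to appear in every session, bracketed annotation markers embedded
in utterances, and a few structurally broken sessions that lack bot turns.

Utterance text is assembled from a small closed vocabulary partitioned into
sentiment-bearing, first-person, filler and neutral words, with
class-conditional sampling rates, so every downstream feature is
analytically checkable.  Depressed participants differ from controls by
configurable effect sizes on four channels:

* speech speed (words/second; default −0.4, i.e. slower speech),
* response latency to bot questions (seconds; default +1.0),
* negative sentiment-word rate (default +0.08),
* first-person word rate (default +0.06).

Per-subject parameters are drawn around class means with configurable
dispersions, so a zero effect size yields genuinely exchangeable classes.
Participant turn durations are word count / subject speech rate and
bot→participant gaps are log-normal with the subject's mean latency, so
speech_speed and avg_response_time are recoverable by construction.

Randomness: one global stream keyed by the seed drives class/invalid
assignment; each session uses an independent substream derived from the
session index, so identical configs give byte-identical corpora.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import BOT, PARTICIPANT, LabelRecord, Session, Turn
from .feature_extraction import (
    DEFAULT_QUESTION_POOL,
    FILLER_WORDS,
    FIRST_PERSON_WORDS,
    NEGATIVE_WORDS,
    NEUTRAL_ADJECTIVES,
    NEUTRAL_ADVERBS,
    NEUTRAL_NOUNS,
    NEUTRAL_VERBS,
    POSITIVE_WORDS,
)

__all__ = [
    "EffectSizes",
    "NoiseScales",
    "GenConfig",
    "SessionPlan",
    "CorpusBundle",
    "ConfigError",
    "generate_corpus",
    "write_corpus",
]

# Class-independent baselines of the timing / lexical model.
BASE_SPEECH_RATE = 2.0   # words/second, typical conversational rate
BASE_LATENCY = 1.0       # seconds between bot question and reply
BASE_NEG_RATE = 0.05     # per-token probability of a negative word
BASE_POS_RATE = 0.06     # per-token probability of a positive word
BASE_FP_RATE = 0.10      # per-token probability of a first-person word
FILLER_RATE = 0.08       # per-token probability of a filler word
MEAN_ANSWER_WORDS = 11   # Poisson mean of answer length (+1 word minimum)
BOT_SPEECH_RATE = 3.0    # bot words/second (timing only)
LATENCY_SIGMA = 0.35     # log-normal shape of response gaps

MARKERS = ("[laughter]", "[sigh]", "<sync>", "(clears throat)")

GREETING = "hi i'm ellie thanks for coming in today"
GREETING_REPLY_WORDS = 6
CLOSING = "okay that is everything i wanted to ask thanks for your time"

# neutral-category weights: nouns, verbs, adjectives, adverbs
_NEUTRAL_WEIGHTS = (0.4, 0.3, 0.15, 0.15)
_NEUTRAL_LISTS = (NEUTRAL_NOUNS, NEUTRAL_VERBS, NEUTRAL_ADJECTIVES,
                  NEUTRAL_ADVERBS)
_POSITIVE = tuple(POSITIVE_WORDS)
_NEGATIVE = tuple(NEGATIVE_WORDS)


class ConfigError(ValueError):
    """Raised when a GenConfig violates its invariants."""


@dataclass(frozen=True)
class EffectSizes:
    """Class-conditional shifts (depressed minus control) per channel."""

    speech_speed: float = -0.4   # words/s
    negative_rate: float = 0.08  # per-token probability
    fp_rate: float = 0.06        # per-token probability
    latency: float = 1.0         # seconds

    def scaled(self, c: float) -> "EffectSizes":
        return EffectSizes(self.speech_speed * c, self.negative_rate * c,
                           self.fp_rate * c, self.latency * c)


@dataclass(frozen=True)
class NoiseScales:
    """Between-subject dispersions (SD) of the per-channel parameters."""

    speech_speed: float = 0.2
    negative_rate: float = 0.04
    fp_rate: float = 0.03
    latency: float = 0.5


@dataclass(frozen=True)
class GenConfig:
    n_sessions: int = 188
    n_depressed: int = 56
    question_pool: tuple[str, ...] = DEFAULT_QUESTION_POOL
    question_presence_prob: float = 0.85
    n_invalid_sessions: int = 3
    marker_rate: float = 0.15
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    noise_scales: NoiseScales = field(default_factory=NoiseScales)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if not 0 <= self.n_depressed <= self.n_sessions:
            raise ConfigError("need 0 <= n_depressed <= n_sessions")
        if not 0 <= self.n_invalid_sessions <= self.n_sessions:
            raise ConfigError("need 0 <= n_invalid_sessions <= n_sessions")
        for name in ("question_presence_prob", "marker_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        for name, v in dataclasses.asdict(self.noise_scales).items():
            if v < 0:
                raise ConfigError(f"noise scale {name} must be >= 0, got {v}")
        if not self.question_pool:
            raise ConfigError("question_pool must be non-empty")


@dataclass
class SessionPlan:
    """Per-session ground truth recorded alongside the generated turns."""

    session_id: str
    depressed: bool
    invalid: bool
    speech_rate: float
    latency_mean: float
    negative_rate: float
    fp_rate: float
    questions_asked: tuple[str, ...]
    #: question → cleaned answer tokens (one turn per question)
    answer_tokens: dict[str, list[str]]
    #: cleaned token plan of every participant comment, in order
    comment_tokens: list[list[str]]


@dataclass
class CorpusBundle:
    sessions: list[Session]
    labels: list[LabelRecord]
    ground_truth: GenConfig
    plans: list[SessionPlan]


def _draw_tokens(rng: np.random.Generator, n: int, neg_rate: float,
                 fp_rate: float) -> list[str]:
    """Sample n words: category first, then uniform within category."""
    p_neutral = max(0.0, 1.0 - neg_rate - BASE_POS_RATE - fp_rate - FILLER_RATE)
    probs = np.array([neg_rate, BASE_POS_RATE, fp_rate, FILLER_RATE,
                      *(w * p_neutral for w in _NEUTRAL_WEIGHTS)])
    probs = probs / probs.sum()
    cats = rng.choice(8, size=n, p=probs)
    pools = (_NEGATIVE, _POSITIVE, FIRST_PERSON_WORDS, FILLER_WORDS,
             *_NEUTRAL_LISTS)
    return [pools[c][rng.integers(len(pools[c]))] for c in cats]


def _maybe_mark(rng: np.random.Generator, tokens: list[str],
                marker_rate: float) -> str:
    """Render tokens as an utterance, possibly with one annotation marker."""
    words = list(tokens)
    if words and rng.random() < marker_rate:
        pos = int(rng.integers(len(words) + 1))
        words.insert(pos, MARKERS[int(rng.integers(len(MARKERS)))])
    return " ".join(words)


def _session_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(index,)))


def _generate_session(
    config: GenConfig, index: int, depressed: bool, invalid: bool
) -> tuple[Session, SessionPlan]:
    rng = _session_rng(config.seed, index)
    es, ns = config.effect_sizes, config.noise_scales
    d = 1.0 if depressed else 0.0
    speech_rate = max(0.3, BASE_SPEECH_RATE + d * es.speech_speed
                      + rng.normal(0.0, ns.speech_speed))
    latency = max(0.1, BASE_LATENCY + d * es.latency
                  + rng.normal(0.0, ns.latency))
    neg_rate = float(np.clip(BASE_NEG_RATE + d * es.negative_rate
                             + rng.normal(0.0, ns.negative_rate), 0.0, 0.6))
    fp_rate = float(np.clip(BASE_FP_RATE + d * es.fp_rate
                            + rng.normal(0.0, ns.fp_rate), 0.0, 0.5))

    session_id = str(300 + index)
    asked = tuple(q for q in config.question_pool
                  if rng.random() < config.question_presence_prob)

    turns: list[Turn] = []
    comment_tokens: list[list[str]] = []
    answer_tokens: dict[str, list[str]] = {}
    t = 0.0
    mu = math.log(latency) - LATENCY_SIGMA ** 2 / 2  # log-normal mean = latency

    def participant_turn(tokens: list[str]) -> None:
        nonlocal t
        dur = len(tokens) / speech_rate
        turns.append(Turn(t, t + dur, PARTICIPANT,
                          _maybe_mark(rng, tokens, config.marker_rate)))
        comment_tokens.append(tokens)
        t += dur + 0.3 + rng.exponential(0.3)  # pause before next bot turn

    def bot_turn(text: str) -> None:
        nonlocal t
        dur = len(text.split()) / BOT_SPEECH_RATE
        turns.append(Turn(t, t + dur, BOT,
                          _maybe_mark(rng, text.split(), config.marker_rate)))
        t += dur + rng.lognormal(mu, LATENCY_SIGMA)  # response gap

    if invalid:
        # structurally broken: participant monologue, zero bot turns
        for _ in range(int(rng.integers(3, 7))):
            participant_turn(_draw_tokens(
                rng, 1 + int(rng.poisson(MEAN_ANSWER_WORDS)),
                neg_rate, fp_rate))
    else:
        bot_turn(GREETING)
        participant_turn(_draw_tokens(rng, GREETING_REPLY_WORDS,
                                      neg_rate, fp_rate))
        prefixes = ("so", "okay", "and", "")
        for q in asked:
            prefix = prefixes[int(rng.integers(len(prefixes)))]
            bot_turn(f"{prefix} {q}".strip())
            tokens = _draw_tokens(rng, 1 + int(rng.poisson(MEAN_ANSWER_WORDS)),
                                  neg_rate, fp_rate)
            answer_tokens[q] = tokens
            participant_turn(tokens)
        bot_turn(CLOSING)

    plan = SessionPlan(
        session_id=session_id, depressed=depressed, invalid=invalid,
        speech_rate=speech_rate, latency_mean=latency,
        negative_rate=neg_rate, fp_rate=fp_rate,
        questions_asked=asked if not invalid else (),
        answer_tokens=answer_tokens, comment_tokens=comment_tokens)
    return Session(session_id=session_id, turns=turns), plan


def generate_corpus(config: GenConfig = GenConfig()) -> CorpusBundle:
    """Generate a labelled corpus under the configured study conditions.

    Exactly ``n_depressed`` of the ``n_sessions`` labels are depressed and
    exactly ``n_invalid_sessions`` sessions contain no bot turn.  Identical
    configs (including the seed) produce identical bundles.
    """
    config.validate()
    top = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    depressed_idx = set(top.choice(config.n_sessions,
                                   size=config.n_depressed, replace=False))
    invalid_idx = set(top.choice(config.n_sessions,
                                 size=config.n_invalid_sessions, replace=False))

    sessions: list[Session] = []
    plans: list[SessionPlan] = []
    labels: list[LabelRecord] = []
    for i in range(config.n_sessions):
        depressed = i in depressed_idx
        session, plan = _generate_session(config, i, depressed,
                                          i in invalid_idx)
        sessions.append(session)
        plans.append(plan)
        lab_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i, 1)))
        score = int(lab_rng.integers(11, 25)) if depressed \
            else int(lab_rng.integers(0, 11))
        labels.append(LabelRecord(
            participant_id=session.session_id,
            phq8_binary=int(depressed),
            phq8_score=score,
            gender=int(top.integers(0, 2))))
    return CorpusBundle(sessions=sessions, labels=labels,
                        ground_truth=config, plans=plans)


def write_corpus(bundle: CorpusBundle, directory: str | Path) -> dict:
    """Write the bundle in the on-disk transcript/label dialect.

    One ``<id>_TRANSCRIPT.tsv`` per session (speakers written as "Ellie" /
    "Participant", times as full-precision decimals so re-reading
    round-trips exactly), a ``labels.csv`` table, and a ``manifest.json``
    echoing the generating configuration.  Returns the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    speaker_names = {BOT: "Ellie", PARTICIPANT: "Participant"}
    files: list[str] = []
    for session in bundle.sessions:
        name = f"{session.session_id}_TRANSCRIPT.tsv"
        lines = ["start_time\tstop_time\tspeaker\tvalue"]
        lines += [f"{t.start_time!r}\t{t.stop_time!r}"
                  f"\t{speaker_names[t.speaker]}\t{t.text}"
                  for t in session.turns]
        (directory / name).write_text("\n".join(lines) + "\n")
        files.append(name)

    label_lines = ["Participant_ID,PHQ8_Binary,PHQ8_Score,Gender"]
    label_lines += [f"{r.participant_id},{r.phq8_binary},"
                    f"{r.phq8_score},{r.gender}" for r in bundle.labels]
    (directory / "labels.csv").write_text("\n".join(label_lines) + "\n")

    manifest = {
        "transcripts": files,
        "labels": "labels.csv",
        "config": dataclasses.asdict(bundle.ground_truth),
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
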