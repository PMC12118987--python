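"""Transcript / label I/O, session validation and the train-test split.

Transcripts are tab-separated turn records (``start_time  stop_time  speaker
value``), one file per interview session; depression labels come from a CSV
table keyed by participant id with the PHQ-8 total score, the binary label
derived from it, and gender (carried but never modelled).

Sessions without any interviewer ("bot") turn are structurally broken for
this pipeline — most features hinge on the bot's questions — and are
excluded before splitting, so that a corpus of 188 sessions with 3 broken
ones splits 148/37 at an 80% training fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Turn",
    "Session",
    "LabelRecord",
    "SplitResult",
    "CorpusFormatError",
    "read_transcript",
    "read_labels",
    "validate_session",
    "split_corpus",
    "BOT",
    "PARTICIPANT",
    "DEFAULT_SPEAKER_ALIASES",
]

logger = logging.getLogger(__name__)

BOT = "bot"
PARTICIPANT = "participant"

#: Case-insensitive speaker-name → role map.  "Ellie" is the virtual
#: interviewer's name in the corpus this dialect mirrors.
DEFAULT_SPEAKER_ALIASES: dict[str, str] = {
    "ellie": BOT,
    "bot": BOT,
    "interviewer": BOT,
    "participant": PARTICIPANT,
    "interviewee": PARTICIPANT,
}

TRANSCRIPT_COLUMNS = ["start_time", "stop_time", "speaker", "value"]
LABEL_COLUMNS = ["Participant_ID", "PHQ8_Binary", "PHQ8_Score", "Gender"]


class CorpusFormatError(ValueError):
    """Raised for malformed transcript or label files."""


@dataclass(frozen=True)
class Turn:
    start_time: float
    stop_time: float
    speaker: str  # BOT or PARTICIPANT
    text: str

    def __post_init__(self) -> None:
        if self.stop_time < self.start_time:
            raise ValueError(
                f"stop_time {self.stop_time} precedes start_time {self.start_time}"
            )
        if self.speaker not in (BOT, PARTICIPANT):
            raise ValueError(f"unknown speaker role {self.speaker!r}")


@dataclass
class Session:
    """One interview: a time-ordered list of turns plus its identifier."""

    session_id: str
    turns: list[Turn] = field(default_factory=list)

    def bot_turns(self) -> list[Turn]:
        return [t for t in self.turns if t.speaker == BOT]

    def participant_turns(self) -> list[Turn]:
        return [t for t in self.turns if t.speaker == PARTICIPANT]


@dataclass(frozen=True)
class LabelRecord:
    """PHQ-8 outcome for one participant: 1 = depressed (score > threshold)."""

    participant_id: str
    phq8_binary: int
    phq8_score: int
    gender: int  # carried through, never used by any model


@dataclass(frozen=True)
class SplitResult:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int


def read_transcript(
    path: str | Path,
    speaker_aliases: dict[str, str] | None = None,
    session_id: str | None = None,
) -> Session:
    """Parse one tab-separated transcript file into a :class:`Session`.

    The header must provide ``start_time``, ``stop_time``, ``speaker`` and
    ``value`` columns.  Speaker names are mapped to roles through a
    case-insensitive alias table; turns are sorted by start time (stable, so
    ties keep file order).
    """
    path = Path(path)
    aliases = {k.lower(): v for k, v in (speaker_aliases or DEFAULT_SPEAKER_ALIASES).items()}
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CorpusFormatError(f"{path}: empty transcript file") from None
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing column(s) {missing}")

    turns: list[Turn] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            start = float(row.start_time)
            stop = float(row.stop_time)
        except ValueError:
            raise CorpusFormatError(
                f"{path}:{i}: non-numeric time "
                f"({row.start_time!r}, {row.stop_time!r})"
            ) from None
        role = aliases.get(str(row.speaker).strip().lower())
        if role is None:
            raise CorpusFormatError(f"{path}:{i}: unknown speaker {row.speaker!r}")
        turns.append(Turn(start, stop, role, str(row.value)))
    turns.sort(key=lambda t: t.start_time)  # stable: file order breaks ties
    sid = session_id if session_id is not None else path.stem.split("_")[0]
    return Session(session_id=sid, turns=turns)


def read_labels(
    path: str | Path,
    threshold: int = 10,
    strict: bool = False,
) -> list[LabelRecord]:
    """Read the PHQ-8 label table.

    Enforces unique participant ids and checks the threshold rule
    ``score > threshold  ⇔  binary == 1`` per record; inconsistencies warn by
    default and raise in strict mode.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing column(s) {missing}")
    ids = df["Participant_ID"].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise CorpusFormatError(f"{path}: duplicate participant id(s) {dupes}")

    records: list[LabelRecord] = []
    for row in df.itertuples(index=False):
        rec = LabelRecord(
            participant_id=str(row.Participant_ID),
            phq8_binary=int(row.PHQ8_Binary),
            phq8_score=int(row.PHQ8_Score),
            gender=int(row.Gender),
        )
        expected = int(rec.phq8_score > threshold)
        if rec.phq8_binary != expected:
            msg = (
                f"{path}: participant {rec.participant_id}: PHQ8_Score "
                f"{rec.phq8_score} with PHQ8_Binary {rec.phq8_binary} violates "
                f"'score > {threshold} ⇒ 1'"
            )
            if strict:
                raise CorpusFormatError(msg)
            warnings.warn(msg, stacklevel=2)
        records.append(rec)
    return records


def validate_session(
    session: Session,
    require_participant: bool = False,
    require_any: bool = False,
) -> tuple[bool, list[str]]:
    """Flag structurally broken sessions.

    A session is invalid when it has no bot turns (the default and the rule
    the pipeline relies on); optional switches also require participant
    turns / any turns at all.  Pure function of the turn list.
    """
    reasons: list[str] = []
    n_bot = len(session.bot_turns())
    n_part = len(session.participant_turns())
    if n_bot == 0:
        reasons.append("no bot turns")
    if require_participant and n_part == 0:
        reasons.append("no participant turns")
    if require_any and not session.turns:
        reasons.append("no turns")
    return (not reasons, reasons)


def split_corpus(
    sessions: list[Session],
    labels: list[LabelRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitResult:
    """Seeded uniform train/test split over the retained (valid) sessions.

    Invalid sessions are removed *before* splitting, so 188 sessions with 3
    broken ones yield round(0.8 × 185) = 148 training and 37 test sessions.
    Every retained session must carry a label; both sides of the split must
    be non-empty.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    labelled = {rec.participant_id for rec in labels}
    retained: list[str] = []
    for s in sessions:
        ok, reasons = validate_session(s)
        if not ok:
            logger.info("excluding session %s: %s", s.session_id, "; ".join(reasons))
            continue
        if s.session_id not in labelled:
            raise CorpusFormatError(f"session {s.session_id} has no label record")
        retained.append(s.session_id)

    n = len(retained)
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(
            f"split leaves an empty side: {n_train} train / {n - n_train} test of {n}"
        )
    order = np.random.default_rng(seed).permutation(sorted(retained))
    return SplitResult(
        train_ids=tuple(order[:n_train]),
        test_ids=tuple(order[n_train:]),
        seed=seed,
    )
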