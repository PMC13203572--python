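"""Core domain types for timed, speaker-tagged, language-tagged utterance data.

The data model mirrors how bilingual play sessions are coded: each utterance
has an onset/offset in integer milliseconds and carries zero or more
language segments.  Language ``A`` is the community's English; language ``B``
is the community's other language (French or Spanish).  An utterance with no
identifiable segments is treated as wholly unknown-language speech.

All time intervals are half-open ``[onset, offset)`` so that duration sums
are exact and abutting segments do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Language(str, Enum):
    """A coded language label.  A = community English; B = French/Spanish."""

    A = "A"
    B = "B"
    UNKNOWN = "unknown"


#: The two identifiable languages, in canonical order.
IDENTIFIABLE = (Language.A, Language.B)


class SpeakerRole(str, Enum):
    TARGET_CHILD = "target_child"
    PRIMARY_CAREGIVER = "primary_caregiver"
    OTHER_HOUSEHOLD = "other_household"


class Community(str, Enum):
    FRENCH_ENGLISH = "french_english"
    SPANISH_ENGLISH = "spanish_english"


class SessionType(str, Enum):
    """A = one-on-one with the primary caregiver; B = multi-party."""

    A = "A"
    B = "B"


class UtteranceKind(str, Enum):
    """Language classification of a whole utterance."""

    SINGLE_A = "single_A"
    SINGLE_B = "single_B"
    MIXED = "mixed"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class LanguageSegment:
    """A within-utterance span attributed to a single language."""

    language: Language
    onset: int
    offset: int

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError(
                f"segment offset must exceed onset: [{self.onset}, {self.offset})"
            )

    @property
    def duration(self) -> int:
        return self.offset - self.onset


@dataclass
class Utterance:
    """One continuous stretch of speech by one speaker.

    ``segments`` lists the language-coded spans inside the utterance, ordered
    by onset and non-overlapping.  An empty list means no part of the
    utterance could be attributed to a language.
    """

    utterance_id: str
    speaker_id: str
    speaker_role: SpeakerRole
    onset: int
    offset: int
    segments: list[LanguageSegment] = field(default_factory=list)
    transcript: Optional[str] = None

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError(
                f"utterance {self.utterance_id}: offset must exceed onset "
                f"([{self.onset}, {self.offset}))"
            )

    @property
    def duration(self) -> int:
        return self.offset - self.onset

    def language_ms(self, language: Language) -> int:
        """Total coded milliseconds in ``language`` within this utterance."""
        return sum(s.duration for s in self.segments if s.language == language)

    @property
    def identifiable_ms(self) -> int:
        return self.language_ms(Language.A) + self.language_ms(Language.B)


@dataclass
class SessionRecord:
    """An ordered collection of utterances from one recorded play session."""

    session_id: str
    family_id: str
    community: Community
    session_type: SessionType
    utterances: list[Utterance] = field(default_factory=list)
    roster: dict[str, SpeakerRole] = field(default_factory=dict)
    child_age_months: Optional[float] = None

    @property
    def target_child_id(self) -> str:
        """Speaker id of the unique target child.

        Raises ``ValueError`` if the roster does not contain exactly one
        target child (use :func:`langalign.annotation_io.validate_session`
        to obtain a non-raising report instead).
        """
        children = [
            s for s, r in self.roster.items() if r == SpeakerRole.TARGET_CHILD
        ]
        if len(children) != 1:
            raise ValueError(
                f"session {self.session_id}: expected exactly one target child, "
                f"found {len(children)}"
            )
        return children[0]

    def speaker_utterances(self, speaker_id: str) -> list[Utterance]:
        return [u for u in self.utterances if u.speaker_id == speaker_id]


def relabel_languages(session: SessionRecord) -> SessionRecord:
    """Return a copy of ``session`` with languages A and B swapped everywhere.

    Used by symmetry checks: every alignment statistic must be invariant
    (or sign-symmetric) under this relabeling.
    """
    swap = {Language.A: Language.B, Language.B: Language.A,
            Language.UNKNOWN: Language.UNKNOWN}
    utterances = [
        Utterance(
            utterance_id=u.utterance_id,
            speaker_id=u.speaker_id,
            speaker_role=u.speaker_role,
            onset=u.onset,
            offset=u.offset,
            segments=[
                LanguageSegment(swap[s.language], s.onset, s.offset)
                for s in u.segments
            ],
            transcript=u.transcript,
        )
        for u in session.utterances
    ]
    return SessionRecord(
        session_id=session.session_id,
        family_id=session.family_id,
        community=session.community,
        session_type=session.session_type,
        utterances=utterances,
        roster=dict(session.roster),
        child_age_months=session.child_age_months,
    )
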