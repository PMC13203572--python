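"""Dyadic conversational turn extraction and match/switch coding.

A *turn* is an utterance by one dyad member immediately followed (in the
global utterance order of the session) by an utterance from the other
member.  A turn is a *match* when both utterances are in the same single
identifiable language, a *switch* otherwise.  Mixed-language and
unknown-language utterances cannot be match-coded and are dropped from the
turn series — but they still occupy their position in the sequence, so they
break adjacency between the utterances around them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .core import Language, SessionRecord, SpeakerRole, Utterance
from .language_profiles import single_language


class Direction(str, Enum):
    CHILD_RESPONDS = "child_responds"
    PARTNER_RESPONDS = "partner_responds"
    POOLED = "pooled"


@dataclass(frozen=True)
class Turn:
    prev_utterance_id: str
    response_utterance_id: str
    prev_speaker_id: str
    response_speaker_id: str
    prev_language: Language
    response_language: Language
    gap_ms: int

    @property
    def match(self) -> bool:
        return self.prev_language == self.response_language


@dataclass
class TurnSeries:
    """Ordered match-codable turns for one dyad and direction in a session."""

    session_id: str
    dyad: tuple[str, str]
    direction: Direction
    turns: list[Turn] = field(default_factory=list)

    @property
    def n_turns(self) -> int:
        return len(self.turns)

    @property
    def n_match(self) -> int:
        return sum(t.match for t in self.turns)

    def prev_languages(self) -> list[Language]:
        return [t.prev_language for t in self.turns]

    def response_languages(self) -> list[Language]:
        return [t.response_language for t in self.turns]


@dataclass(frozen=True)
class TurnSummary:
    n_turns: int
    n_match: int
    match_rate: Optional[float]
    prev_counts: dict
    response_counts: dict


def order_utterances(session: SessionRecord) -> list[Utterance]:
    """Total deterministic order: onset, then offset, speaker, utterance id."""
    return sorted(
        session.utterances,
        key=lambda u: (u.onset, u.offset, u.speaker_id, u.utterance_id),
    )


def _resolve_responder(
    session: SessionRecord, dyad: tuple[str, str], direction: Direction
) -> Optional[str]:
    """Which dyad member must be the responder, or None for pooled."""
    if direction == Direction.POOLED:
        return None
    child_members = [
        s for s in dyad if session.roster.get(s) == SpeakerRole.TARGET_CHILD
    ]
    if len(child_members) != 1:
        raise ValueError(
            f"directional extraction needs exactly one target child in the dyad "
            f"{dyad}; found {len(child_members)}"
        )
    child = child_members[0]
    partner = dyad[0] if dyad[1] == child else dyad[1]
    return child if direction == Direction.CHILD_RESPONDS else partner


def extract_turns(
    session: SessionRecord,
    dyad: tuple[str, str],
    direction: Direction = Direction.POOLED,
    max_gap_ms: Optional[int] = None,
    skip_other_speakers: bool = False,
    allow_chaining: bool = True,
) -> TurnSeries:
    """Extract the match-codable turn series for one dyad.

    Adjacency is strict by default: an utterance by any third speaker between
    two dyad utterances cancels the candidate turn (``skip_other_speakers``
    relaxes this for sensitivity analyses).  ``allow_chaining`` controls
    whether a response may serve as the previous utterance of the next turn;
    chaining is on by default, matching the natural adjacent-pair reading.
    """
    for member in dyad:
        if member not in session.roster:
            raise KeyError(f"dyad member {member!r} not in session roster")
    if dyad[0] == dyad[1]:
        raise ValueError("a dyad needs two distinct speakers")
    responder = _resolve_responder(session, dyad, direction)

    ordered = order_utterances(session)
    if skip_other_speakers:
        ordered = [u for u in ordered if u.speaker_id in dyad]

    series = TurnSeries(session_id=session.session_id, dyad=dyad, direction=direction)
    last_response_id: Optional[str] = None
    for prev_u, resp_u in zip(ordered, ordered[1:]):
        if {prev_u.speaker_id, resp_u.speaker_id} != set(dyad):
            continue
        if responder is not None and resp_u.speaker_id != responder:
            continue
        if not allow_chaining and prev_u.utterance_id == last_response_id:
            continue
        prev_lang = single_language(prev_u)
        resp_lang = single_language(resp_u)
        if prev_lang is None or resp_lang is None:
            continue  # mixed or unknown utterances are not match-codable
        gap = resp_u.onset - prev_u.offset
        if max_gap_ms is not None and gap > max_gap_ms:
            continue
        series.turns.append(
            Turn(
                prev_utterance_id=prev_u.utterance_id,
                response_utterance_id=resp_u.utterance_id,
                prev_speaker_id=prev_u.speaker_id,
                response_speaker_id=resp_u.speaker_id,
                prev_language=prev_lang,
                response_language=resp_lang,
                gap_ms=gap,
            )
        )
        last_response_id = resp_u.utterance_id
    return series


def summarize_turns(series: TurnSeries) -> TurnSummary:
    """Descriptive summary: counts, observed match rate, language marginals."""
    n = series.n_turns
    prev_counts = {lang.value: 0 for lang in (Language.A, Language.B)}
    resp_counts = {lang.value: 0 for lang in (Language.A, Language.B)}
    for t in series.turns:
        prev_counts[t.prev_language.value] += 1
        resp_counts[t.response_language.value] += 1
    return TurnSummary(
        n_turns=n,
        n_match=series.n_match,
        match_rate=series.n_match / n if n else None,
        prev_counts=prev_counts,
        response_counts=resp_counts,
    )


def caregiver_child_dyad(session: SessionRecord) -> tuple[str, str]:
    """The (primary caregiver, target child) dyad of a session."""
    child = session.target_child_id
    caregivers = [
        s
        for s, r in session.roster.items()
        if r == SpeakerRole.PRIMARY_CAREGIVER
    ]
    if len(caregivers) != 1:
        raise ValueError(
            f"session {session.session_id}: expected exactly one primary "
            f"caregiver, found {len(caregivers)}"
        )
    return caregivers[0], child


def turns_table(series_list: Sequence[TurnSeries]) -> pd.DataFrame:
    """Model-ready export: one row per turn, for external mixed-model fits."""
    rows = []
    for series in series_list:
        for t in series.turns:
            rows.append(
                {
                    "session_id": series.session_id,
                    "dyad": "|".join(series.dyad),
                    "direction": series.direction.value,
                    "prev_utterance_id": t.prev_utterance_id,
                    "response_utterance_id": t.response_utterance_id,
                    "prev_speaker_id": t.prev_speaker_id,
                    "response_speaker_id": t.response_speaker_id,
                    "prev_language": t.prev_language.value,
                    "response_language": t.response_language.value,
                    "match": int(t.match),
                    "gap_ms": t.gap_ms,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "session_id",
            "dyad",
            "direction",
            "prev_utterance_id",
            "response_utterance_id",
            "prev_speaker_id",
            "response_speaker_id",
            "prev_language",
            "response_language",
            "match",
            "gap_ms",
        ],
    )
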