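"""Shared fixtures: hand-built sessions and turn-series factories."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from langalign.core import (
    Community,
    Language,
    LanguageSegment,
    SessionRecord,
    SessionType,
    SpeakerRole,
    Utterance,
)
from langalign.turn_extraction import Direction, Turn, TurnSeries


def make_utterance(
    utterance_id: str,
    speaker_id: str,
    role: SpeakerRole,
    onset: int,
    offset: int,
    language=None,
    segments=None,
) -> Utterance:
    """Build an utterance; ``language`` fills the whole span with one segment."""
    if segments is None:
        if language is None:
            segments = []
        elif language == "mixed":
            mid = (onset + offset) // 2
            segments = [
                LanguageSegment(Language.A, onset, mid),
                LanguageSegment(Language.B, mid, offset),
            ]
        else:
            segments = [LanguageSegment(language, onset, offset)]
    return Utterance(
        utterance_id=utterance_id,
        speaker_id=speaker_id,
        speaker_role=role,
        onset=onset,
        offset=offset,
        segments=segments,
    )


def dyad_session(language_sequence, session_id="s1", session_type=SessionType.A):
    """Alternating caregiver/child session from a sequence of language labels.

    ``language_sequence`` items: Language.A, Language.B, "mixed", or None
    (unknown).  Caregiver speaks at even indices, child at odd indices.
    """
    utterances = []
    t = 0
    for i, lang in enumerate(language_sequence):
        speaker, role = (
            ("cg", SpeakerRole.PRIMARY_CAREGIVER)
            if i % 2 == 0
            else ("ch", SpeakerRole.TARGET_CHILD)
        )
        utterances.append(
            make_utterance(f"u{i:03d}", speaker, role, t, t + 1000, language=lang)
        )
        t += 1500
    return SessionRecord(
        session_id=session_id,
        family_id=session_id,
        community=Community.FRENCH_ENGLISH,
        session_type=session_type,
        utterances=utterances,
        roster={"cg": SpeakerRole.PRIMARY_CAREGIVER, "ch": SpeakerRole.TARGET_CHILD},
    )


def series_from_langs(
    prev_langs, resp_langs, session_id="s1", direction=Direction.CHILD_RESPONDS
) -> TurnSeries:
    """Construct a turn series directly from language label lists."""
    assert len(prev_langs) == len(resp_langs)
    turns = [
        Turn(
            prev_utterance_id=f"p{i}",
            response_utterance_id=f"r{i}",
            prev_speaker_id="cg",
            response_speaker_id="ch",
            prev_language=p,
            response_language=r,
            gap_ms=100,
        )
        for i, (p, r) in enumerate(zip(prev_langs, resp_langs))
    ]
    return TurnSeries(
        session_id=session_id, dyad=("cg", "ch"), direction=direction, turns=turns
    )


def random_series(rng: np.random.Generator, n_turns: int) -> TurnSeries:
    """Random turn series with base rates drawn uniformly from (0.2, 0.8)."""
    p_prev, p_resp = rng.uniform(0.2, 0.8, size=2)
    prev = [Language.A if rng.random() < p_prev else Language.B for _ in range(n_turns)]
    resp = [Language.A if rng.random() < p_resp else Language.B for _ in range(n_turns)]
    return series_from_langs(prev, resp)


def exact_match_rate_distribution(series: TurnSeries) -> dict[float, float]:
    """Brute-force null: enumerate all response permutations (oracle).

    Only feasible for small series; used to check the Monte Carlo null.
    """
    prev = [t.prev_language for t in series.turns]
    resp = [t.response_language for t in series.turns]
    n = len(prev)
    counts: dict[float, int] = {}
    total = 0
    for perm in itertools.permutations(resp):
        rate = sum(p == r for p, r in zip(prev, perm)) / n
        counts[rate] = counts.get(rate, 0) + 1
        total += 1
    return {rate: c / total for rate, c in counts.items()}


@pytest.fixture
def simple_session():
    """Caregiver A, child A, caregiver B, child A: one match, one switch."""
    return dyad_session([Language.A, Language.A, Language.B, Language.A])
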