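"""Per-speaker language-use profiles and cohort summary tables.

Language proportions are **time-weighted**: the time a speaker spent in each
language divided by their total identifiable speech time.  The identifiable
proportion uses the speaker's total speech time (identifiable + unknown) as
its denominator.  Undefined statistics (e.g. the language split of a speaker
whose speech was never identifiable) are reported as nulls, never as zero —
a silent or unintelligible speaker is not a monolingual one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    Language,
    SessionRecord,
    SpeakerRole,
    Utterance,
    UtteranceKind,
)


def classify_utterance(utterance: Utterance) -> UtteranceKind:
    """Classify an utterance by its identifiable language content.

    ``SINGLE_A``/``SINGLE_B`` when all identifiable time is in one language,
    ``MIXED`` when both languages occur, ``UNKNOWN`` when no segment time is
    identifiable.
    """
    ms_a = utterance.language_ms(Language.A)
    ms_b = utterance.language_ms(Language.B)
    if ms_a > 0 and ms_b > 0:
        return UtteranceKind.MIXED
    if ms_a > 0:
        return UtteranceKind.SINGLE_A
    if ms_b > 0:
        return UtteranceKind.SINGLE_B
    return UtteranceKind.UNKNOWN


def single_language(utterance: Utterance) -> Optional[Language]:
    """The utterance's single identifiable language, or None if mixed/unknown."""
    kind = classify_utterance(utterance)
    if kind == UtteranceKind.SINGLE_A:
        return Language.A
    if kind == UtteranceKind.SINGLE_B:
        return Language.B
    return None


@dataclass(frozen=True)
class SpeakerProfile:
    """Time-weighted language use of one speaker in one session."""

    speaker_id: str
    speaker_role: SpeakerRole
    total_speech_ms: int
    ms_a: int
    ms_b: int
    ms_unknown: int

    @property
    def identifiable_ms(self) -> int:
        return self.ms_a + self.ms_b

    @property
    def identifiable_prop(self) -> Optional[float]:
        """Identifiable time / total time; None for a silent speaker."""
        if self.total_speech_ms == 0:
            return None
        return self.identifiable_ms / self.total_speech_ms

    def prop_language(self, language: Language) -> Optional[float]:
        """Share of identifiable time in ``language``; None if undefined."""
        if self.identifiable_ms == 0:
            return None
        ms = {Language.A: self.ms_a, Language.B: self.ms_b}[language]
        return ms / self.identifiable_ms


def speaker_profile(session: SessionRecord, speaker_id: str) -> SpeakerProfile:
    """Compute one speaker's profile from their utterances in a session.

    Unknown time is the utterance time not covered by identifiable segments,
    so per-language milliseconds always sum to total speech milliseconds.
    """
    if speaker_id not in session.roster:
        raise KeyError(f"speaker {speaker_id!r} not in session roster")
    ms_a = ms_b = total = 0
    for utt in session.speaker_utterances(speaker_id):
        total += utt.duration
        ms_a += utt.language_ms(Language.A)
        ms_b += utt.language_ms(Language.B)
    return SpeakerProfile(
        speaker_id=speaker_id,
        speaker_role=session.roster[speaker_id],
        total_speech_ms=total,
        ms_a=ms_a,
        ms_b=ms_b,
        ms_unknown=total - ms_a - ms_b,
    )


def profile_table(sessions: Sequence[SessionRecord]) -> pd.DataFrame:
    """One row per (session, speaker): proportions and raw milliseconds.

    ``other_household`` speakers are averaged *within* each session into a
    single row (so multi-member households contribute one value, matching
    how family-level summaries weight speakers), in addition to their
    individual rows which carry ``pooled=False``.
    """
    rows = []
    for session in sessions:
        others = []
        for speaker_id in sorted(session.roster):
            prof = speaker_profile(session, speaker_id)
            row = {
                "session_id": session.session_id,
                "family_id": session.family_id,
                "community": session.community.value,
                "session_type": session.session_type.value,
                "speaker_id": speaker_id,
                "speaker_role": prof.speaker_role.value,
                "pooled": False,
                "total_speech_ms": prof.total_speech_ms,
                "ms_a": prof.ms_a,
                "ms_b": prof.ms_b,
                "ms_unknown": prof.ms_unknown,
                "prop_a": prof.prop_language(Language.A),
                "prop_b": prof.prop_language(Language.B),
                "identifiable_prop": prof.identifiable_prop,
            }
            rows.append(row)
            if prof.speaker_role == SpeakerRole.OTHER_HOUSEHOLD:
                others.append(row)
        if others:
            props = [r["prop_a"] for r in others if r["prop_a"] is not None]
            idents = [
                r["identifiable_prop"]
                for r in others
                if r["identifiable_prop"] is not None
            ]
            rows.append(
                {
                    "session_id": session.session_id,
                    "family_id": session.family_id,
                    "community": session.community.value,
                    "session_type": session.session_type.value,
                    "speaker_id": "__others_mean__",
                    "speaker_role": SpeakerRole.OTHER_HOUSEHOLD.value,
                    "pooled": True,
                    "total_speech_ms": sum(r["total_speech_ms"] for r in others),
                    "ms_a": sum(r["ms_a"] for r in others),
                    "ms_b": sum(r["ms_b"] for r in others),
                    "ms_unknown": sum(r["ms_unknown"] for r in others),
                    "prop_a": float(np.mean(props)) if props else None,
                    "prop_b": 1.0 - float(np.mean(props)) if props else None,
                    "identifiable_prop": float(np.mean(idents)) if idents else None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "session_id",
            "family_id",
            "community",
            "session_type",
            "speaker_id",
            "speaker_role",
            "pooled",
            "total_speech_ms",
            "ms_a",
            "ms_b",
            "ms_unknown",
            "prop_a",
            "prop_b",
            "identifiable_prop",
        ],
    )


def usage_summary(
    sessions: Sequence[SessionRecord],
    group_by: Sequence[str] = ("community", "session_type", "speaker_role"),
) -> pd.DataFrame:
    """Grouped summary of language-A use and identifiability.

    Per group: count, mean/SD/min/max of each speaker's language-A share,
    and mean/SD/min/max of their identifiable-speech proportion.  Families
    are weighted equally (one value per speaker per session); multiple
    other-household members are first averaged within their session.  A
    single-observation group reports SD as null.
    """
    table = profile_table(sessions)
    if table.empty:
        raise ValueError("usage_summary requires at least one session")
    # keep individual rows for child/caregiver, pooled rows for others
    is_other = table["speaker_role"] == SpeakerRole.OTHER_HOUSEHOLD.value
    table = pd.concat(
        [table[~is_other & ~table["pooled"]], table[is_other & table["pooled"]]]
    )

    def _agg(group: pd.DataFrame) -> pd.Series:
        out = {"n": len(group)}
        for col, prefix in (("prop_a", "prop_a"), ("identifiable_prop", "identifiable")):
            vals = group[col].dropna().astype(float)
            out[f"{prefix}_mean"] = vals.mean() if len(vals) else np.nan
            out[f"{prefix}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            out[f"{prefix}_min"] = vals.min() if len(vals) else np.nan
            out[f"{prefix}_max"] = vals.max() if len(vals) else np.nan
        return pd.Series(out)

    grouped = (
        table.groupby(list(group_by), sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    grouped["n"] = grouped["n"].astype(int)
    return grouped
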