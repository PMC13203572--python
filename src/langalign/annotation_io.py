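"""Read, validate and write utterance-level annotation data.

Two on-disk representations are supported:

* a **canonical delimited table** (tab-separated by default, UTF-8) with one
  row per language segment — utterances with no identifiable language carry
  a single row with ``language=unknown`` spanning the utterance;
* **ELAN EAF** files (the XML format the sessions were originally coded in),
  read through a configurable ``tier_map`` because tier naming conventions
  vary between coding schemes.

Round-trip guarantee: ``read_utterance_table(write_utterance_table(s)) == s``
for any valid list of session records.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from lxml import etree

from .core import (
    Community,
    Language,
    LanguageSegment,
    SessionRecord,
    SessionType,
    SpeakerRole,
    Utterance,
)

CANONICAL_COLUMNS = [
    "session_id",
    "family_id",
    "community",
    "session_type",
    "speaker_id",
    "speaker_role",
    "utterance_id",
    "onset_ms",
    "offset_ms",
    "language",
    "seg_onset_ms",
    "seg_offset_ms",
    "transcript",
]


class SchemaError(ValueError):
    """The file header does not match the canonical schema."""


class RowValidationError(ValueError):
    """A data row violates a type invariant; carries the 1-based row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class EafFormatError(ValueError):
    """The EAF document is structurally unusable (e.g. dangling time refs)."""


class TierConfigurationError(ValueError):
    """tier_map references tiers that the EAF document does not contain."""


def _parse_enum(enum_cls, token: str, row_index: int, column: str):
    try:
        return enum_cls(token)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise RowValidationError(
            row_index, f"unknown {column} token {token!r} (expected one of: {valid})"
        )


def read_utterance_table(
    path: Union[str, Path], delimiter: str = "\t"
) -> list[SessionRecord]:
    """Parse a canonical delimited table into session records.

    One row per language segment; rows of the same utterance share the
    utterance-level columns.  Raises :class:`SchemaError` for a missing
    column and :class:`RowValidationError` (with the offending row index)
    for invalid values.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in CANONICAL_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column: {col!r}")
        rows = list(reader)

    sessions: dict[str, SessionRecord] = {}
    utterances: dict[tuple[str, str], Utterance] = {}
    for i, row in enumerate(rows, start=1):
        sid = row["session_id"]
        if sid not in sessions:
            sessions[sid] = SessionRecord(
                session_id=sid,
                family_id=row["family_id"],
                community=_parse_enum(Community, row["community"], i, "community"),
                session_type=_parse_enum(
                    SessionType, row["session_type"], i, "session_type"
                ),
            )
        session = sessions[sid]
        role = _parse_enum(SpeakerRole, row["speaker_role"], i, "speaker_role")
        session.roster.setdefault(row["speaker_id"], role)

        try:
            onset, offset = int(row["onset_ms"]), int(row["offset_ms"])
            seg_onset = int(row["seg_onset_ms"])
            seg_offset = int(row["seg_offset_ms"])
        except ValueError as exc:
            raise RowValidationError(i, f"non-integer time value ({exc})")
        if offset <= onset:
            raise RowValidationError(
                i, f"utterance offset_ms ({offset}) <= onset_ms ({onset})"
            )
        if seg_offset <= seg_onset:
            raise RowValidationError(
                i, f"seg_offset_ms ({seg_offset}) <= seg_onset_ms ({seg_onset})"
            )

        key = (sid, row["utterance_id"])
        if key not in utterances:
            transcript = row["transcript"] or None
            utt = Utterance(
                utterance_id=row["utterance_id"],
                speaker_id=row["speaker_id"],
                speaker_role=role,
                onset=onset,
                offset=offset,
                transcript=transcript,
            )
            utterances[key] = utt
            session.utterances.append(utt)
        language = _parse_enum(Language, row["language"], i, "language")
        # an unknown row spanning the whole utterance encodes "no segments"
        if not (
            language == Language.UNKNOWN
            and seg_onset == onset
            and seg_offset == offset
        ):
            utterances[key].segments.append(
                LanguageSegment(language, seg_onset, seg_offset)
            )

    for session in sessions.values():
        for utt in session.utterances:
            utt.segments.sort(key=lambda s: s.onset)
    return [sessions[sid] for sid in sorted(sessions)]


def write_utterance_table(
    sessions: Iterable[SessionRecord],
    path: Union[str, Path],
    delimiter: str = "\t",
) -> Path:
    """Write session records as the canonical delimited table.

    Rows are emitted in a deterministic order (session_id, utterance onset,
    utterance_id, segment onset), one row per segment; utterances without
    segments get a single ``unknown`` row spanning the utterance.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for session in sorted(sessions, key=lambda s: s.session_id):
            ordered = sorted(
                session.utterances, key=lambda u: (u.onset, u.utterance_id)
            )
            for utt in ordered:
                segments = sorted(utt.segments, key=lambda s: s.onset) or [
                    LanguageSegment(Language.UNKNOWN, utt.onset, utt.offset)
                ]
                for seg in segments:
                    writer.writerow(
                        [
                            session.session_id,
                            session.family_id,
                            session.community.value,
                            session.session_type.value,
                            utt.speaker_id,
                            utt.speaker_role.value,
                            utt.utterance_id,
                            utt.onset,
                            utt.offset,
                            seg.language.value,
                            seg.onset,
                            seg.offset,
                            utt.transcript or "",
                        ]
                    )
    return path


# ---------------------------------------------------------------------------
# EAF (ELAN Annotation Format) ingestion
# ---------------------------------------------------------------------------

#: Default mapping from language-tier annotation values to language codes.
DEFAULT_LANGUAGE_TOKENS = {
    "eng": Language.A,
    "english": Language.A,
    "a": Language.A,
    "fra": Language.B,
    "french": Language.B,
    "spa": Language.B,
    "spanish": Language.B,
    "b": Language.B,
    "unk": Language.UNKNOWN,
    "unknown": Language.UNKNOWN,
}


@dataclass
class SpeakerTierSpec:
    """How one EAF speaker tier maps onto the data model."""

    tier: str
    speaker_id: str
    speaker_role: SpeakerRole
    language_tier: Optional[str] = None


@dataclass
class TierMap:
    """Configuration for reading one EAF file."""

    speakers: list[SpeakerTierSpec]
    language_tokens: dict[str, Language] = field(
        default_factory=lambda: dict(DEFAULT_LANGUAGE_TOKENS)
    )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "TierMap":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = json.load(fh)
        speakers = [
            SpeakerTierSpec(
                tier=s["tier"],
                speaker_id=s["speaker_id"],
                speaker_role=SpeakerRole(s["speaker_role"]),
                language_tier=s.get("language_tier"),
            )
            for s in data["speakers"]
        ]
        tokens = dict(DEFAULT_LANGUAGE_TOKENS)
        for k, v in data.get("language_tokens", {}).items():
            tokens[k.lower()] = Language(v)
        return cls(speakers=speakers, language_tokens=tokens)


def _eaf_alignable_annotations(tier_el, time_values) -> list[tuple[int, int, str]]:
    out = []
    for ann in tier_el.findall("ANNOTATION/ALIGNABLE_ANNOTATION"):
        ref1, ref2 = ann.get("TIME_SLOT_REF1"), ann.get("TIME_SLOT_REF2")
        if ref1 not in time_values or ref2 not in time_values:
            raise EafFormatError(f"unresolvable time slot reference {ref1!r}/{ref2!r}")
        t1, t2 = time_values[ref1], time_values[ref2]
        if t1 is None or t2 is None:
            raise EafFormatError("time slot without TIME_VALUE is not supported")
        value_el = ann.find("ANNOTATION_VALUE")
        out.append((t1, t2, (value_el.text or "") if value_el is not None else ""))
    out.sort()
    return out


def read_eaf(
    path: Union[str, Path],
    tier_map: TierMap,
    session_id: Optional[str] = None,
    family_id: Optional[str] = None,
    community: Community = Community.FRENCH_ENGLISH,
    session_type: SessionType = SessionType.A,
) -> SessionRecord:
    """Read one EAF file into a session record.

    Each annotation on a mapped speaker tier becomes an utterance; alignable
    annotations on the associated language tier become language segments,
    attached to the utterance whose span contains the segment midpoint.
    Utterances with no covering language annotation are left segment-free
    (wholly unknown).
    """
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()

    time_values: dict[str, Optional[int]] = {}
    for slot in root.findall("TIME_ORDER/TIME_SLOT"):
        tv = slot.get("TIME_VALUE")
        time_values[slot.get("TIME_SLOT_ID")] = int(tv) if tv is not None else None

    tiers = {t.get("TIER_ID"): t for t in root.findall("TIER")}
    stem = path.stem
    session = SessionRecord(
        session_id=session_id or stem,
        family_id=family_id or stem,
        community=community,
        session_type=session_type,
    )

    for spec in tier_map.speakers:
        if spec.tier not in tiers:
            raise TierConfigurationError(
                f"speaker tier {spec.tier!r} not present in {path.name}"
            )
        if spec.language_tier is not None and spec.language_tier not in tiers:
            raise TierConfigurationError(
                f"language tier {spec.language_tier!r} not present in {path.name}"
            )
        session.roster[spec.speaker_id] = spec.speaker_role

        spans = _eaf_alignable_annotations(tiers[spec.tier], time_values)
        lang_spans: list[tuple[int, int, str]] = []
        if spec.language_tier is not None:
            lang_spans = _eaf_alignable_annotations(
                tiers[spec.language_tier], time_values
            )

        for n, (t1, t2, text) in enumerate(spans, start=1):
            utt = Utterance(
                utterance_id=f"{spec.speaker_id}-{n:04d}",
                speaker_id=spec.speaker_id,
                speaker_role=spec.speaker_role,
                onset=t1,
                offset=t2,
                transcript=text or None,
            )
            for s1, s2, token in lang_spans:
                mid = (s1 + s2) // 2
                if t1 <= mid < t2:
                    language = tier_map.language_tokens.get(token.strip().lower())
                    if language is None:
                        raise EafFormatError(
                            f"unrecognized language token {token!r} on tier "
                            f"{spec.language_tier!r}"
                        )
                    if language != Language.UNKNOWN:
                        utt.segments.append(
                            LanguageSegment(language, max(s1, t1), min(s2, t2))
                        )
            utt.segments.sort(key=lambda s: s.onset)
            session.utterances.append(utt)

    session.utterances.sort(key=lambda u: (u.onset, u.offset, u.speaker_id))
    return session


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    """One machine-readable validation finding."""

    kind: str
    session_id: str
    detail: str
    utterance_id: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "session_id": self.session_id,
            "utterance_id": self.utterance_id,
            "detail": self.detail,
        }


def validate_session(session: SessionRecord) -> list[Issue]:
    """Check a session against the data-model invariants.

    Never raises on content: every violation becomes an :class:`Issue`.
    An empty list means the record satisfies all invariants.
    """
    issues: list[Issue] = []
    sid = session.session_id

    children = [s for s, r in session.roster.items() if r == SpeakerRole.TARGET_CHILD]
    if len(children) != 1:
        issues.append(
            Issue(
                "target_child_count",
                sid,
                f"expected exactly 1 target child in roster, found {len(children)}",
            )
        )
    if session.session_type == SessionType.A:
        caregivers = [
            s
            for s, r in session.roster.items()
            if r == SpeakerRole.PRIMARY_CAREGIVER
        ]
        if len(caregivers) != 1:
            issues.append(
                Issue(
                    "caregiver_count",
                    sid,
                    "session type A requires exactly one primary caregiver, "
                    f"found {len(caregivers)}",
                )
            )

    for utt in session.utterances:
        if utt.speaker_id not in session.roster:
            issues.append(
                Issue(
                    "unknown_speaker",
                    sid,
                    f"speaker {utt.speaker_id!r} not in roster",
                    utt.utterance_id,
                )
            )
        elif (
            session.session_type == SessionType.A
            and session.roster[utt.speaker_id] == SpeakerRole.OTHER_HOUSEHOLD
        ):
            issues.append(
                Issue(
                    "role_violation",
                    sid,
                    "other-household speech in a one-on-one (type A) session",
                    utt.utterance_id,
                )
            )
        if utt.offset <= utt.onset:
            issues.append(
                Issue(
                    "negative_duration",
                    sid,
                    f"utterance span [{utt.onset}, {utt.offset}) is empty",
                    utt.utterance_id,
                )
            )
        ordered = sorted(utt.segments, key=lambda s: s.onset)
        for a, b in zip(ordered, ordered[1:]):
            if b.onset < a.offset:
                issues.append(
                    Issue(
                        "segment_overlap",
                        sid,
                        f"segments [{a.onset},{a.offset}) and "
                        f"[{b.onset},{b.offset}) overlap",
                        utt.utterance_id,
                    )
                )
        for seg in ordered:
            if seg.onset < utt.onset or seg.offset > utt.offset:
                issues.append(
                    Issue(
                        "segment_outside_utterance",
                        sid,
                        f"segment [{seg.onset},{seg.offset}) outside utterance "
                        f"span [{utt.onset},{utt.offset})",
                        utt.utterance_id,
                    )
                )
    return issues
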