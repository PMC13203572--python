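"""End-to-end orchestration: ingestion -> profiles -> turns -> tests -> reports.

A pipeline run is fully determined by its config and seed: per-session
Monte Carlo seeds are derived from the master seed by session id order, all
tables are sorted deterministically, and the manifest records every file
written together with its row count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .alignment_mc import (
    AlignmentTestResult,
    attrition_report,
    results_table,
    run_alignment_test,
)
from .annotation_io import TierMap, read_eaf, read_utterance_table, validate_session
from .core import SessionRecord, SessionType, SpeakerRole
from .correspondence_stats import (
    UndefinedCorrelationError,
    fisher_z_independent,
    pearson_correlation,
    steiger_dependent_z,
)
from .language_profiles import profile_table, usage_summary
from .turn_extraction import (
    Direction,
    caregiver_child_dyad,
    extract_turns,
    turns_table,
)

logger = logging.getLogger("langalign.pipeline")


@dataclass
class RunConfig:
    out_dir: Union[str, Path]
    input_table: Optional[Union[str, Path]] = None
    eaf_dir: Optional[Union[str, Path]] = None
    tier_map: Optional[Union[str, Path]] = None
    n_iterations: int = 10_000
    seed: int = 0
    dominance_threshold: float = 0.80
    min_turns: int = 30
    max_gap_ms: Optional[int] = None
    formats: tuple[str, ...] = ("tsv", "json")

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.dominance_threshold <= 1:
            raise ValueError("dominance_threshold must lie in (0, 1]")
        if self.min_turns < 0:
            raise ValueError("min_turns must be non-negative")
        for fmt in self.formats:
            if fmt not in ("tsv", "json"):
                raise ValueError(f"unknown report format {fmt!r}")
        if self.input_table is None and self.eaf_dir is None:
            raise ValueError("either input_table or eaf_dir must be given")


def load_sessions(config: RunConfig) -> list[SessionRecord]:
    if config.input_table is not None:
        sessions = read_utterance_table(config.input_table)
    else:
        if config.tier_map is None:
            raise ValueError("eaf_dir input requires a tier_map")
        tier_map = TierMap.from_json(config.tier_map)
        sessions = [
            read_eaf(p, tier_map)
            for p in sorted(Path(config.eaf_dir).glob("*.eaf"))
        ]
    valid = []
    for session in sessions:
        issues = validate_session(session)
        if issues:
            for issue in issues:
                logger.warning(
                    "validation session=%s kind=%s detail=%s",
                    session.session_id,
                    issue.kind,
                    issue.detail,
                )
        else:
            valid.append(session)
    if not valid:
        raise ValueError(
            f"no valid sessions among {len(sessions)} loaded; see warnings"
        )
    return sorted(valid, key=lambda s: s.session_id)


def write_reports(
    frame: pd.DataFrame,
    stem: Path,
    formats: Sequence[str] = ("tsv", "json"),
) -> list[Path]:
    """Write one table in the requested formats with deterministic content."""
    if frame.empty:
        raise ValueError(f"refusing to write empty report {stem.name!r}")
    written = []
    for fmt in formats:
        if fmt == "tsv":
            path = stem.with_suffix(".tsv")
            frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        elif fmt == "json":
            path = stem.with_suffix(".json")
            records = json.loads(frame.to_json(orient="records"))
            path.write_text(
                json.dumps(records, indent=1, sort_keys=True) + "\n",
                encoding="utf-8",
            )
        else:
            raise ValueError(f"unknown report format {fmt!r}")
        written.append(path)
    return written


def _session_seeds(sessions: Sequence[SessionRecord], master_seed: int) -> dict[str, int]:
    streams = np.random.SeedSequence(master_seed).spawn(len(sessions))
    return {
        s.session_id: int(stream.generate_state(1)[0] % (2**31))
        for s, stream in zip(sessions, streams)
    }


def correspondence_tables(
    sessions: Sequence[SessionRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Family-level proportion table and the correlation comparisons on it.

    Input table: one row per (family, session type) with the child's,
    primary caregiver's, and other household members' mean language-A
    proportions.  Tests: child-caregiver Pearson r per community and session
    type; Fisher r-to-z across communities per session type; Steiger Z for
    child-caregiver vs child-others (dependent, sharing the child) per
    community in multi-party sessions.
    """
    profiles = profile_table(sessions)
    is_other = profiles["speaker_role"] == SpeakerRole.OTHER_HOUSEHOLD.value
    keep = profiles[(~is_other & ~profiles["pooled"]) | (is_other & profiles["pooled"])]
    wide = keep.pivot_table(
        index=["community", "session_type", "family_id"],
        columns="speaker_role",
        values="prop_a",
        aggfunc="first",
    ).reset_index()
    wide = wide.rename(
        columns={
            SpeakerRole.TARGET_CHILD.value: "child_prop_a",
            SpeakerRole.PRIMARY_CAREGIVER.value: "caregiver_prop_a",
            SpeakerRole.OTHER_HOUSEHOLD.value: "others_prop_a",
        }
    )
    for col in ("child_prop_a", "caregiver_prop_a", "others_prop_a"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide = wide.sort_values(["community", "session_type", "family_id"]).reset_index(
        drop=True
    )

    results = []

    def _corr(sub: pd.DataFrame, xcol: str, ycol: str):
        sub = sub.dropna(subset=[xcol, ycol])
        if len(sub) < 4:
            return None
        try:
            return pearson_correlation(sub[xcol], sub[ycol])
        except UndefinedCorrelationError:
            return None

    by_group: dict[tuple[str, str], object] = {}
    for (community, stype), sub in wide.groupby(["community", "session_type"]):
        res = _corr(sub, "caregiver_prop_a", "child_prop_a")
        by_group[(community, stype)] = res
        if res is not None:
            results.append(
                {
                    "test": "pearson_child_caregiver",
                    "community": community,
                    "session_type": stype,
                    "r": res.r,
                    "n": res.n,
                    "z": None,
                    "p": res.p,
                }
            )
        # dependent comparison: child-caregiver vs child-others
        sub3 = sub.dropna(subset=["child_prop_a", "caregiver_prop_a", "others_prop_a"])
        if len(sub3) >= 4:
            try:
                r12 = pearson_correlation(sub3["child_prop_a"], sub3["caregiver_prop_a"]).r
                r13 = pearson_correlation(sub3["child_prop_a"], sub3["others_prop_a"]).r
                r23 = pearson_correlation(
                    sub3["caregiver_prop_a"], sub3["others_prop_a"]
                ).r
                cmp_res = steiger_dependent_z(r12, r13, r23, len(sub3))
                results.append(
                    {
                        "test": "steiger_caregiver_vs_others",
                        "community": community,
                        "session_type": stype,
                        "r": None,
                        "n": len(sub3),
                        "z": cmp_res.z,
                        "p": cmp_res.p,
                    }
                )
            except (UndefinedCorrelationError, ValueError):
                pass

    communities = sorted({c for c, _ in by_group})
    if len(communities) == 2:
        for stype in sorted({s for _, s in by_group}):
            res_a = by_group.get((communities[0], stype))
            res_b = by_group.get((communities[1], stype))
            if res_a is not None and res_b is not None:
                cmp_res = fisher_z_independent(res_a.r, res_a.n, res_b.r, res_b.n)
                results.append(
                    {
                        "test": "fisher_z_between_communities",
                        "community": f"{communities[0]}|{communities[1]}",
                        "session_type": stype,
                        "r": None,
                        "n": res_a.n + res_b.n,
                        "z": cmp_res.z,
                        "p": cmp_res.p,
                    }
                )
    results_frame = pd.DataFrame(
        results, columns=["test", "community", "session_type", "r", "n", "z", "p"]
    )
    return wide, results_frame


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = load_sessions(config)
    logger.info("stage=ingest sessions=%d", len(sessions))

    manifest: dict = {
        "langalign_version": __version__,
        "seed": config.seed,
        "n_iterations": config.n_iterations,
        "dominance_threshold": config.dominance_threshold,
        "min_turns": config.min_turns,
        "max_gap_ms": config.max_gap_ms,
        "n_sessions": len(sessions),
        "files": {},
    }

    def _emit(frame: pd.DataFrame, name: str) -> None:
        for path in write_reports(frame, out / name, config.formats):
            manifest["files"][path.name] = int(len(frame))

    _emit(profile_table(sessions), "profiles")
    _emit(usage_summary(sessions), "usage_summary")
    logger.info("stage=profiles")

    seeds = _session_seeds(sessions, config.seed)
    series_list = []
    alignment_results: list[AlignmentTestResult] = []
    session_meta = {}
    for session in sessions:
        dyad = caregiver_child_dyad(session)
        session_meta[session.session_id] = (
            session.community.value,
            session.session_type.value,
        )
        for direction in Direction:
            series_list.append(
                extract_turns(
                    session, dyad, direction=direction, max_gap_ms=config.max_gap_ms
                )
            )
        for direction in (Direction.CHILD_RESPONDS, Direction.PARTNER_RESPONDS,
                          Direction.POOLED):
            result = run_alignment_test(
                session,
                dyad,
                direction=direction,
                n_iterations=config.n_iterations,
                seed=seeds[session.session_id],
                dominance_threshold=config.dominance_threshold,
                min_turns=config.min_turns,
                max_gap_ms=config.max_gap_ms,
            )
            alignment_results.append(result)
            if not result.included:
                logger.warning(
                    "excluded session=%s direction=%s reason=%s",
                    session.session_id,
                    direction.value,
                    result.exclusion_reason.value,
                )
    _emit(turns_table(series_list), "turns")
    logger.info("stage=turns series=%d", len(series_list))
    _emit(results_table(alignment_results), "alignment_results")
    pooled = [r for r in alignment_results if r.direction == Direction.POOLED]
    _emit(attrition_report(pooled, session_meta), "attrition")
    logger.info("stage=align results=%d", len(alignment_results))

    corr_input, corr_results = correspondence_tables(sessions)
    _emit(corr_input, "correspondence_input")
    if not corr_results.empty:
        _emit(corr_results, "correspondence_results")
    logger.info("stage=correspond tests=%d", len(corr_results))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    manifest["files"][manifest_path.name] = 1
    return manifest
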