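"""Monte Carlo test of turn-by-turn language alignment against chance.

The null hypothesis is that each speaker chooses languages independently
according to their own preferences, so any apparent matching is a by-product
of shared base rates.  The null is realized by a frequency-preserving
permutation scheme: each replicate applies a uniform random permutation to
the sequence of *response* languages across the series' turns, which
preserves both speakers' observed language counts exactly.  (Permuting the
previous-language sequence as well is distributionally equivalent for the
match statistic; an option is provided for verification.)

Sessions where one language dominates, or with too few turns, cannot
distinguish alignment from chance — they are flagged by inclusion filters
but still computed, since the filters gate interpretation, not arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import Language, SessionRecord
from .turn_extraction import (
    Direction,
    TurnSeries,
    extract_turns,
    summarize_turns,
)

#: Significance threshold used when labeling sessions in reports.
ALPHA = 0.05

DOMINANCE_THRESHOLD = 0.80
MIN_TURNS = 30


class ExclusionReason(str, Enum):
    NONE = "none"
    DOMINANCE = "dominance"
    TOO_FEW_TURNS = "too_few_turns"
    BOTH = "both"


def expected_rate_analytic(
    prev_dist: Sequence[float], resp_dist: Sequence[float], atol: float = 1e-8
) -> float:
    """Match probability under independent pairing: sum_l p_prev(l)*p_resp(l).

    Each argument is a distribution over the two identifiable languages
    (order A, B) and must sum to 1.
    """
    prev = np.asarray(prev_dist, dtype=float)
    resp = np.asarray(resp_dist, dtype=float)
    for name, dist in (("prev_dist", prev), ("resp_dist", resp)):
        if dist.shape != (2,):
            raise ValueError(f"{name} must have exactly two entries (A, B)")
        if not np.isclose(dist.sum(), 1.0, atol=max(atol, 1e-8)):
            raise ValueError(f"{name} must sum to 1, got {dist.sum()!r}")
        if (dist < -atol).any():
            raise ValueError(f"{name} has negative mass")
    return float(prev @ resp)


@dataclass(frozen=True)
class NullDistribution:
    """Monte Carlo null distribution of match rates for one turn series."""

    rates: np.ndarray
    n_iterations: int
    n_turns: int

    @property
    def mean(self) -> float:
        return float(self.rates.mean())

    @property
    def sd(self) -> float:
        return float(self.rates.std(ddof=1)) if self.n_iterations > 1 else 0.0


def _language_codes(languages: Sequence[Language]) -> np.ndarray:
    return np.array([0 if lang == Language.A else 1 for lang in languages])


def permutation_null(
    series: TurnSeries,
    n_iterations: int = 10_000,
    seed: Union[int, np.random.Generator, None] = None,
    permute_both: bool = False,
) -> NullDistribution:
    """Generate the frequency-preserving null distribution of match rates.

    Every replicate permutes the response-language sequence uniformly at
    random (and, with ``permute_both``, the previous-language sequence too)
    and records the fraction of matches.  All replicates preserve the
    observed per-language counts of both roles exactly.
    """
    if series.n_turns < 1:
        raise ValueError("permutation_null requires a series with at least one turn")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    prev = _language_codes(series.prev_languages())
    resp = _language_codes(series.response_languages())
    n = len(resp)

    # argsort of iid uniforms = uniform random permutation, one row per replicate
    perm = np.argsort(rng.random((n_iterations, n)), axis=1)
    resp_perm = resp[perm]
    if permute_both:
        perm2 = np.argsort(rng.random((n_iterations, n)), axis=1)
        prev_rows = prev[perm2]
    else:
        prev_rows = prev[np.newaxis, :]
    rates = (resp_perm == prev_rows).mean(axis=1)
    return NullDistribution(rates=rates, n_iterations=n_iterations, n_turns=n)


def mc_p_value(observed_rate: float, null_rates: np.ndarray) -> float:
    """One-sided upper-tail Monte Carlo p with the add-one estimator.

    p = (1 + #{null >= observed}) / (1 + n); ties count toward the tail and
    p is never zero (its floor is 1/(n+1)).
    """
    null_rates = np.asarray(null_rates, dtype=float)
    if null_rates.size == 0:
        raise ValueError("null_rates must be non-empty")
    exceed = int((null_rates >= observed_rate - 1e-12).sum())
    return (1 + exceed) / (1 + null_rates.size)


def cohens_h(p1: float, p2: float) -> float:
    """Arcsine effect size for two proportions: 2*asin(sqrt(p1)) - 2*asin(sqrt(p2))."""
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    return float(2 * np.arcsin(np.sqrt(p1)) - 2 * np.arcsin(np.sqrt(p2)))


def alignment_gap(observed_rate: float, expected_rate: float) -> float:
    """Observed minus expected match rate, in percentage points."""
    return 100.0 * (observed_rate - expected_rate)


def apply_inclusion_filters(
    series: TurnSeries,
    dominance_threshold: float = DOMINANCE_THRESHOLD,
    min_turns: int = MIN_TURNS,
) -> tuple[bool, ExclusionReason]:
    """Classify a series against the balance and turn-count filters.

    Dominance: for either role (previous-speaker or response languages over
    the series' turns), the most frequent language's share reaches the
    threshold, i.e. the series fails the "< threshold use of one language"
    requirement.  Too-few-turns: fewer than ``min_turns`` turns.
    """
    too_few = series.n_turns < min_turns
    dominated = False
    if series.n_turns > 0:
        for langs in (series.prev_languages(), series.response_languages()):
            codes = _language_codes(langs)
            top_share = max(codes.mean(), 1 - codes.mean())
            if top_share >= dominance_threshold - 1e-12:
                dominated = True
    if dominated and too_few:
        return False, ExclusionReason.BOTH
    if dominated:
        return False, ExclusionReason.DOMINANCE
    if too_few:
        return False, ExclusionReason.TOO_FEW_TURNS
    return True, ExclusionReason.NONE


@dataclass(frozen=True)
class AlignmentTestResult:
    session_id: str
    dyad: tuple[str, str]
    direction: Direction
    n_turns: int
    observed_rate: Optional[float]
    null_mean: Optional[float]
    null_sd: Optional[float]
    expected_rate_analytic: Optional[float]
    p_value: Optional[float]
    cohens_h: Optional[float]
    n_iterations: int
    seed: Optional[int]
    included: bool
    exclusion_reason: ExclusionReason

    @property
    def significant(self) -> Optional[bool]:
        if self.p_value is None:
            return None
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "dyad": "|".join(self.dyad),
            "direction": self.direction.value,
            "n_turns": self.n_turns,
            "observed_rate": self.observed_rate,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "expected_rate_analytic": self.expected_rate_analytic,
            "p_value": self.p_value,
            "cohens_h": self.cohens_h,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "included": self.included,
            "exclusion_reason": self.exclusion_reason.value,
            "significant": self.significant,
        }


def run_series_test(
    series: TurnSeries,
    n_iterations: int = 10_000,
    seed: Optional[int] = None,
    dominance_threshold: float = DOMINANCE_THRESHOLD,
    min_turns: int = MIN_TURNS,
    permute_both: bool = False,
) -> AlignmentTestResult:
    """Run the alignment test on an already-extracted turn series."""
    summary = summarize_turns(series)
    included, reason = apply_inclusion_filters(
        series, dominance_threshold=dominance_threshold, min_turns=min_turns
    )
    if summary.n_turns == 0:
        return AlignmentTestResult(
            session_id=series.session_id,
            dyad=series.dyad,
            direction=series.direction,
            n_turns=0,
            observed_rate=None,
            null_mean=None,
            null_sd=None,
            expected_rate_analytic=None,
            p_value=None,
            cohens_h=None,
            n_iterations=n_iterations,
            seed=seed,
            included=included,
            exclusion_reason=reason,
        )
    null = permutation_null(
        series, n_iterations=n_iterations, seed=seed, permute_both=permute_both
    )
    n = summary.n_turns
    prev_dist = [summary.prev_counts["A"] / n, summary.prev_counts["B"] / n]
    resp_dist = [
        summary.response_counts["A"] / n,
        summary.response_counts["B"] / n,
    ]
    observed = summary.match_rate
    return AlignmentTestResult(
        session_id=series.session_id,
        dyad=series.dyad,
        direction=series.direction,
        n_turns=n,
        observed_rate=observed,
        null_mean=null.mean,
        null_sd=null.sd,
        expected_rate_analytic=expected_rate_analytic(prev_dist, resp_dist),
        p_value=mc_p_value(observed, null.rates),
        cohens_h=cohens_h(observed, null.mean),
        n_iterations=n_iterations,
        seed=seed,
        included=included,
        exclusion_reason=reason,
    )


def run_alignment_test(
    session: SessionRecord,
    dyad: tuple[str, str],
    direction: Direction = Direction.POOLED,
    n_iterations: int = 10_000,
    seed: Optional[int] = None,
    dominance_threshold: float = DOMINANCE_THRESHOLD,
    min_turns: int = MIN_TURNS,
    max_gap_ms: Optional[int] = None,
    permute_both: bool = False,
) -> AlignmentTestResult:
    """Extract a dyad's turns and test observed matching against the MC null.

    The same seed and inputs always produce an identical result.
    """
    series = extract_turns(
        session, dyad, direction=direction, max_gap_ms=max_gap_ms
    )
    return run_series_test(
        series,
        n_iterations=n_iterations,
        seed=seed,
        dominance_threshold=dominance_threshold,
        min_turns=min_turns,
        permute_both=permute_both,
    )


def results_table(results: Sequence[AlignmentTestResult]) -> pd.DataFrame:
    rows = [r.to_dict() for r in results]
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(
            ["session_id", "dyad", "direction"], kind="mergesort"
        ).reset_index(drop=True)
    return frame


def attrition_report(
    results: Sequence[AlignmentTestResult],
    session_meta: dict[str, tuple[str, str]],
) -> pd.DataFrame:
    """Sample-attrition accounting per community x session type.

    ``session_meta`` maps session_id -> (community, session_type).  Columns:
    ``initial`` (sessions tested), ``excluded_dominance`` (dominance alone or
    combined with too few turns), ``excluded_turns`` (too few turns alone),
    ``excluded_both`` (the overlap, reported separately), ``included``,
    ``significant`` and ``non_significant`` among included.  The identity
    ``initial = excluded_dominance + excluded_turns + included`` always
    holds because doubly-excluded sessions are counted once, in the
    dominance column.
    """
    rows = []
    for r in results:
        community, session_type = session_meta[r.session_id]
        rows.append(
            {
                "community": community,
                "session_type": session_type,
                "reason": r.exclusion_reason.value,
                "included": r.included,
                "significant": bool(r.significant) if r.included else False,
            }
        )
    frame = pd.DataFrame(rows)
    out = []
    for (community, session_type), grp in frame.groupby(
        ["community", "session_type"], sort=True
    ):
        n_both = int((grp["reason"] == ExclusionReason.BOTH.value).sum())
        n_dom = int((grp["reason"] == ExclusionReason.DOMINANCE.value).sum())
        n_turn = int((grp["reason"] == ExclusionReason.TOO_FEW_TURNS.value).sum())
        n_inc = int(grp["included"].sum())
        n_sig = int(grp["significant"].sum())
        out.append(
            {
                "community": community,
                "session_type": session_type,
                "initial": len(grp),
                "excluded_dominance": n_dom + n_both,
                "excluded_turns": n_turn,
                "excluded_both": n_both,
                "included": n_inc,
                "significant": n_sig,
                "non_significant": n_inc - n_sig,
            }
        )
    report = pd.DataFrame(out)
    if not report.empty:
        total = {
            "community": "TOTAL",
            "session_type": "",
            **{
                col: int(report[col].sum())
                for col in report.columns
                if col not in ("community", "session_type")
            },
        }
        report = pd.concat([report, pd.DataFrame([total])], ignore_index=True)
    return report
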