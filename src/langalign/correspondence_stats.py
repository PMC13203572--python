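"""Session-level correspondence between speakers' language-use proportions.

Families whose caregivers use more English tend to have children who use
more English; this module quantifies that correspondence with Pearson
correlations across families, and compares correlations with two classical
tests: Fisher's r-to-z for two independent samples (e.g. the same
correlation measured in two communities) and Steiger's Z for two dependent,
overlapping correlations (e.g. child-caregiver vs child-other, which share
the child variable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


class UndefinedCorrelationError(ValueError):
    """One of the inputs has zero variance, so r is undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    r2: float
    n1: int
    n2: int
    z: float
    p: float
    ci_r_difference: Optional[tuple[float, float]] = None


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Product-moment correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal-length")
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(x), p=float(res.pvalue))


def fisher_z_independent(
    r1: float, n1: int, r2: float, n2: int, ci_level: float = 0.95
) -> CorrelationComparison:
    """Compare two correlations from independent samples.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p from
    the standard normal, and a confidence interval for the correlation
    difference obtained by back-transforming the z-scale interval.
    """
    for name, n in (("n1", n1), ("n2", n2)):
        if n < 4:
            raise ValueError(f"{name} must be >= 4 for the Fisher transform test")
    for name, r in (("r1", r1), ("r2", r2)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    dz = np.arctanh(r1) - np.arctanh(r2)
    z = float(dz / se)
    p = float(2 * stats.norm.sf(abs(z)))
    crit = stats.norm.ppf(0.5 + ci_level / 2)
    ci = (float(np.tanh(dz - crit * se)), float(np.tanh(dz + crit * se)))
    return CorrelationComparison(
        r1=r1, r2=r2, n1=n1, n2=n2, z=z, p=p, ci_r_difference=ci
    )


def _check_psd(r12: float, r13: float, r23: float) -> None:
    matrix = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]], dtype=float)
    eigvals = np.linalg.eigvalsh(matrix)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"correlations ({r12}, {r13}, {r23}) do not form a valid "
            "(positive semi-definite) correlation matrix"
        )


def steiger_dependent_z(
    r12: float, r13: float, r23: float, n: int
) -> CorrelationComparison:
    """Compare two overlapping dependent correlations sharing variable 1.

    Tests r12 = r13 given that both are measured on the same n cases and
    correlate through r23.  Uses the Fisher-transformed difference with the
    covariance term built on the average of the two compared correlations
    (the widely used variant of Steiger's Z for overlapping correlations):

        rm  = (r12 + r13) / 2
        psi = r23 (1 - 2 rm^2) - rm^2 (1 - 2 rm^2 - r23^2) / 2
        s   = psi / (1 - rm^2)^2
        Z   = (atanh r12 - atanh r13) * sqrt((n - 3) / (2 - 2 s))
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    for name, r in (("r12", r12), ("r13", r13)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    if not -1 <= r23 <= 1:
        raise ValueError("r23 must lie in [-1, 1]")
    _check_psd(r12, r13, r23)

    rm = (r12 + r13) / 2.0
    psi = r23 * (1 - 2 * rm**2) - 0.5 * rm**2 * (1 - 2 * rm**2 - r23**2)
    s = psi / (1 - rm**2) ** 2
    z = float(
        (np.arctanh(r12) - np.arctanh(r13)) * np.sqrt((n - 3) / (2 - 2 * s))
    )
    p = float(2 * stats.norm.sf(abs(z)))
    return CorrelationComparison(r1=r12, r2=r13, n1=n, n2=n, z=z, p=p)
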