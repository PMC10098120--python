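"""Statistical analyses: Pearson correlation with two-sided p, linear
regression, Welch's two-sample t, and subject-table group summaries."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .io import SubjectRecord

__all__ = [
    "CorrelationResult",
    "pearson",
    "welch_t",
    "cohort_summary",
    "density_psqi_analysis",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    slope: float
    intercept: float
    r_squared: float


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with exact two-sided t-based p and the
    least-squares line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"pearson needs n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sstats.pearsonr(x, y)
    lr = sstats.linregress(x, y)
    return CorrelationResult(
        r=float(r), p=float(p), n=n,
        slope=float(lr.slope), intercept=float(lr.intercept),
        r_squared=float(r) ** 2,
    )


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sample t with Satterthwaite df; two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("welch_t degenerate: both groups constant")
    t, p = sstats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _round1(x: float) -> float:
    """Round to 1 decimal, halves up (decimal, not binary, arithmetic)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cohort_summary(subjects: Sequence[SubjectRecord]) -> dict[str, dict[str, float]]:
    """Per-group means of first-cycle minutes and spindle counts, to one
    decimal place."""
    out: dict[str, dict[str, float]] = {}
    for group in ("DS", "NS"):
        rows = [s for s in subjects if s.group == group]
        if not rows:
            raise ValueError(f"empty group {group!r}")
        if any(s.first_cycle_min is None or s.first_cycle_spindles is None for s in rows):
            raise ValueError(f"group {group!r} has missing first-cycle columns")
        # exact decimal means: the table values are decimal, so avoid
        # binary rounding artifacts at the half boundary
        minutes = [Decimal(repr(s.first_cycle_min)) for s in rows]
        counts = [Decimal(s.first_cycle_spindles) for s in rows]
        mean_min = sum(minutes) / len(minutes)
        mean_cnt = sum(counts) / len(counts)
        out[group] = {
            "n": len(rows),
            "first_cycle_min_mean": float(
                mean_min.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
            ),
            "first_cycle_spindles_mean": float(
                mean_cnt.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
            ),
        }
    return out


def density_psqi_analysis(
    subjects: Sequence[SubjectRecord],
    densities: dict[str, float],
) -> tuple[CorrelationResult, list[dict]]:
    """Pearson correlation between PSQI score and spindle density, plus
    the per-point scatter export."""
    ids = [s.subject_id for s in subjects]
    missing = [i for i in ids if i not in densities]
    extra = [i for i in densities if i not in set(ids)]
    if missing or extra:
        raise ValueError(
            f"subject/density id mismatch (missing={missing}, extra={extra})"
        )
    psqi = [s.psqi for s in subjects]
    dens = [densities[s.subject_id] for s in subjects]
    result = pearson(psqi, dens)
    scatter = [
        {"subject_id": s.subject_id, "group": s.group, "psqi": s.psqi,
         "density_per_min": densities[s.subject_id]}
        for s in subjects
    ]
    return result, scatter
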