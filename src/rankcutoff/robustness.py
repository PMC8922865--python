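"""Stability of the cutoff under low-abundance dropout.

High-throughput assays detect low-abundance variables unreliably: the
same sample re-sequenced can gain or lose thousands of near-zero
records.  The truncation sweep emulates that deterministically —
lowest-value records are removed in fixed increments, the cutoff is
recomputed from scratch on each reduced list, and the resulting
shortlist is compared (as an identifier set) with the full-data
shortlist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import (
    CutoffResult,
    RankedProfile,
    extract_shortlist,
    find_cutoff,
    rank_profile,
)
from .errors import DegenerateProfileError, ValidationError

__all__ = ["TruncationStep", "StabilityTable", "shortlist_overlap", "truncation_sweep"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TruncationStep:
    """One step of the sweep: ``removed_count`` lowest-ranked records
    dropped, ranks reassigned, cutoff recomputed.

    ``cutoff_rank`` is in the truncated profile's coordinates;
    ``cutoff_original_rank`` maps it back to the full profile for
    traceability.  ``cutoff_stable`` is true when the truncated
    shortlist is identical, as an identifier set, to the full-data
    shortlist.
    """

    removed_count: int
    removed_fraction: float
    cutoff_rank: int
    cutoff_original_rank: int
    cutoff_identifier: str
    shortlist_size: int
    shortlist_percent_of_full: float
    overlap_with_full: float
    cutoff_stable: bool


@dataclass(frozen=True)
class StabilityTable:
    """Fig.-style record of cutoff behaviour across a truncation sweep."""

    steps: list[TruncationStep]
    increment: int
    max_stable_fraction: float


def shortlist_overlap(a: set, b: set) -> float:
    """Fraction of the reference shortlist ``b`` recovered in ``a``.

    Returns ``|a & b| / |b|``; 1.0 when ``b`` is empty (nothing was
    there to lose).
    """
    if not b:
        return 1.0
    return len(a & b) / len(b)


def truncation_sweep(profile: RankedProfile, increment: int) -> StabilityTable:
    """Remove lowest-value records in steps of ``increment`` and track
    the cutoff.

    Every step is a fresh, independent computation: the surviving
    records are re-ranked 1..N', the chord re-fit and the cutoff
    recomputed, exactly as if the truncated table had been the input.
    The sweep covers removed counts 0, increment, 2*increment, ... and
    stops before the remainder drops below 3 records or becomes flat.
    """
    if increment < 1:
        raise ValidationError(f"increment must be >= 1, got {increment}")

    full_cutoff = find_cutoff(profile)
    full_ids = {r.identifier for r in extract_shortlist(profile, full_cutoff)}
    full_size = len(full_ids)
    n_full = profile.n
    all_records = profile.records()  # already in rank order

    steps: list[TruncationStep] = []
    removed = 0
    while n_full - removed >= 3:
        remaining = all_records[removed:]
        try:
            sub = rank_profile(remaining)
            cutoff = find_cutoff(sub)
        except DegenerateProfileError:
            logger.warning(
                "truncation sweep stopped at removed_count=%d: remaining "
                "profile is flat",
                removed,
            )
            break
        ids = {r.identifier for r in extract_shortlist(sub, cutoff)}
        steps.append(
            TruncationStep(
                removed_count=removed,
                removed_fraction=removed / n_full,
                cutoff_rank=cutoff.cutoff_rank,
                cutoff_original_rank=cutoff.cutoff_rank + removed,
                cutoff_identifier=cutoff.cutoff_identifier,
                shortlist_size=cutoff.shortlist_size,
                shortlist_percent_of_full=(
                    100.0 * cutoff.shortlist_size / full_size
                    if full_size
                    else (100.0 if cutoff.shortlist_size == 0 else float("inf"))
                ),
                overlap_with_full=shortlist_overlap(ids, full_ids),
                cutoff_stable=(ids == full_ids),
            )
        )
        removed += increment

    max_stable = 0.0
    for step in steps:
        if not step.cutoff_stable:
            break
        max_stable = step.removed_fraction
    return StabilityTable(
        steps=steps, increment=increment, max_stable_fraction=max_stable
    )
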