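"""Cutoff-point identification on ranked value distributions.

Descriptive omics datasets (gene expression in a tissue, protein
abundance, chemical-sensitivity scores) typically produce a biphasic
ranked curve: a long first phase of values growing slowly with rank
followed by a short second phase growing rapidly.  The boundary between
the two phases — the bending point of the curve — separates the
low-value background from the small set of dominant variables.

The method implemented here locates that boundary geometrically.  All
values are sorted ascending and plotted against their integer rank
(curve ``A``).  A chord ``B`` is drawn from the first ranked point
``(1, V_min)`` to the last ``(N, V_max)``.  For every point of the
curve the length ``D`` of the perpendicular segment dropped onto the
chord is computed, and the rank maximising ``D`` is the cutoff.
Variables ranked strictly above the cutoff form the shortlist.

Two equivalent distance computations are provided: a stepwise
construction that builds the perpendicular line through each curve
point and intersects it with the chord, and a closed form.  Both reduce
algebraically to the standard point-to-line distance

    D = |V - m_B * R - b_B| / sqrt(1 + m_B**2)

which is what the production path (:func:`distance_profile`) uses for
numerical stability; the stepwise and closed forms are kept as
independently testable references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateProfileError, SizeError, ValidationError

__all__ = [
    "ValueRecord",
    "RankedProfile",
    "Chord",
    "PerpendicularGeometry",
    "DistanceProfile",
    "CutoffResult",
    "rank_profile",
    "fit_chord",
    "perpendicular_geometry",
    "segment_length_stepwise",
    "segment_length_closed",
    "distance_profile",
    "find_cutoff",
    "extract_shortlist",
    "low_tail_control_list",
    "adjust_cutoff",
]

MIN_RECORDS = 3


@dataclass(frozen=True)
class ValueRecord:
    """A single variable: an opaque identifier and a non-negative value."""

    identifier: str
    value: float

    def validate(self) -> None:
        if not self.identifier:
            raise ValidationError("record has an empty identifier")
        if not math.isfinite(self.value):
            raise ValidationError(
                f"record {self.identifier!r} has a non-finite value: {self.value}"
            )
        if self.value < 0:
            raise ValidationError(
                f"record {self.identifier!r} has a negative value: {self.value}"
            )


@dataclass(frozen=True)
class RankedProfile:
    """Values sorted ascending with 1-based ranks (the ranked curve A).

    ``identifiers[i]`` and ``values[i]`` belong to rank ``i + 1``.
    """

    identifiers: tuple[str, ...]
    values: np.ndarray  # float64, non-decreasing

    @property
    def n(self) -> int:
        return len(self.identifiers)

    @property
    def ranks(self) -> np.ndarray:
        """Integer ranks 1..N aligned with :attr:`values`."""
        return np.arange(1, self.n + 1)

    def record_at(self, rank: int) -> ValueRecord:
        """The record at a 1-based rank."""
        return ValueRecord(self.identifiers[rank - 1], float(self.values[rank - 1]))

    def records(self) -> list[ValueRecord]:
        return [
            ValueRecord(i, float(v)) for i, v in zip(self.identifiers, self.values)
        ]


@dataclass(frozen=True)
class Chord:
    """The straight line B through (1, V_min) and (N, V_max)."""

    m_b: float
    b_b: float

    def y_at(self, x: float) -> float:
        return self.m_b * x + self.b_b


@dataclass(frozen=True)
class PerpendicularGeometry:
    """Intermediate quantities of the stepwise perpendicular construction.

    ``(x_ac, y_ac)`` is the curve point (rank, value); ``b_c`` the
    intercept of the perpendicular line C through it; ``(x_cb, y_cb)``
    the foot of the perpendicular on the chord B.
    """

    x_ac: float
    y_ac: float
    b_c: float
    x_cb: float
    y_cb: float


@dataclass(frozen=True)
class DistanceProfile:
    """Perpendicular segment lengths D aligned with ranks 1..N."""

    distances: np.ndarray

    @property
    def n(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class CutoffResult:
    """The identified cutoff and the derived shortlist boundary.

    ``cutoff_rank`` is the rank of the longest perpendicular segment;
    the shortlist comprises the ``n - cutoff_rank`` records ranked
    strictly above it.  ``reference_rank`` is the unadjusted cutoff
    rank: it equals ``cutoff_rank`` unless a stringency offset was
    applied with :func:`adjust_cutoff`.  ``tie_count`` is the number of
    ranks whose D exactly (bit-for-bit) equals the maximum.
    """

    cutoff_rank: int
    cutoff_identifier: str
    cutoff_value: float
    max_distance: float
    shortlist_size: int
    tie_count: int = 1
    reference_rank: int | None = None
    stringency_offset: float = 0.0

    def __post_init__(self):
        if self.reference_rank is None:
            object.__setattr__(self, "reference_rank", self.cutoff_rank)


def rank_profile(records: Iterable[ValueRecord]) -> RankedProfile:
    """Sort records by value ascending and assign 1-based ranks.

    Equal values are ordered by identifier (lexicographic) so ranking
    is deterministic across runs and platforms.

    Raises
    ------
    SizeError
        If fewer than 3 records are supplied.
    ValidationError
        If any value is negative or non-finite, or an identifier is
        empty; the message names the offending identifier.
    """
    recs = list(records)
    if len(recs) < MIN_RECORDS:
        raise SizeError(
            f"need at least {MIN_RECORDS} records to rank, got {len(recs)}"
        )
    for r in recs:
        r.validate()
    recs.sort(key=lambda r: (r.value, r.identifier))
    return RankedProfile(
        identifiers=tuple(r.identifier for r in recs),
        values=np.asarray([r.value for r in recs], dtype=np.float64),
    )


def fit_chord(profile: RankedProfile) -> Chord:
    """Fit the chord B through the first and last ranked points.

    With 1-based ranks the chord passes through ``(1, V_min)`` and
    ``(N, V_max)``, so ``m_B = (V_max - V_min) / (N - 1)`` and
    ``b_B = V_min - m_B``.  For data whose minimum is zero this yields
    ``b_B = -m_B``.

    Raises
    ------
    DegenerateProfileError
        If all values are equal (horizontal chord: no bending point).
    """
    v_min = float(profile.values[0])
    v_max = float(profile.values[-1])
    if v_max == v_min:
        raise DegenerateProfileError(
            "flat profile: all values equal, the ranked curve has no bending point"
        )
    m_b = (v_max - v_min) / (profile.n - 1)
    b_b = v_min - m_b
    return Chord(m_b=m_b, b_b=b_b)


def perpendicular_geometry(rank: float, value: float, chord: Chord) -> PerpendicularGeometry:
    """Build the perpendicular line through ``(rank, value)`` and drop
    it onto the chord (the stepwise construction).

    The perpendicular C has slope ``-1/m_B`` and intercept
    ``b_C = V - (-1/m_B) * R``.  Equating C and B gives the foot
    ``y_CB = (b_B + b_C * m_B**2) / (1 + m_B**2)`` and
    ``x_CB = (y_CB - b_B) / m_B``.
    """
    if chord.m_b == 0:
        raise DegenerateProfileError(
            "horizontal chord: perpendicular slope -1/m_B is undefined"
        )
    m_b, b_b = chord.m_b, chord.b_b
    b_c = value - (-1.0 / m_b) * rank
    y_cb = (b_b + b_c * m_b**2) / (1.0 + m_b**2)
    x_cb = (y_cb - b_b) / m_b
    return PerpendicularGeometry(x_ac=rank, y_ac=value, b_c=b_c, x_cb=x_cb, y_cb=y_cb)


def segment_length_stepwise(rank: float, value: float, chord: Chord) -> float:
    """Segment length D via the stepwise construction and the
    Pythagorean theorem."""
    g = perpendicular_geometry(rank, value, chord)
    return math.hypot(g.x_cb - g.x_ac, g.y_cb - g.y_ac)


def segment_length_closed(rank: float, value: float, chord: Chord) -> float:
    """Segment length D via the closed form

        D = sqrt( ((V*m_B - b_B*m_B - R*m_B^2)^2 + (b_B + m_B*R - V)^2)
                  / (1 + m_B^2)^2 )

    evaluated exactly as written (no algebraic simplification), so it
    can serve as an independent cross-check of the stepwise and
    simplified routes.
    """
    m_b, b_b = chord.m_b, chord.b_b
    num = (value * m_b - b_b * m_b - rank * m_b**2) ** 2 + (
        b_b + m_b * rank - value
    ) ** 2
    return math.sqrt(num / (1.0 + m_b**2) ** 2)


def _point_line_distances(ranks: np.ndarray, values: np.ndarray, chord: Chord) -> np.ndarray:
    # simplified equivalent of the closed form: |residual| / sqrt(1 + m^2)
    resid = values - (chord.m_b * ranks + chord.b_b)
    return np.abs(resid) / math.sqrt(1.0 + chord.m_b**2)


def distance_profile(profile: RankedProfile, chord: Chord) -> DistanceProfile:
    """Perpendicular segment length D for every rank of the profile.

    Uses the simplified point-to-line form, which agrees with both the
    stepwise construction and the closed form to floating-point
    accuracy.  D is exactly 0 at ranks 1 and N (chord endpoints).
    """
    if chord.m_b == 0:
        raise DegenerateProfileError(
            "horizontal chord: perpendicular distances are undefined"
        )
    d = _point_line_distances(profile.ranks.astype(np.float64), profile.values, chord)
    return DistanceProfile(distances=d)


def find_cutoff(profile: RankedProfile) -> CutoffResult:
    """Identify the cutoff rank: the argmax of the distance profile.

    If several ranks tie for the maximum distance (exact binary
    equality) the largest rank is returned — the most stringent
    shortlist — and ``tie_count`` reports how many ranks tied.

    Raises
    ------
    DegenerateProfileError
        If the profile is flat.
    """
    chord = fit_chord(profile)
    dp = distance_profile(profile, chord)
    d = dp.distances
    d_max = float(d.max())
    tied = np.flatnonzero(d == d_max)
    cutoff_rank = int(tied[-1]) + 1
    return CutoffResult(
        cutoff_rank=cutoff_rank,
        cutoff_identifier=profile.identifiers[cutoff_rank - 1],
        cutoff_value=float(profile.values[cutoff_rank - 1]),
        max_distance=d_max,
        shortlist_size=profile.n - cutoff_rank,
        tie_count=int(len(tied)),
    )


def extract_shortlist(profile: RankedProfile, cutoff: CutoffResult) -> list[ValueRecord]:
    """Records ranked strictly above the cutoff rank, highest value first.

    The cutoff record itself is excluded: with N records and cutoff
    rank k the shortlist spans ranks k+1 .. N and has N - k members.
    """
    return [
        profile.record_at(r) for r in range(profile.n, cutoff.cutoff_rank, -1)
    ]


def low_tail_control_list(profile: RankedProfile, size: int) -> list[ValueRecord]:
    """The ``size`` lowest-ranked records with strictly positive values.

    Zero-valued records are skipped: they carry no signal and are
    excluded from the control list (though they do participate in the
    cutoff computation).  Records are returned in rank order, lowest
    first.

    Raises
    ------
    SizeError
        If fewer than ``size`` records have a value > 0.
    """
    if size < 1:
        raise ValidationError(f"control-list size must be positive, got {size}")
    nonzero_ranks = np.flatnonzero(profile.values > 0) + 1
    if size > len(nonzero_ranks):
        raise SizeError(
            f"requested control list of {size} records but only "
            f"{len(nonzero_ranks)} records have non-zero values"
        )
    return [profile.record_at(int(r)) for r in nonzero_ranks[:size]]


def adjust_cutoff(
    cutoff: CutoffResult, profile: RankedProfile, stringency_offset: float
) -> CutoffResult:
    """Shift the cutoff rank by a signed fraction of N.

    The geometric cutoff is a reproducible reference point; some
    applications want a more or less stringent shortlist relative to
    it.  The new rank is ``clamp(round(k + offset * N), 1, N)``; the
    unadjusted rank is retained as ``reference_rank``.

    Raises
    ------
    ValidationError
        If the offset is outside the open interval (-1, 1).
    """
    if not (-1.0 < stringency_offset < 1.0):
        raise ValidationError(
            f"stringency offset must lie strictly between -1 and 1, got "
            f"{stringency_offset}"
        )
    n = profile.n
    # round half away from zero so the shift is platform-independent
    shifted = cutoff.cutoff_rank + stringency_offset * n
    new_rank = int(math.floor(shifted + 0.5))
    new_rank = max(1, min(n, new_rank))
    chord = fit_chord(profile)
    d_at = float(
        _point_line_distances(
            np.asarray([float(new_rank)]), profile.values[new_rank - 1 : new_rank], chord
        )[0]
    )
    return replace(
        cutoff,
        cutoff_rank=new_rank,
        cutoff_identifier=profile.identifiers[new_rank - 1],
        cutoff_value=float(profile.values[new_rank - 1]),
        max_distance=d_at,
        shortlist_size=n - new_rank,
        reference_rank=cutoff.reference_rank,
        stringency_offset=stringency_offset,
    )
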