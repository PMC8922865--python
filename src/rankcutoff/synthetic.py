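"""Synthetic ranked-value datasets with a known bending point.

Descriptive omics curves are biphasic: many low values growing slowly
with rank, then a short steep tail.  The generator here builds the two
simplest shape families matching that description — two-segment
piecewise-linear and piecewise-exponential curves joined at a known
knee rank — so every downstream computation can be checked against an
exact ground truth.  Optional additive Gaussian noise is applied to the
values *before* ranking (ranking is part of the method under test) and
negative values are clamped to zero, consistent with non-negative
abundance data.

The defaults mirror the scale of a whole-transcriptome consensus
expression table: 16,353 records with a knee near rank 15,778, a nearly
flat first phase and a unit-slope second phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ValueRecord
from .errors import ValidationError

__all__ = ["PhaseModel", "BiphasicSpec", "generate_biphasic", "degenerate_fixtures"]


@dataclass(frozen=True)
class PhaseModel:
    """Growth model of one phase: ``linear`` with a slope per rank step,
    or ``exponential`` with a rate per rank step."""

    kind: str  # "linear" | "exponential"
    param: float  # slope s (linear) or rate r (exponential)

    def validate(self, name: str) -> None:
        if self.kind not in ("linear", "exponential"):
            raise ValidationError(
                f"{name}: unknown phase kind {self.kind!r} "
                "(expected 'linear' or 'exponential')"
            )
        if self.param < 0:
            raise ValidationError(f"{name}: growth parameter must be >= 0")


@dataclass(frozen=True)
class BiphasicSpec:
    """Specification of a synthetic biphasic ranked curve.

    ``knee_rank`` is the ground-truth junction: the noiseless curve is
    convex there, growing with ``phase1`` up to the knee and with the
    strictly faster ``phase2`` beyond it.  ``noise_sd`` is the standard
    deviation of additive Gaussian noise in value units (0 = noiseless).
    """

    n: int = 16353
    knee_rank: int = 15778
    phase1: PhaseModel = field(default_factory=lambda: PhaseModel("linear", 0.002))
    phase2: PhaseModel = field(default_factory=lambda: PhaseModel("linear", 1.0))
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 3:
            raise ValidationError(f"n must be >= 3, got {self.n}")
        if not (3 <= self.knee_rank <= self.n - 1):
            raise ValidationError(
                f"knee_rank must lie in [3, n-1] = [3, {self.n - 1}], "
                f"got {self.knee_rank}"
            )
        self.phase1.validate("phase1")
        self.phase2.validate("phase2")
        if self.phase1.kind == self.phase2.kind and self.phase2.param <= self.phase1.param:
            raise ValidationError(
                "phase2 must grow strictly faster than phase1 "
                f"({self.phase2.param} <= {self.phase1.param})"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _phase_values(model: PhaseModel, steps: np.ndarray) -> np.ndarray:
    """Cumulative growth after ``steps`` rank increments, starting at 0."""
    if model.kind == "linear":
        return model.param * steps
    return np.expm1(model.param * steps)


def generate_biphasic(spec: BiphasicSpec) -> list[ValueRecord]:
    """Generate ``spec.n`` records whose noiseless ranked curve has a
    convex junction exactly at ``spec.knee_rank``.

    Identifiers are zero-padded so lexicographic order equals the
    noiseless rank order; generation is reproducible for a fixed seed.
    """
    spec.validate()
    n, k = spec.n, spec.knee_rank
    ranks = np.arange(1, n + 1, dtype=np.float64)
    values = np.empty(n, dtype=np.float64)
    values[:k] = _phase_values(spec.phase1, ranks[:k] - 1.0)
    knee_value = values[k - 1]
    values[k:] = knee_value + _phase_values(spec.phase2, ranks[k:] - float(k))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=n)
        np.clip(values, 0.0, None, out=values)
    width = len(str(n))
    return [
        ValueRecord(f"v{i + 1:0{width}d}", float(values[i])) for i in range(n)
    ]


def degenerate_fixtures() -> dict[str, list[ValueRecord]]:
    """Small edge-case datasets with documented expected behaviour.

    ======================  ==================================================
    name                    expected behaviour
    ======================  ==================================================
    ``flat``                ``fit_chord`` raises a degenerate-profile error
                            (all values equal; horizontal chord).
    ``all_zero``            same: a flat profile at zero.
    ``perfect_line``        all distances are exactly 0; ``find_cutoff``
                            returns rank N under the largest-rank tie rule,
                            with an empty shortlist and ``tie_count == N``.
    ``two_records``         ``rank_profile`` raises a size error (< 3).
    ``single_spike``        one non-zero value: cutoff at rank N-1,
                            shortlist of the single spike.
    ``heavy_ties``          massive value ties; ranking falls back to the
                            lexicographic identifier order and is
                            deterministic.
    ======================  ==================================================
    """
    return {
        "flat": [ValueRecord(f"f{i}", 7.5) for i in range(1, 6)],
        "all_zero": [ValueRecord(f"z{i}", 0.0) for i in range(1, 6)],
        "perfect_line": [ValueRecord(f"l{i}", float(i)) for i in range(1, 7)],
        "two_records": [ValueRecord("a", 1.0), ValueRecord("b", 2.0)],
        "single_spike": [ValueRecord(f"s{i}", 0.0) for i in range(1, 5)]
        + [ValueRecord("s5", 10.0)],
        "heavy_ties": [ValueRecord(f"t{i:02d}", 1.0) for i in range(1, 9)]
        + [ValueRecord("t09", 2.0), ValueRecord("t10", 50.0)],
    }
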