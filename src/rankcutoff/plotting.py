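"""Diagnostic plots: ranked curve with chord and cutoff marker, and the
truncation-stability profile."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import Chord, CutoffResult, RankedProfile
from .robustness import StabilityTable

__all__ = ["plot_ranked_curve", "plot_stability"]


def plot_ranked_curve(
    profile: RankedProfile,
    chord: Chord,
    cutoff: CutoffResult,
    path: str | Path,
) -> None:
    """Plot the ranked value curve A, the chord B and a vertical line at
    the cutoff rank."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.ranks, profile.values, lw=1.2, label="ranked values (A)")
    ax.plot(
        [1, profile.n],
        [chord.y_at(1), chord.y_at(profile.n)],
        "--",
        lw=1.0,
        label="chord (B)",
    )
    ax.axvline(
        cutoff.cutoff_rank,
        color="red",
        lw=1.0,
        label=f"cutoff rank {cutoff.cutoff_rank}",
    )
    ax.set_xlabel("rank")
    ax.set_ylabel("value")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_stability(table: StabilityTable, path: str | Path) -> None:
    """Plot shortlist size (percent of the full-data shortlist) against
    the fraction of lowest-value records removed."""
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = [s.removed_fraction * 100 for s in table.steps]
    ys = [s.shortlist_percent_of_full for s in table.steps]
    ax.plot(xs, ys, marker="o", ms=3, lw=1.0)
    ax.set_xlabel("lowest-value records removed (%)")
    ax.set_ylabel("shortlist size (% of full-data shortlist)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
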