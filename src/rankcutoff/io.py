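"""Readers and writers for the tabular interchange formats.

Input is a delimited text table (TSV by default) with a header row and
at least an identifier column and a value column; ``#`` comment lines
and blank lines are ignored.  Outputs are TSV tables plus a JSON run
summary carrying full double precision; distances in the TSV outputs
are printed with 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    Chord,
    CutoffResult,
    DistanceProfile,
    RankedProfile,
    ValueRecord,
)
from .errors import InputFormatError, ValidationError
from .robustness import StabilityTable

__all__ = [
    "read_value_table",
    "write_records",
    "write_shortlist",
    "write_distances",
    "write_stability",
    "make_summary",
    "write_summary",
    "file_sha256",
]


def read_value_table(
    path: str | Path,
    id_col: str = "id",
    value_col: str = "value",
    delimiter: str = "\t",
) -> list[ValueRecord]:
    """Read (identifier, value) records from a delimited text file.

    Raises
    ------
    InputFormatError
        If the file cannot be parsed or a configured column is missing
        (the message names the columns that are present).
    ValidationError
        If a value cell is not numeric (the message cites the row
        number) or an identifier occurs more than once (the message
        lists the duplicates).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=delimiter, comment="#", skip_blank_lines=True, dtype=str
        )
    except FileNotFoundError:
        raise InputFormatError(f"input file not found: {path}")
    except Exception as exc:  # malformed CSV/TSV
        raise InputFormatError(f"could not parse {path}: {exc}")

    for col in (id_col, value_col):
        if col not in df.columns:
            raise InputFormatError(
                f"column {col!r} not found in {path}; available columns: "
                f"{', '.join(map(repr, df.columns))}"
            )

    ids = df[id_col].astype(str)
    raw = df[value_col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        # +2: header line plus 1-based numbering
        rows = [str(i + 2) for i in df.index[bad][:10]]
        raise ValidationError(
            f"non-numeric value(s) in column {value_col!r} of {path} at "
            f"row(s) {', '.join(rows)}"
        )
    if values.isna().any():
        rows = [str(i + 2) for i in df.index[values.isna()][:10]]
        raise ValidationError(
            f"missing value(s) in column {value_col!r} of {path} at "
            f"row(s) {', '.join(rows)}"
        )

    dup = ids[ids.duplicated(keep=False)].unique()
    if len(dup):
        raise ValidationError(
            f"duplicate identifier(s) in {path}: {', '.join(sorted(dup)[:10])}"
        )

    # parse from the raw strings so written doubles round-trip exactly
    return [ValueRecord(i, float(s)) for i, s in zip(ids, raw)]


def _fmt_distance(d: float) -> str:
    return f"{d:.6g}"


def write_records(
    path: str | Path, records: list[ValueRecord], header_comments: list[str] | None = None
) -> None:
    """Write records as a two-column TSV, optionally with ``#`` header
    comment lines (e.g. the generator seed)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write("id\tvalue\n")
        for r in records:
            fh.write(f"{r.identifier}\t{r.value!r}\n")


def write_shortlist(
    path: str | Path,
    profile: RankedProfile,
    cutoff: CutoffResult,
    distances: DistanceProfile,
) -> None:
    """Write the shortlist (ranks above the cutoff, highest first) as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\trank\tvalue\tdistance\n")
        for rank in range(profile.n, cutoff.cutoff_rank, -1):
            rec = profile.record_at(rank)
            d = distances.distances[rank - 1]
            fh.write(f"{rec.identifier}\t{rank}\t{rec.value!r}\t{_fmt_distance(d)}\n")


def write_distances(
    path: str | Path, profile: RankedProfile, distances: DistanceProfile
) -> None:
    """Write the full per-rank distance profile as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tid\tvalue\tdistance\n")
        for rank in range(1, profile.n + 1):
            rec = profile.record_at(rank)
            d = distances.distances[rank - 1]
            fh.write(f"{rank}\t{rec.identifier}\t{rec.value!r}\t{_fmt_distance(d)}\n")


def write_stability(path: str | Path, table: StabilityTable) -> None:
    """Write the truncation-sweep table as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "removed_count\tremoved_fraction\tcutoff_id\tshortlist_size\t"
            "shortlist_percent_of_full\toverlap_with_full\tstable\n"
        )
        for s in table.steps:
            fh.write(
                f"{s.removed_count}\t{s.removed_fraction:.6g}\t"
                f"{s.cutoff_identifier}\t{s.shortlist_size}\t"
                f"{s.shortlist_percent_of_full:.6g}\t{s.overlap_with_full:.6g}\t"
                f"{str(s.cutoff_stable).lower()}\n"
            )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def make_summary(
    profile: RankedProfile,
    chord: Chord,
    cutoff: CutoffResult,
    input_checksum: str | None = None,
) -> dict:
    """Assemble the run-summary dict written as JSON."""
    summary = {
        "n": profile.n,
        "m_B": chord.m_b,
        "b_B": chord.b_b,
        "cutoff_rank": cutoff.cutoff_rank,
        "cutoff_id": cutoff.cutoff_identifier,
        "cutoff_value": cutoff.cutoff_value,
        "max_distance": cutoff.max_distance,
        "shortlist_size": cutoff.shortlist_size,
        "tie_count": cutoff.tie_count,
        "reference_rank": cutoff.reference_rank,
        "stringency_offset": cutoff.stringency_offset,
        "version": __version__,
    }
    if input_checksum is not None:
        summary["input_sha256"] = input_checksum
    return summary


def write_summary(path: str | Path, summary: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=float)
        fh.write("\n")
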