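"""Descriptive statistics: intron sizes, densities and sliding candidates."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contexts import SpliceContextSet
from .matrix import IntronMatrix, IntronPosition, PRESENT, UNKNOWN

__all__ = ["SizeSummary", "DensitySummary", "size_stats", "density_stats",
           "sliding_candidates"]


@dataclass
class SizeSummary:
    """Global and per-position intron length statistics (bp).

    Positions with fewer than ``min_n`` measured lengths are dropped from
    the per-position table (but kept in the global pool).
    """

    global_stats: pd.Series  # n, mean, sd, median, q1, q3
    per_position: pd.DataFrame  # index position_id; columns n, mean, sd, median, q1, q3
    min_n: int
    excluded_positions: tuple[str, ...]


def _describe(lengths: pd.Series) -> pd.Series:
    return pd.Series({
        "n": float(len(lengths)),
        "mean": lengths.mean(),
        "sd": lengths.std(ddof=1) if len(lengths) > 1 else 0.0,
        "median": lengths.median(),
        "q1": lengths.quantile(0.25),
        "q3": lengths.quantile(0.75),
    })


def size_stats(contexts: SpliceContextSet, min_n: int = 10) -> SizeSummary:
    """Intron size summaries, overall and per position."""
    present = contexts.present
    lengths = present["length_bp"].astype(float)
    if (lengths <= 0).any():
        raise ValueError("non-positive intron lengths")
    per = (
        present.groupby("position_id")["length_bp"]
        .apply(lambda s: _describe(s.astype(float)))
        .unstack()
    )
    keep = per["n"] >= min_n
    excluded = tuple(per.index[~keep])
    return SizeSummary(
        global_stats=_describe(lengths),
        per_position=per[keep],
        min_n=min_n,
        excluded_positions=excluded,
    )


@dataclass
class DensitySummary:
    """Introns per gene copy.

    Copies containing any unknown state are flagged; the grand mean and
    range cover fully-known copies only (so grand mean x number of those
    copies equals their total present count exactly).
    """

    per_copy: pd.DataFrame  # index copy_id; columns species, n_present, has_unknown
    species_mean: pd.Series
    grand_mean: float  # NaN when no fully-known copy exists
    count_range: tuple[Optional[int], Optional[int]]
    flagged_copies: tuple[str, ...]


def density_stats(matrix: IntronMatrix) -> DensitySummary:
    n_present = (matrix.states == PRESENT).sum(axis=1)
    has_unknown = (matrix.states == UNKNOWN).any(axis=1)
    per_copy = pd.DataFrame({
        "species": matrix.species.to_numpy(),
        "n_present": n_present,
        "has_unknown": has_unknown,
    }, index=matrix.copies.index)
    full = per_copy[~per_copy["has_unknown"]]
    grand = float(full["n_present"].mean()) if len(full) else float("nan")
    rng = (int(full["n_present"].min()), int(full["n_present"].max())) \
        if len(full) else (None, None)
    return DensitySummary(
        per_copy=per_copy,
        species_mean=per_copy.groupby("species")["n_present"].mean(),
        grand_mean=grand,
        count_range=rng,
        flagged_copies=tuple(per_copy.index[per_copy["has_unknown"]]),
    )


def sliding_candidates(
    positions: Sequence[IntronPosition], matrix: IntronMatrix
) -> list[tuple[str, str]]:
    """Candidate intron-sliding pairs.

    Two positions are a candidate displacement if their nucleotide-level
    insertion points (3 x codon + phase on the coding sequence) are exactly
    1 bp apart and no single gene copy ever carries both introns.
    """
    frame = matrix.to_frame()
    out = []
    ordered = sorted(positions, key=lambda p: p.nucleotide_offset)
    for a, b in zip(ordered, ordered[1:]):
        if b.nucleotide_offset - a.nucleotide_offset != 1:
            continue
        co_present = (
            (frame[a.position_id] == PRESENT) & (frame[b.position_id] == PRESENT)
        ).any()
        if not co_present:
            out.append((a.position_id, b.position_id))
    return out
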