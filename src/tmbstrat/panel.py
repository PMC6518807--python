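"""Targeted-panel territory: the TMB denominator.

A hybridization-capture gene panel is represented as a set of sorted,
non-overlapping, 0-based half-open genomic intervals. The summed interval
length, in megabases, is the coding territory by which somatic mutation
counts are normalized.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES_PER_MB = 1_000_000


@dataclass(frozen=True)
class PanelDefinition:
    """Sorted, disjoint capture intervals and their derived territory.

    ``intervals`` is a DataFrame with columns ``chrom`` (str), ``start``,
    ``end`` (ints, 0-based half-open). Construction validates ordering and
    disjointness; use :func:`merge_intervals` first for raw interval sets.
    """

    intervals: pd.DataFrame
    _starts_by_chrom: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.intervals
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"panel intervals need columns {sorted(required)}")
        if (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(
                f"interval end <= start at {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        # per-chrom sorted lookup tables for fast membership queries
        lookup: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            starts = sub["start"].tolist()
            ends = sub["end"].tolist()
            for i in range(1, len(starts)):
                if starts[i] < ends[i - 1]:
                    raise ValueError(
                        f"overlapping intervals on {chrom}: "
                        f"[{starts[i - 1]},{ends[i - 1]}) and [{starts[i]},{ends[i]})"
                    )
            lookup[chrom] = (starts, ends)
        object.__setattr__(self, "_starts_by_chrom", lookup)

    @property
    def territory_bases(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    @property
    def territory_mb(self) -> float:
        """Territory in megabases; unrounded (outputs round to 0.1 Mb)."""
        return self.territory_bases / BASES_PER_MB

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based variant position in the panel."""
        entry = self._starts_by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        pos0 = pos - 1  # VCF 1-based -> BED 0-based; sole conversion point
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < ends[i]


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping or bookended intervals per chromosome."""
    from intervaltree import IntervalTree

    out = []
    for chrom in sorted(df["chrom"].unique()):
        sub = df[df["chrom"] == chrom]
        tree = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"])
        )
        tree.merge_overlaps(strict=False)  # strict=False also joins bookends
        for iv in sorted(tree):
            out.append((chrom, iv.begin, iv.end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def generate_panel(n_intervals: int, territory_mb: float, seed: int) -> PanelDefinition:
    """Simulate a capture panel of ``n_intervals`` disjoint intervals.

    The summed interval length equals ``territory_mb`` megabases to within
    one base (exactly, by construction). Intervals are placed on a single
    synthetic contig with random inter-interval gaps.
    """
    if territory_mb <= 0:
        raise ValueError(f"territory must be positive, got {territory_mb} Mb")
    if n_intervals < 1:
        raise ValueError("need at least one interval")
    total = round(territory_mb * BASES_PER_MB)
    if total < n_intervals:
        raise ValueError("territory too small for the requested interval count")
    rng = np.random.default_rng(seed)
    # random composition of `total` bases into n positive parts
    extra = rng.multinomial(total - n_intervals, np.full(n_intervals, 1.0 / n_intervals))
    lengths = extra + 1
    gaps = rng.integers(1_000, 100_000, size=n_intervals)
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    df = pd.DataFrame(
        {"chrom": "chr1", "start": starts.astype(int), "end": (starts + lengths).astype(int)}
    )
    return PanelDefinition(df)
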