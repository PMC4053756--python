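"""Core data containers: probe-level signal tracks and interval sets.

All coordinates are 0-based half-open, BED-native.  A :class:`ProbeTrack`
couples a sorted probe table (chrom, start, end, gc_count) with one score
vector per replicate; interval sets (domains, elements) hold disjoint
sorted intervals per chromosome together with the parameters that
produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["chrom", "start", "end", "gc_count"]


class TrackShapeError(ValueError):
    """Probe sets or score vectors do not line up."""


@dataclass
class ProbeTrack:
    """Per-probe signal over a tiling layout.

    Parameters
    ----------
    probes
        DataFrame with columns ``chrom, start, end, gc_count``, sorted by
        (chrom, start).
    scores
        Array of shape ``(n_probes, n_replicates)`` or ``(n_probes,)``
        (treated as a single replicate).  Values are in score units
        (log2-ratio-derived, dimensionless).
    sample
        Free-text sample label, e.g. ``"LMN-1"`` or ``"GFP-control"``.
    """

    probes: pd.DataFrame
    scores: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim == 1:
            self.scores = self.scores[:, None]
        if self.scores.ndim != 2:
            raise TrackShapeError("scores must be 1-D or 2-D")
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise TrackShapeError(f"probe table lacks columns {missing}")
        if len(self.probes) != self.scores.shape[0]:
            raise TrackShapeError(
                f"{len(self.probes)} probes but {self.scores.shape[0]} score rows"
            )
        if not self._is_sorted():
            order = np.lexsort(
                (self.probes["start"].to_numpy(), self.probes["chrom"].to_numpy())
            )
            self.probes = self.probes.iloc[order].reset_index(drop=True)
            self.scores = self.scores[order]
        if not np.all(np.isfinite(self.scores)):
            raise TrackShapeError("scores contain non-finite values")

    def _is_sorted(self) -> bool:
        chrom = self.probes["chrom"].to_numpy()
        start = self.probes["start"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(start[1:][same] < start[:-1][same]):
            return False
        # chromosome blocks must be contiguous
        changes = np.count_nonzero(chrom[1:] != chrom[:-1])
        return changes == len(np.unique(chrom)) - 1

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_replicates(self) -> int:
        return self.scores.shape[1]

    def values(self) -> np.ndarray:
        """Single score vector; averages replicates if more than one."""
        if self.n_replicates == 1:
            return self.scores[:, 0]
        return self.scores.mean(axis=1)

    def with_scores(self, scores: np.ndarray, sample: str | None = None) -> "ProbeTrack":
        """New track over the same probes with replacement scores."""
        return ProbeTrack(self.probes, scores, self.sample if sample is None else sample)

    def chrom_slices(self) -> Iterator[tuple[str, slice]]:
        """Yield (chromosome, row-slice) per contiguous chromosome block."""
        chrom = self.probes["chrom"].to_numpy()
        if len(chrom) == 0:
            return
        breaks = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        bounds = np.concatenate(([0], breaks, [len(chrom)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            yield str(chrom[lo]), slice(int(lo), int(hi))

    def same_probes(self, other: "ProbeTrack") -> bool:
        a, b = self.probes, other.probes
        return (
            len(a) == len(b)
            and np.array_equal(a["chrom"].to_numpy(), b["chrom"].to_numpy())
            and np.array_equal(a["start"].to_numpy(), b["start"].to_numpy())
        )

    def require_same_probes(self, other: "ProbeTrack") -> None:
        if not self.same_probes(other):
            raise TrackShapeError("tracks are defined over different probe sets")


def _check_interval_frame(intervals: pd.DataFrame) -> pd.DataFrame:
    for col in ("chrom", "start", "end"):
        if col not in intervals.columns:
            raise ValueError(f"interval table lacks column {col!r}")
    intervals = intervals.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )
    if len(intervals) and (intervals["end"] <= intervals["start"]).any():
        raise ValueError("intervals must have end > start")
    same = intervals["chrom"].to_numpy()[1:] == intervals["chrom"].to_numpy()[:-1]
    overlap = intervals["start"].to_numpy()[1:] < intervals["end"].to_numpy()[:-1]
    if np.any(same & overlap):
        raise ValueError("intervals overlap within a chromosome")
    return intervals


@dataclass
class DomainSet:
    """Disjoint sorted genomic intervals continuously associated with a factor."""

    label: str
    intervals: pd.DataFrame  # chrom, start, end, n_probes, score
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = _check_interval_frame(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        if len(self.intervals) == 0:
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def sizes(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy()


@dataclass
class ElementSet:
    """Short factor-exclusive or detachment intervals with probe support counts."""

    label: str
    intervals: pd.DataFrame  # chrom, start, end, n_probes
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = _check_interval_frame(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        if len(self.intervals) == 0:
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals; output disjoint and sorted.

    Overlap means sharing at least one base (adjacent intervals that touch
    end-to-start are merged too, matching the >=1 bp window-joining rule
    applied with half-open coordinates).
    """
    if len(intervals) == 0:
        return intervals.loc[:, ["chrom", "start", "end"]].copy()
    iv = intervals.sort_values(["chrom", "start"], kind="mergesort")
    out: list[tuple[str, int, int]] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for chrom, start, end in zip(iv["chrom"], iv["start"], iv["end"]):
        if chrom == cur_chrom and start <= cur_end:
            cur_end = max(cur_end, end)
        else:
            if cur_chrom is not None:
                out.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = chrom, start, end
    out.append((cur_chrom, cur_start, cur_end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def overlap_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total base pairs shared between two interval tables."""
    total = 0
    for chrom in set(a["chrom"]).intersection(set(b["chrom"])):
        ia = a[a["chrom"] == chrom]
        ib = b[b["chrom"] == chrom]
        starts_a = ia["start"].to_numpy()
        ends_a = ia["end"].to_numpy()
        starts_b = ib["start"].to_numpy()
        ends_b = ib["end"].to_numpy()
        i = j = 0
        while i < len(starts_a) and j < len(starts_b):
            lo = max(starts_a[i], starts_b[j])
            hi = min(ends_a[i], ends_b[j])
            if hi > lo:
                total += int(hi - lo)
            if ends_a[i] <= ends_b[j]:
                i += 1
            else:
                j += 1
    return total


def interval_jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Jaccard index (shared bp over union bp) of two interval tables."""
    ma = merge_intervals(a)
    mb = merge_intervals(b)
    inter = overlap_bp(ma, mb)
    size_a = int((ma["end"] - ma["start"]).sum()) if len(ma) else 0
    size_b = int((mb["end"] - mb["start"]).sum()) if len(mb) else 0
    union = size_a + size_b - inter
    return inter / union if union > 0 else float("nan")
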