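"""Read-level quality metrics: concordance/QV and GC-binned relative depth.

Concordance of an aligned read is M / (M + X + D + I) over the CIGAR
match/mismatch/indel tallies, and QV is its Phred scale capped by the
read-length term:

    QV = min(-10*log10(1 - concordance), -10*log10(1 / (1 + read_length)))

so a perfect read of length L reports QV = -10*log10(1/(1+L)) rather than
infinity.  GC bias is summarised as the median relative depth (window depth
over the median depth of all windows) per GC-content bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentStats",
    "QVResult",
    "DepthWindow",
    "GCBiasProfile",
    "read_concordance_qv",
    "gc_bias_profile",
    "depth_windows",
]

WINDOW_SIZE = 500  # bp, GC-bias window width
GC_RANGE = (20.0, 65.0)  # percent GC covered by the profile
GC_BIN_WIDTH = 5.0  # percentage points per bin


@dataclass(frozen=True)
class AlignmentStats:
    """Per-read CIGAR tallies: matches, mismatches, deleted/inserted bases."""

    read_id: str
    M: int
    X: int
    D: int
    I: int
    read_length: int

    def __post_init__(self) -> None:
        if min(self.M, self.X, self.D, self.I) < 0:
            raise ValueError("negative alignment tallies")


@dataclass(frozen=True)
class QVResult:
    read_id: str
    concordance: float
    qv: float


def read_concordance_qv(stats: AlignmentStats) -> QVResult:
    """Concordance and Phred-scaled QV of one aligned read."""
    denom = stats.M + stats.X + stats.D + stats.I
    if denom <= 0:
        raise ValueError(f"read {stats.read_id}: all-zero alignment tallies")
    if stats.read_length <= 0:
        raise ValueError(f"read {stats.read_id}: non-positive read length")
    concordance = stats.M / denom
    cap = -10.0 * math.log10(1.0 / (1.0 + stats.read_length))
    if concordance >= 1.0:
        qv = cap
    else:
        qv = min(-10.0 * math.log10(1.0 - concordance), cap)
    return QVResult(stats.read_id, concordance, qv)


@dataclass(frozen=True)
class DepthWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gc_fraction: float
    depth: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction outside [0, 1]")
        if self.depth < 0:
            raise ValueError("negative depth")


@dataclass
class GCBiasProfile:
    """Median relative depth per GC bin over the 20-65% GC range."""

    bins: pd.DataFrame  # columns: gc_low, gc_high, median_relative_depth, n_windows
    median_depth: float
    n_windows_used: int
    n_windows_out_of_range: int


def gc_bias_profile(
    windows: Sequence[DepthWindow],
    gc_range: tuple[float, float] = GC_RANGE,
    bin_width: float = GC_BIN_WIDTH,
) -> GCBiasProfile:
    """Per-GC-bin median relative depth.

    Relative depth of a window is its depth divided by the median depth of
    *all* windows (in-range or not).  Windows with GC outside ``gc_range``
    are excluded from the bins and counted.
    """
    if not windows:
        raise ValueError("no depth windows supplied")
    depths = np.array([w.depth for w in windows], dtype=float)
    med = float(np.median(depths))
    if med <= 0:
        raise ValueError("median window depth is zero; relative depth undefined")
    gc_pct = np.array([w.gc_fraction for w in windows]) * 100.0
    rel = depths / med
    lo, hi = gc_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    rows = []
    in_range = (gc_pct >= lo) & (gc_pct <= hi)
    for b_lo, b_hi in zip(edges[:-1], edges[1:]):
        mask = (gc_pct >= b_lo) & (gc_pct < b_hi)
        if b_hi == edges[-1]:  # last bin right-closed so 65% is included
            mask |= gc_pct == b_hi
        vals = rel[mask]
        rows.append(
            {
                "gc_low": b_lo,
                "gc_high": b_hi,
                "median_relative_depth": float(np.median(vals)) if vals.size else np.nan,
                "n_windows": int(vals.size),
            }
        )
    return GCBiasProfile(
        bins=pd.DataFrame(rows),
        median_depth=med,
        n_windows_used=int(in_range.sum()),
        n_windows_out_of_range=int((~in_range).sum()),
    )


def depth_windows(
    chromosomes: dict[str, str],
    reads: Iterable[tuple[str, int, int]],
    window_size: int = WINDOW_SIZE,
) -> list[DepthWindow]:
    """Tile chromosomes into fixed windows with GC content and mean depth.

    ``reads`` are (chrom, start, end) alignment intervals.  Windows that
    contain an undetermined base (N) are dropped because their GC content
    is undefined; a trailing partial window is dropped as well.
    """
    cover: dict[str, np.ndarray] = {
        name: np.zeros(len(seq) + 1, dtype=np.int64) for name, seq in chromosomes.items()
    }
    for chrom, start, end in reads:
        arr = cover[chrom]
        s = max(0, start)
        e = min(len(arr) - 1, end)
        if e > s:
            arr[s] += 1
            arr[e] -= 1
    out: list[DepthWindow] = []
    for name, seq in chromosomes.items():
        depth = np.cumsum(cover[name][:-1])
        n_win = len(seq) // window_size
        if n_win == 0:
            continue
        arr = np.frombuffer(seq[: n_win * window_size].encode("ascii"),
                            dtype=np.uint8).reshape(n_win, window_size)
        acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        valid = acgt.all(axis=1)
        gc_counts = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)).sum(axis=1)
        depth_means = depth[: n_win * window_size].reshape(n_win, window_size).mean(axis=1)
        for k in np.flatnonzero(valid):
            out.append(DepthWindow(name, int(k) * window_size,
                                   (int(k) + 1) * window_size,
                                   gc_counts[k] / window_size,
                                   float(depth_means[k])))
    return out
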