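"""Clustered-SNP (cSNP) identification, distance histograms, Monte Carlo null.

A SNP is clustered when another SNP lies within 1-1000 bp on the same
chromosome and the two are co-supported by at least one common read; the
read-sharing condition guards against pairing calls from different
haplotypes or mapping artifacts.  Each clustered SNP is counted once, in
the distance bin of its nearest neighbour.  The null model redraws the same
number of SNP positions uniformly (without replacement) per chromosome and
counts clustered SNPs by position alone, since read identity cannot be
simulated from positions; exceedance p-values use the add-one estimator
(1 + #{null >= observed}) / (reps + 1) so that finite replication never
reports p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .variants import SNPCall

__all__ = [
    "SNPNeighborRecord",
    "DistanceBinHistogram",
    "MonteCarloNull",
    "identify_csnps",
    "distance_histogram",
    "monte_carlo_null",
    "DISTANCE_BINS",
    "MAX_CLUSTER_DISTANCE",
]

MAX_CLUSTER_DISTANCE = 1000  # bp
DISTANCE_BINS: tuple[tuple[int, int], ...] = ((1, 9), (10, 99), (100, 299), (300, 1000))


@dataclass(frozen=True)
class SNPNeighborRecord:
    snp_id: tuple  # (chrom, pos, ref, alt)
    nn_distance: Optional[int]  # bp to nearest other SNP on the chromosome
    shares_read_with_nn: bool
    clustered: bool


def identify_csnps(
    calls: Sequence[SNPCall], max_distance: int = MAX_CLUSTER_DISTANCE
) -> tuple[set, list[SNPNeighborRecord]]:
    """Find clustered SNPs and per-SNP nearest-neighbour records.

    Returns the set of clustered SNP keys and one record per input SNP.
    Multi-allelic records at the same position collapse to one position for
    distance purposes (distances are measured between point positions).
    """
    records: list[SNPNeighborRecord] = []
    clustered: set = set()
    by_chrom: dict[str, list[SNPCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda c: c.pos)
        positions = [c.pos for c in group]
        n = len(group)
        for i, call in enumerate(group):
            nn_dist: Optional[int] = None
            nn_idx: Optional[int] = None
            is_clustered = False
            shares_nn = False
            # scan outwards until beyond max_distance on both sides
            for j in range(i - 1, -1, -1):
                d = call.pos - positions[j]
                if d == 0:
                    continue  # collapsed multi-allelic site
                if nn_dist is None or d < nn_dist:
                    nn_dist, nn_idx = d, j
                if d > max_distance:
                    break
                if call.supporting_reads & group[j].supporting_reads:
                    is_clustered = True
            for j in range(i + 1, n):
                d = positions[j] - call.pos
                if d == 0:
                    continue
                if nn_dist is None or d < nn_dist:
                    nn_dist, nn_idx = d, j
                if d > max_distance:
                    break
                if call.supporting_reads & group[j].supporting_reads:
                    is_clustered = True
            if nn_idx is not None:
                shares_nn = bool(
                    call.supporting_reads & group[nn_idx].supporting_reads
                )
            is_clustered = is_clustered and nn_dist is not None and nn_dist >= 1
            if is_clustered:
                clustered.add(call.key)
            records.append(
                SNPNeighborRecord(call.key, nn_dist, shares_nn, is_clustered)
            )
    return clustered, records


@dataclass
class DistanceBinHistogram:
    counts: tuple[int, ...]  # one per bin in DISTANCE_BINS
    total_snps: int
    bins: tuple[tuple[int, int], ...] = DISTANCE_BINS

    @property
    def total_clustered(self) -> int:
        return sum(self.counts)


def distance_histogram(
    records: Sequence[SNPNeighborRecord],
    bins: tuple[tuple[int, int], ...] = DISTANCE_BINS,
) -> DistanceBinHistogram:
    """Bin clustered SNPs by nearest-neighbour distance (inclusive bounds)."""
    counts = [0] * len(bins)
    for rec in records:
        if not rec.clustered or rec.nn_distance is None:
            continue
        for k, (lo, hi) in enumerate(bins):
            if lo <= rec.nn_distance <= hi:
                counts[k] += 1
                break
    return DistanceBinHistogram(tuple(counts), total_snps=len(records), bins=bins)


@dataclass
class MonteCarloNull:
    reps: int
    seed: int
    expected: tuple[float, ...]  # per-bin mean null count
    observed: Optional[tuple[int, ...]]
    p_values: Optional[tuple[float, ...]]  # add-one exceedance estimates
    bins: tuple[tuple[int, int], ...] = DISTANCE_BINS


def _sample_positions(
    rng: np.random.Generator, length: int, n: int, reps: int
) -> np.ndarray:
    """(reps, n) uniform integer positions in [0, length), unique per row."""
    if n > length:
        raise ValueError(f"cannot place {n} SNPs on a {length}-bp chromosome")
    if n == 0:
        return np.empty((reps, 0), dtype=np.int64)
    if 4 * n >= length:
        # dense case: exact without-replacement draw per row
        return np.stack([rng.choice(length, size=n, replace=False) for _ in range(reps)])
    pos = rng.integers(0, length, size=(reps, n))
    for _ in range(64):
        s = np.sort(pos, axis=1)
        bad = (np.diff(s, axis=1) == 0).any(axis=1)
        if not bad.any():
            break
        pos[bad] = rng.integers(0, length, size=(int(bad.sum()), n))
    return pos


def _bin_counts_by_position(
    pos: np.ndarray, bins: tuple[tuple[int, int], ...], max_distance: int
) -> np.ndarray:
    """Per-rep clustered-SNP counts per bin from a (reps, n) position array."""
    reps = pos.shape[0]
    out = np.zeros((reps, len(bins)), dtype=np.int64)
    if pos.shape[1] < 2:
        return out
    s = np.sort(pos, axis=1)
    gaps = np.diff(s, axis=1)
    inf = np.iinfo(np.int64).max
    left = np.concatenate([np.full((reps, 1), inf), gaps], axis=1)
    right = np.concatenate([gaps, np.full((reps, 1), inf)], axis=1)
    nn = np.minimum(left, right)
    for k, (lo, hi) in enumerate(bins):
        out[:, k] = ((nn >= lo) & (nn <= hi) & (nn <= max_distance)).sum(axis=1)
    return out


def monte_carlo_null(
    n_snps_per_chrom: Mapping[str, int],
    chrom_lengths: Mapping[str, int],
    reps: int = 100_000,
    seed: int = 0,
    observed: Optional[Sequence[int]] = None,
    bins: tuple[tuple[int, int], ...] = DISTANCE_BINS,
    max_distance: int = MAX_CLUSTER_DISTANCE,
) -> MonteCarloNull:
    """Null expectation (and exceedance p-values) for per-bin cSNP counts.

    For each replicate the observed number of SNPs on each chromosome is
    re-placed uniformly without replacement, clustered SNPs are counted per
    distance bin by position alone, and counts are summed over chromosomes.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    totals = np.zeros((reps, len(bins)), dtype=np.int64)
    for chrom, n in n_snps_per_chrom.items():
        length = chrom_lengths[chrom]
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        pos = _sample_positions(rng, length, n, reps)
        totals += _bin_counts_by_position(pos, bins, max_distance)
    expected = tuple(float(x) for x in totals.mean(axis=0))
    p_values = None
    obs_t = None
    if observed is not None:
        obs = np.asarray(observed, dtype=np.int64)
        if obs.shape != (len(bins),):
            raise ValueError("observed must have one count per bin")
        p_values = tuple(
            float((1 + int((totals[:, k] >= obs[k]).sum())) / (reps + 1))
            for k in range(len(bins))
        )
        obs_t = tuple(int(x) for x in obs)
    return MonteCarloNull(reps, seed, expected, obs_t, p_values, bins)
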