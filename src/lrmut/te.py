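"""TE insertion classification, TSD detection, non-B DNA motif scanning,
window enrichment, and duplication-mechanism calls.

An insertion is *complex* when it carries an immediate flanking deletion
and/or a linked duplication, and *simple* otherwise.  A target-site
duplication (TSD) is the longest identical sequence (4-30 bp) immediately
flanking both sides of the inserted block.  hAT-family (hobo) breakpoints
are checked against the 8-bp transposase recognition motif nTnnnnAn.

The non-B motif scanner implements a documented grammar for seven classes:

* G_Quadruplex_Motif  - >= 4 maximal G-tracts (>= 3 G each) chained by the
                        shortest 1-7 nt loops; C-tract pattern on "-"
* Short_Tandem_Repeat - unit 1-9 bp, >= 5 copies, total >= 10 bp
* Direct_Repeat       - unit >= 10 bp repeated once, spacer <= 10 bp
* Inverted_Repeat     - arms >= 6 bp reverse-complementary, spacer <= 100 bp
* Mirror_Repeat       - arms >= 6 bp mirror-symmetric, spacer <= 100 bp
* Z_DNA_Motif         - >= 10 bp of alternating purine/pyrimidine built from
                        GC/CG/GT/TG/AC/CA steps (AT/TA steps break the run)
* A_Phased_Repeat     - >= 3 A-tracts (3-9 bp; T-tracts on "-") with centre
                        spacing 8-12 bp

Within a class the reported hits are a maximum-cardinality set of
non-overlapping candidate intervals (earliest-end greedy); overlaps across
classes are allowed and the per-window total is the sum over classes.  Any
non-ACGT base breaks motifs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .simulate import revcomp
from .stats import TestResult, wilcoxon_one_sided

logger = logging.getLogger(__name__)

__all__ = [
    "TEInsertionCall",
    "LinkedDuplication",
    "NonBMotifHit",
    "WindowMotifCounts",
    "DuplicationCall",
    "detect_tsd",
    "classify_transposition",
    "hobo_motif_match",
    "scan_nonb_motifs",
    "window_motif_enrichment",
    "classify_duplication_mechanism",
    "MOTIF_CLASSES",
    "NAHR_MIN_HOMOLOGY",
]

MOTIF_CLASSES = (
    "A_Phased_Repeat",
    "G_Quadruplex_Motif",
    "Direct_Repeat",
    "Inverted_Repeat",
    "Mirror_Repeat",
    "Short_Tandem_Repeat",
    "Z_DNA_Motif",
)
TSD_MIN, TSD_MAX = 4, 30
NAHR_MIN_HOMOLOGY = 62  # bp of breakpoint homology implying NAHR


@dataclass(frozen=True)
class LinkedDuplication:
    span: tuple  # (chrom, start, end) of the duplicated block
    microhomology_length: int
    de_novo_insertion_length: int


@dataclass
class TEInsertionCall:
    chrom: str
    start: int  # inserted block, 0-based half-open, in the carrier genome
    end: int
    te_family: str
    tsd_sequence: Optional[str] = None
    flank_deletion_length: int = 0
    linked_duplication: Optional[LinkedDuplication] = None
    breakpoint_kmer: Optional[str] = None  # 8-mer at the integration target

    @property
    def classification(self) -> str:
        if self.flank_deletion_length > 0 or self.linked_duplication is not None:
            return "complex"
        return "simple"


def detect_tsd(chromosomes: dict, call: TEInsertionCall,
               min_tsd: int = TSD_MIN, max_tsd: int = TSD_MAX) -> Optional[str]:
    """Longest identical flank (min_tsd..max_tsd bp) on both sides of the block.

    Returns None when no flank of at least ``min_tsd`` matches, or when a
    breakpoint is too close to a contig edge to test (logged).
    """
    seq = chromosomes[call.chrom]
    if call.start < min_tsd or call.end + min_tsd > len(seq):
        logger.warning("insertion at %s:%d: breakpoint at contig edge, TSD "
                       "undetermined", call.chrom, call.start)
        return None
    limit = min(max_tsd, call.start, len(seq) - call.end)
    best = None
    for k in range(min_tsd, limit + 1):
        if seq[call.start - k : call.start] == seq[call.end : call.end + k]:
            best = seq[call.start - k : call.start]
    return best


def hobo_motif_match(kmer: str) -> bool:
    """nTnnnnAn: T at position 2 and A at position 7 of the 8-mer."""
    if len(kmer) != 8:
        raise ValueError("motif check requires an 8-mer")
    return kmer[1] == "T" and kmer[6] == "A"


def classify_transposition(call: TEInsertionCall) -> tuple[str, Optional[bool]]:
    """(simple|complex, motif match) for an insertion call.

    The motif is only defined for hobo-family calls with a resolved
    breakpoint 8-mer; other families return None (logged once per family).
    """
    motif: Optional[bool] = None
    if call.te_family == "hobo":
        if call.breakpoint_kmer is not None:
            motif = hobo_motif_match(call.breakpoint_kmer)
    else:
        logger.debug("family %s: no transposase motif defined, check skipped",
                     call.te_family)
    return call.classification, motif


@dataclass(frozen=True)
class NonBMotifHit:
    motif_class: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")


def _greedy_nonoverlap(cands: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Maximum-cardinality non-overlapping subset (earliest-end greedy).

    The count of kept hits is the maximum independent set size over the
    candidate intervals, which makes per-class totals invariant under
    reverse complementation of the scanned sequence.
    """
    out: list[tuple[int, int, str]] = []
    last_end = -1
    for s, e, strand in sorted(cands, key=lambda c: (c[1], c[0])):
        if s >= last_end:
            out.append((s, e, strand))
            last_end = e
    return out


def _g4_one_strand(seq: str, base: str) -> list[tuple[int, int]]:
    """Greedy quadruplex parse: tracts are maximal runs of >= 3 ``base``;
    from each starting tract the shortest 1-7 nt loop to the next tract is
    taken repeatedly; >= 4 tracts make a hit ending at the last tract."""
    runs = [(m.start(), m.end()) for m in re.finditer(base + "{3,}", seq)]
    starts = {s: e for s, e in runs}
    hits = []
    for s, e in runs:
        cursor, tracts = e, 1
        while True:
            nxt = None
            for gap in range(1, 8):
                if cursor + gap in starts:
                    nxt = cursor + gap
                    break
            if nxt is None:
                break
            cursor, tracts = starts[nxt], tracts + 1
        if tracts >= 4:
            hits.append((s, cursor))
    return hits


def _scan_g4(seq: str) -> list[tuple[int, int, str]]:
    cands = [(s, e, "+") for s, e in _g4_one_strand(seq, "G")]
    cands += [(s, e, "-") for s, e in _g4_one_strand(seq, "C")]
    return cands


def _str_run(seq: str, i: int, unit: int) -> int:
    """Length of the self-aligned run seq[j] == seq[j-unit] starting at i."""
    j = i + unit
    while j < len(seq) and seq[j] == seq[j - unit]:
        j += 1
    return j - i


def _scan_str(seq: str) -> list[tuple[int, int, str]]:
    n = len(seq)
    cands = []
    for i in range(n):
        best = 0
        for unit in range(1, 10):
            if i + unit > n:
                break
            run = _str_run(seq, i, unit)
            if run >= max(5 * unit, 10) and run > best:
                best = run
        if best:
            cands.append((i, i + best, "+"))
    return cands


def _scan_direct(seq: str, min_unit: int = 10, max_spacer: int = 10) -> list:
    """Unit >= 10 bp repeated once with spacer <= 10 bp, seeded by k-mer pairs.

    For unit start pair (i, j) with offset d = j - i and common-prefix
    length m, the widest legal repeat takes u = min(m, d) (spacer d - u);
    it is a hit when the spacer fits.
    """
    n = len(seq)
    if n < 2 * min_unit:
        return []
    index: dict[str, list[int]] = {}
    for i in range(n - min_unit + 1):
        index.setdefault(seq[i : i + min_unit], []).append(i)
    cands = []
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai, i in enumerate(positions):
            for j in positions[ai + 1 :]:
                d = j - i
                if d < min_unit:
                    continue
                m = min_unit
                while j + m < n and seq[i + m] == seq[j + m]:
                    m += 1
                u = min(m, d)
                if d - u <= max_spacer:
                    cands.append((i, j + u, "+"))
    return cands


def _scan_palindrome(seq: str, mirror: bool, min_arm: int = 6,
                     max_spacer: int = 100) -> list:
    """Inverted (revcomp arms) or mirror (reversed arms) repeats."""
    n = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    cands = []
    for center in range(n):
        for g in range(0, max_spacer + 1):
            # arms end at center and start at center+g
            a = 0
            while (center - a - 1 >= 0 and center + g + a < n):
                left = seq[center - a - 1]
                right = seq[center + g + a]
                ok = (left == right) if mirror else (comp[left] == right)
                if not ok:
                    break
                a += 1
            if a >= min_arm:
                cands.append((center - a, center + g + a, "+"))
    return cands


_Z_STEPS = {"GC", "CG", "GT", "TG", "AC", "CA"}


def _scan_zdna(seq: str, min_len: int = 10) -> list:
    n = len(seq)
    cands = []
    i = 0
    while i < n - 1:
        j = i
        while j < n - 1 and seq[j : j + 2] in _Z_STEPS:
            j += 1
        if j - i + 1 >= min_len:
            cands.append((i, j + 1, "+"))
        i = max(j, i + 1)
    return cands


def _a_tracts(seq: str, base: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(base + "{3,9}", seq)
            if not (m.start() > 0 and seq[m.start() - 1] == base)
            and not (m.end() < len(seq) and seq[m.end()] == base)]


def _scan_aphased(seq: str) -> list:
    cands = []
    for base, strand in (("A", "+"), ("T", "-")):
        tracts = _a_tracts(seq, base)
        centers = [(s + e) / 2 for s, e in tracts]
        i = 0
        while i < len(tracts):
            j = i
            while (j + 1 < len(tracts)
                   and 8 <= centers[j + 1] - centers[j] <= 12):
                j += 1
            if j - i + 1 >= 3:
                cands.append((tracts[i][0], tracts[j][1], strand))
            i = j + 1
    return cands


_SCANNERS = {
    "G_Quadruplex_Motif": _scan_g4,
    "Short_Tandem_Repeat": _scan_str,
    "Direct_Repeat": lambda s: _scan_direct(s),
    "Inverted_Repeat": lambda s: _scan_palindrome(s, mirror=False),
    "Mirror_Repeat": lambda s: _scan_palindrome(s, mirror=True),
    "Z_DNA_Motif": _scan_zdna,
    "A_Phased_Repeat": _scan_aphased,
}


def scan_nonb_motifs(seq: str, chrom: str = "seq") -> list[NonBMotifHit]:
    """All non-B motif hits in a sequence under the module grammar.

    The sequence is split on non-ACGT characters (N breaks motifs) and each
    segment scanned per class; per-class hits are made maximal and
    non-overlapping greedily.
    """
    seq = seq.upper()
    hits: list[NonBMotifHit] = []
    for m in re.finditer("[ACGT]+", seq):
        segment, off = m.group(), m.start()
        for cls, scanner in _SCANNERS.items():
            cands = scanner(segment)
            for s, e, strand in _greedy_nonoverlap(cands):
                hits.append(NonBMotifHit(cls, chrom, off + s, off + e, strand))
    hits.sort(key=lambda h: (h.start, h.motif_class))
    return hits


@dataclass
class WindowMotifCounts:
    chrom: str
    start: int
    end: int
    group: str  # "complex" | "simple" | "random"
    total_motif_count: int
    per_class: dict


def _window_counts(chromosomes: dict, chrom: str, start: int, end: int,
                   group: str) -> WindowMotifCounts:
    L = len(chromosomes[chrom])
    s, e = max(0, start), min(L, end)
    if (s, e) != (start, end):
        logger.warning("window %s:%d-%d clipped to contig bounds", chrom, start, end)
    hits = scan_nonb_motifs(chromosomes[chrom][s:e], chrom)
    per_class = {cls: 0 for cls in MOTIF_CLASSES}
    for h in hits:
        per_class[h.motif_class] += 1
    return WindowMotifCounts(chrom, s, e, group, len(hits), per_class)


def window_motif_enrichment(
    sites_by_group: dict,
    chromosomes: dict,
    flank: int = 200,
    n_random: int = 1000,
    seed: int = 0,
) -> tuple[list[WindowMotifCounts], dict]:
    """Non-B motif counts around breakpoints vs. random windows.

    ``sites_by_group`` maps group name ("complex", "simple") to a list of
    (chrom, pos) breakpoints; each site contributes a +/- ``flank`` window.
    ``n_random`` control windows of the same total width are drawn
    uniformly (seeded).  One-sided rank-sum tests compare complex > simple,
    complex > random and simple > random on the total motif counts.
    """
    if not sites_by_group or any(not v for v in sites_by_group.values()):
        raise ValueError("every site group must be non-empty")
    rng = np.random.default_rng(seed)
    rows: list[WindowMotifCounts] = []
    for group, sites in sites_by_group.items():
        for chrom, pos in sites:
            rows.append(_window_counts(chromosomes, chrom, pos - flank, pos + flank,
                                       group))
    names = sorted(chromosomes)
    lengths = np.array([len(chromosomes[c]) for c in names], dtype=float)
    width = 2 * flank
    for _ in range(n_random):
        c = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
        hi = len(chromosomes[c]) - width
        if hi <= 0:
            raise ValueError("genome too short for random control windows")
        s = int(rng.integers(0, hi))
        rows.append(_window_counts(chromosomes, c, s, s + width, "random"))
    totals = {g: [r.total_motif_count for r in rows if r.group == g]
              for g in list(sites_by_group) + ["random"]}
    tests: dict[str, TestResult] = {}
    pairs = [("complex", "simple"), ("complex", "random"), ("simple", "random")]
    for hi_g, lo_g in pairs:
        if hi_g in totals and lo_g in totals:
            tests[f"{hi_g}_gt_{lo_g}"] = wilcoxon_one_sided(
                totals[hi_g], totals[lo_g], alternative="greater")
    return rows, tests


@dataclass
class DuplicationCall:
    span: tuple  # (chrom, start, end)
    orientation: str  # "tandem" | "inverted"
    breakpoint_homology_length: int
    de_novo_insertion_length: int = 0


def classify_duplication_mechanism(dup: DuplicationCall) -> dict:
    """NAHR for >= 62 bp of breakpoint homology, error-prone repair otherwise."""
    if dup.breakpoint_homology_length < 0 or dup.de_novo_insertion_length < 0:
        raise ValueError("lengths must be non-negative")
    if dup.breakpoint_homology_length >= NAHR_MIN_HOMOLOGY:
        return {"mechanism": "NAHR",
                "breakpoint_homology_length": dup.breakpoint_homology_length}
    return {
        "mechanism": "repair",
        "microhomology_length": dup.breakpoint_homology_length,
        "de_novo_insertion_length": dup.de_novo_insertion_length,
    }
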