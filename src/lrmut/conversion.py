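"""TE gene-conversion detection by iterative fragment growth and exact
donor search.

Clustered SNPs are seeded into fragments (nearest cSNP pairs 1-1000 bp
apart, padded symmetrically to at least 50 bp), the fragment sequence is
rebuilt with the derived alleles substituted in, and all exact occurrences
of that sequence elsewhere in the genome (both strands) are candidate
donors.  Each donor-positive fragment is then greedily merged with its
nearest SNP (clustered or not, within 1000 bp) and re-searched; merging
stops when the extended fragment loses all donors, and the last
donor-positive extent defines the event.  "Perfect match" is strict: a
mismatch anywhere in the fragment, diagnostic or not, disqualifies a donor.

Donor selection prefers the minimum same-chromosome distance (gap between
interval ends, 0 when adjacent); when every candidate sits on another
arm/chromosome one is chosen at random under the caller's seed.  Events are
classified proximal (<= 10 kb), distal (> 10 kb) or interarm, treating each
chromosome name as one arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .simulate import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "DonorCandidate",
    "ConversionEvent",
    "ConversionGCSummary",
    "seed_fragments",
    "find_perfect_donors",
    "build_conversion_events",
    "classify_conversion",
    "conversion_gc_direction",
    "MIN_FRAGMENT_LENGTH",
    "PROXIMAL_MAX_DISTANCE",
]

MIN_FRAGMENT_LENGTH = 50  # bp; shorter fragments are padded symmetrically
PROXIMAL_MAX_DISTANCE = 10_000  # bp; proximal/distal boundary (inclusive)
MERGE_MAX_DISTANCE = 1000  # bp; nearest-SNP merge radius


@dataclass
class Fragment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    member_snps: list  # [(pos, ref, alt)] sorted by pos
    clipped: bool = False  # extension hit a chromosome boundary

    def sequence(self, chromosomes: dict) -> str:
        """Fragment sequence with the derived (alt) alleles substituted in."""
        seq = list(chromosomes[self.chrom][self.start : self.end])
        for pos, _ref, alt in self.member_snps:
            seq[pos - self.start] = alt
        return "".join(seq)


@dataclass(frozen=True)
class DonorCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    distance: Optional[int]  # same-arm gap in bp; None when interarm
    divergence: Optional[float] = None  # TE copy divergence vs. consensus
    te_coverage: Optional[float] = None  # donor TE length / consensus length


@dataclass
class ConversionEvent:
    chrom: str
    start: int  # final donor-positive fragment extent
    end: int
    converted_snps: list  # [(pos, ref, alt)], >= 2
    candidate_donors: list
    chosen_donor: DonorCandidate
    donor_multiplicity: str  # "unique" | "multiple"
    distance_class: str
    min_tract_length: int  # span between outermost converted SNPs


def seed_fragments(csnps: Sequence[tuple], chromosomes: dict) -> list[Fragment]:
    """Pair each clustered SNP with its nearest clustered neighbour.

    ``csnps`` are (chrom, pos, ref, alt) tuples.  Pairs 1-1000 bp apart
    become fragments spanning both SNPs; fragments shorter than 50 bp are
    extended symmetrically to 50 bp (clipped and flagged at chromosome
    boundaries).
    """
    by_chrom: dict[str, list[tuple]] = {}
    for s in csnps:
        by_chrom.setdefault(s[0], []).append(s)
    fragments: list[Fragment] = []
    seen_pairs: set = set()
    for chrom, group in by_chrom.items():
        group.sort(key=lambda s: s[1])
        n = len(group)
        for i, snp in enumerate(group):
            best_j, best_d = None, None
            for j in (i - 1, i + 1):
                if 0 <= j < n:
                    d = abs(group[j][1] - snp[1])
                    if d >= 1 and (best_d is None or d < best_d):
                        best_j, best_d = j, d
            if best_j is None or best_d is None or best_d > MERGE_MAX_DISTANCE:
                continue
            lo_i, hi_i = sorted((i, best_j))
            if (chrom, lo_i, hi_i) in seen_pairs:
                continue
            seen_pairs.add((chrom, lo_i, hi_i))
            a, b = group[lo_i], group[hi_i]
            start, end = a[1], b[1] + 1
            clipped = False
            if end - start < MIN_FRAGMENT_LENGTH:
                pad = MIN_FRAGMENT_LENGTH - (end - start)
                start -= pad // 2
                end += pad - pad // 2
                L = len(chromosomes[chrom])
                if start < 0:
                    end = min(L, end - start)
                    start, clipped = 0, True
                if end > L:
                    start = max(0, start - (end - L))
                    end, clipped = L, True
            # every known clustered SNP inside the (padded) span contributes
            # its derived allele, or the fragment sequence would misrepresent
            # the converted haplotype
            members = [(s[1], s[2], s[3]) for s in group if start <= s[1] < end]
            fragments.append(Fragment(chrom, start, end, members, clipped))
    return fragments


def _occurrences(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _te_annotation_for(interval: tuple, te_annotation, consensus_lengths) -> tuple:
    """(divergence, te_coverage) when the interval falls inside an annotated TE."""
    if te_annotation is None:
        return None, None
    chrom, start, end = interval
    for te in te_annotation:
        if te["chrom"] == chrom and te["start"] <= start and end <= te["end"]:
            cov = None
            if consensus_lengths and te.get("family") in consensus_lengths:
                cov = (te["end"] - te["start"]) / consensus_lengths[te["family"]]
            return te.get("divergence"), cov
    return None, None


def find_perfect_donors(
    fragment: Fragment,
    chromosomes: dict,
    te_annotation: Optional[Sequence[dict]] = None,
    consensus_lengths: Optional[dict] = None,
) -> list[DonorCandidate]:
    """All exact genomic occurrences of the fragment's derived sequence.

    Both strands are searched; any occurrence overlapping the acceptor span
    is excluded.  Occurrences inside annotated TEs carry the copy's
    divergence and its coverage of the family consensus.
    """
    frag_seq = fragment.sequence(chromosomes)
    rc = revcomp(frag_seq)
    L = len(frag_seq)
    donors: list[DonorCandidate] = []
    for chrom, seq in chromosomes.items():
        for strand, needle in (("+", frag_seq), ("-", rc)):
            if strand == "-" and rc == frag_seq:
                continue  # palindromic fragment: avoid double-counting
            for pos in _occurrences(seq, needle):
                s, e = pos, pos + L
                if chrom == fragment.chrom and s < fragment.end and fragment.start < e:
                    continue  # the acceptor locus itself
                dist = None
                if chrom == fragment.chrom:
                    dist = max(0, max(s, fragment.start) - min(e, fragment.end))
                div, cov = _te_annotation_for((chrom, s, e), te_annotation,
                                              consensus_lengths)
                donors.append(DonorCandidate(chrom, s, e, strand, dist, div, cov))
    return donors


def _nearest_snp_outside(fragment: Fragment, all_snps_sorted: dict) -> Optional[tuple]:
    """Nearest SNP within 1000 bp of the fragment span, not already a member."""
    group = all_snps_sorted.get(fragment.chrom, [])
    member_pos = {p for p, _r, _a in fragment.member_snps}
    best, best_d = None, None
    for snp in group:
        pos = snp[1]
        if pos in member_pos or (fragment.start <= pos < fragment.end):
            continue
        d = fragment.start - pos if pos < fragment.start else pos - fragment.end + 1
        if d <= MERGE_MAX_DISTANCE and (best_d is None or d < best_d):
            best, best_d = snp, d
    return best


def build_conversion_events(
    fragments: Sequence[Fragment],
    all_snps: Sequence[tuple],
    chromosomes: dict,
    seed: int = 0,
    te_annotation: Optional[Sequence[dict]] = None,
    consensus_lengths: Optional[dict] = None,
) -> list[ConversionEvent]:
    """Grow donor-positive fragments and assemble conversion events.

    ``all_snps`` are (chrom, pos, ref, alt) for every filtered SNP (the
    merge step may absorb unclustered SNPs).  Events whose converted-SNP
    sets are subsets of another event's are dropped as duplicates of the
    same underlying tract.
    """
    rng = np.random.default_rng(seed)
    snps_sorted: dict[str, list[tuple]] = {}
    for s in all_snps:
        snps_sorted.setdefault(s[0], []).append(s)
    for group in snps_sorted.values():
        group.sort(key=lambda s: s[1])
    def _members(chrom: str, start: int, end: int) -> list[tuple]:
        return sorted((s[1], s[2], s[3]) for s in snps_sorted.get(chrom, [])
                      if start <= s[1] < end)

    events: list[ConversionEvent] = []
    for frag in fragments:
        # re-materialise members from the full call set: padding may have
        # pulled additional SNPs into the span
        current = Fragment(frag.chrom, frag.start, frag.end,
                           _members(frag.chrom, frag.start, frag.end)
                           or list(frag.member_snps), frag.clipped)
        donors = find_perfect_donors(current, chromosomes)
        if not donors:
            continue
        while True:
            nxt = _nearest_snp_outside(current, snps_sorted)
            if nxt is None:
                break
            new_start = min(current.start, nxt[1])
            new_end = max(current.end, nxt[1] + 1)
            merged = Fragment(current.chrom, new_start, new_end,
                              _members(current.chrom, new_start, new_end))
            # any exact occurrence of the longer fragment must extend an
            # occurrence of the current one, so only extensions of known
            # donors need checking
            new_donors = _extend_donors(donors, current, merged, chromosomes)
            if not new_donors:
                break  # the event boundary stays at the pre-merge extent
            current, donors = merged, new_donors
        if len(current.member_snps) < 2:
            continue
        donors = [_annotate_donor(d, te_annotation, consensus_lengths)
                  for d in donors]
        chosen = _choose_donor(donors, rng)
        multiplicity = "multiple" if len(donors) >= 2 else "unique"
        events.append(ConversionEvent(
            chrom=current.chrom,
            start=current.start,
            end=current.end,
            converted_snps=sorted(current.member_snps),
            candidate_donors=donors,
            chosen_donor=chosen,
            donor_multiplicity=multiplicity,
            distance_class=classify_conversion_donor(chosen),
            min_tract_length=(current.member_snps[-1][0]
                              - current.member_snps[0][0] + 1),
        ))
    return _dedupe_events(events)


def _annotate_donor(d: DonorCandidate, te_annotation, consensus_lengths
                    ) -> DonorCandidate:
    if te_annotation is None:
        return d
    div, cov = _te_annotation_for((d.chrom, d.start, d.end), te_annotation,
                                  consensus_lengths)
    return DonorCandidate(d.chrom, d.start, d.end, d.strand, d.distance, div, cov)


def _extend_donors(donors: Sequence[DonorCandidate], old: Fragment,
                   new: Fragment, chromosomes: dict) -> list[DonorCandidate]:
    """Donors of the extended fragment, verified locally at each candidate."""
    frag_seq = new.sequence(chromosomes)
    rc = revcomp(frag_seq)
    left = old.start - new.start
    right = new.end - old.end
    out = []
    for d in donors:
        if d.strand == "+":
            s, e = d.start - left, d.end + right
        else:
            s, e = d.start - right, d.end + left
        seq = chromosomes[d.chrom]
        if s < 0 or e > len(seq):
            continue
        if d.chrom == new.chrom and s < new.end and new.start < e:
            continue
        if seq[s:e] != (frag_seq if d.strand == "+" else rc):
            continue
        dist = None
        if d.chrom == new.chrom:
            dist = max(0, max(s, new.start) - min(e, new.end))
        out.append(DonorCandidate(d.chrom, s, e, d.strand, dist))
    return out


def _choose_donor(donors: Sequence[DonorCandidate],
                  rng: np.random.Generator) -> DonorCandidate:
    same_arm = [d for d in donors if d.distance is not None]
    if same_arm:
        return min(same_arm, key=lambda d: (d.distance, d.chrom, d.start))
    idx = int(rng.integers(len(donors)))
    return donors[idx]


def _dedupe_events(events: list[ConversionEvent]) -> list[ConversionEvent]:
    """Drop events whose converted-SNP set is contained in another event's."""
    keyed = [(frozenset((p for p, _r, _a in ev.converted_snps)), ev) for ev in events]
    out = []
    for i, (snps_i, ev) in enumerate(keyed):
        redundant = any(
            (snps_i < snps_j) or (snps_i == snps_j and j < i)
            for j, (snps_j, _e) in enumerate(keyed) if j != i
        )
        if not redundant:
            out.append(ev)
    return out


def classify_conversion_donor(donor: DonorCandidate) -> str:
    if donor is None:
        raise ValueError("event has no chosen donor")
    if donor.distance is None:
        return "interarm"
    return "proximal" if donor.distance <= PROXIMAL_MAX_DISTANCE else "distal"


def classify_conversion(event: ConversionEvent) -> str:
    """Distance class of an event from its chosen donor."""
    return classify_conversion_donor(event.chosen_donor)


WEAK = frozenset("AT")
STRONG = frozenset("GC")


@dataclass
class ConversionGCSummary:
    n_weak_to_strong: int
    n_strong_to_weak: int
    n_excluded: int  # W<->W and S<->S changes
    p_value: float  # two-sided binomial vs. 0.5


def conversion_gc_direction(events: Sequence[ConversionEvent]) -> ConversionGCSummary:
    """GC bias of conversion: weak->strong vs. strong->weak counts at
    converted sites, with a two-sided binomial test against symmetry."""
    ws = sw = excl = 0
    for ev in events:
        for _pos, ref, alt in ev.converted_snps:
            if ref in WEAK and alt in STRONG:
                ws += 1
            elif ref in STRONG and alt in WEAK:
                sw += 1
            else:
                excl += 1
    n = ws + sw
    p = 1.0 if n == 0 else float(sps.binomtest(ws, n, 0.5, alternative="two-sided").pvalue)
    return ConversionGCSummary(ws, sw, excl, p)
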