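"""Synthetic genomes with planted TE paralogs, conversion tracts, insertions,
and per-read support tables.

The generator emulates the substrate the downstream analyses assume: a
multi-chromosome genome carrying diverged paralogous TE copies whose
differing sites act as diagnostic SNPs; gene-conversion tracts that copy a
donor segment onto an acceptor paralog (tract lengths drawn from a
log-normal with a 135-bp median); TE insertions with target-site
duplications and optional flanking deletions (3-380 bp) or templated
duplications with microhomology; and per-SNP read support with the VAF
structure of a largely homozygous inbred individual sequenced at a given
coverage and per-base error rate.

All coordinates are 0-based half-open.  Every stochastic step draws from a
generator derived from ``config.seed`` plus a fixed per-stage offset, so a
single seed reproduces the entire genome byte-for-byte.  Edits never
overlap; placement resamples up to 100 times and then fails.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .variants import SNPCall

logger = logging.getLogger(__name__)

__all__ = [
    "TEFamilyModel",
    "TECopy",
    "TruthConversion",
    "TruthInsertion",
    "TruthSNP",
    "SimulatedGenome",
    "SimulationConfig",
    "default_te_families",
    "generate_reference",
    "spike_conversions",
    "spike_insertions",
    "spike_background_snps",
    "simulate_read_support",
    "ReadSupport",
]

MAX_PLACEMENT_RETRIES = 100
_EDGE_PAD = 6000  # bp kept free of planted features at chromosome ends

# per-stage RNG stream offsets (mixed with config.seed)
_S_REFERENCE, _S_CONVERSION, _S_INSERTION, _S_READS, _S_BGSNP = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class TEFamilyModel:
    """A TE family: consensus sequence, class, and integration signature."""

    name: str
    consensus: str
    te_class: str  # "DNA" | "LTR" | "non-LTR"
    tsd_length: int
    recognition_motif: Optional[str] = None  # degenerate 8-mer, N = any base

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus) - set("ACGT"):
            raise ValueError(f"family {self.name}: consensus must be non-empty ACGT")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        if self.te_class not in ("DNA", "LTR", "non-LTR"):
            raise ValueError(f"unknown te_class {self.te_class!r}")


@dataclass(frozen=True)
class TECopy:
    copy_id: str
    family: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" | "-"
    divergence: float  # realized per-site divergence from consensus
    duplicate_group: Optional[str] = None  # shared by byte-identical copies


@dataclass(frozen=True)
class TruthConversion:
    event_id: str
    chrom: str
    tract_start: int  # planted tract span on the acceptor
    tract_end: int
    acceptor_copy: str
    donor_copy: str
    donor_chrom: str
    donor_start: int
    donor_end: int
    converted_sites: tuple  # ((pos, ref, alt), ...) sorted by pos
    distance_class: str  # proximal | distal | interarm
    donor_distance: Optional[int]  # same-arm gap in bp, None if interarm
    n_identical_donors: int

    @property
    def min_tract_length(self) -> int:
        return self.converted_sites[-1][0] - self.converted_sites[0][0] + 1


@dataclass(frozen=True)
class DuplicationTruth:
    source_chrom: str
    source_start: int
    length: int
    microhomology_length: int
    de_novo_insertion_length: int


@dataclass(frozen=True)
class TruthInsertion:
    insertion_id: str
    chrom: str
    start: int  # inserted block in the edited genome
    end: int
    family: str
    classification: str  # "simple" | "complex"
    tsd_sequence: Optional[str]
    flank_deletion_length: int
    duplication: Optional[DuplicationTruth]
    breakpoint_kmer: str  # 8-mer at the pre-insertion target site


@dataclass(frozen=True)
class TruthSNP:
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "homozygous" | "heterozygous"
    origin: str  # "conversion" | "background"
    individuals: tuple = ("A", "B")  # which individuals carry the variant

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    ``tract_median``/``tract_sigma`` parameterise a log-normal tract-length
    distribution with the given median.  ``per_base_error`` is the total
    per-base error of a consensus read, split 80/10/10 between
    substitutions, deletions and insertions.
    """

    seed: int
    n_chromosomes: int = 3
    chromosome_length: int = 5_000_000
    gc_content: float = 0.42
    te_families: Optional[tuple[TEFamilyModel, ...]] = None
    copies_per_family: int = 4
    n_exact_duplicates: int = 2  # extra byte-identical donor copies (one family)
    te_copy_divergence: float = 0.02
    tract_median: float = 135.0
    tract_sigma: float = 0.6
    deletion_size_range: tuple[int, int] = (3, 380)
    duplication_size_range: tuple[int, int] = (45, 600)
    coverage: float = 50.0
    per_base_error: float = 2.5e-4
    read_length_median: int = 4500
    sex_chromosomes: tuple = ()

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content outside [0, 1]")
        if not (0.0 <= self.te_copy_divergence <= 1.0):
            raise ValueError("te_copy_divergence outside [0, 1]")
        if not (0.0 <= self.per_base_error <= 1.0):
            raise ValueError("per_base_error outside [0, 1]")
        if self.deletion_size_range[0] > self.deletion_size_range[1]:
            raise ValueError("deletion_size_range not ordered")
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")


@dataclass
class SimulatedGenome:
    chromosomes: dict  # name -> sequence (str)
    te_registry: list = field(default_factory=list)  # list[TECopy]
    te_families: dict = field(default_factory=dict)  # name -> TEFamilyModel
    truth_conversions: list = field(default_factory=list)
    truth_insertions: list = field(default_factory=list)
    truth_snps: list = field(default_factory=list)
    inserted_bases: int = 0
    deleted_bases: int = 0
    original_lengths: dict = field(default_factory=dict)

    def copy_sequence(self, copy: TECopy) -> str:
        return self.chromosomes[copy.chrom][copy.start : copy.end]

    def diagnostic_sites(self, a: TECopy, b: TECopy) -> list[int]:
        """Offsets (in consensus orientation) where two same-family copies differ."""
        sa = self.copy_sequence(a) if a.strand == "+" else revcomp(self.copy_sequence(a))
        sb = self.copy_sequence(b) if b.strand == "+" else revcomp(self.copy_sequence(b))
        if len(sa) != len(sb):
            raise ValueError("copies of unequal length are not comparable")
        return [i for i, (x, y) in enumerate(zip(sa, sb)) if x != y]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n == 0:
        return ""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)
    return codes.tobytes().decode("ascii")


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def default_te_families(rng: np.random.Generator, gc: float = 0.42) -> tuple:
    """Three families mirroring the active elements of the fly system:
    a DNA transposon with the hAT-like nTnnnnAn target motif (hobo-like),
    an LTR retrotransposon (Copia-like), and a non-LTR element (Jockey-like).
    Consensus sequences are random under the background composition.
    """
    return (
        TEFamilyModel("hobo", _random_seq(rng, 3000, gc), "DNA", 8, "NTNNNNAN"),
        TEFamilyModel("Copia", _random_seq(rng, 5000, gc), "LTR", 5, None),
        TEFamilyModel("Jockey", _random_seq(rng, 4000, gc), "non-LTR", 9, None),
    )


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, float]:
    """Substitute each site independently with probability ``rate``."""
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq, 0.0
    sites = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for i in sites:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out), k / n


class _Placer:
    """Non-overlapping interval placement with bounded resampling."""

    def __init__(self, chrom_lengths: dict, pad: int = 1200):
        self.lengths = chrom_lengths
        self.pad = pad
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}

    def collides(self, chrom: str, start: int, end: int) -> bool:
        if start < _EDGE_PAD or end > self.lengths[chrom] - _EDGE_PAD:
            return True
        return any(start - self.pad < e and s < end + self.pad
                   for s, e in self.used[chrom])

    def claim(self, chrom: str, start: int, end: int) -> None:
        self.used[chrom].append((start, end))

    def place(self, rng: np.random.Generator, length: int,
              chrom: Optional[str] = None, near: Optional[tuple] = None) -> tuple:
        """Return (chrom, start) for a free interval, or raise after retries."""
        names = list(self.lengths)
        for _ in range(MAX_PLACEMENT_RETRIES):
            if near is not None:
                c, anchor_end = near
                gap = int(rng.integers(1500, 8000))
                start = anchor_end + gap
            else:
                c = chrom if chrom is not None else names[rng.integers(len(names))]
                hi = self.lengths[c] - length - _EDGE_PAD
                if hi <= _EDGE_PAD:
                    raise ValueError(
                        f"chromosome {c} too short to host a {length}-bp feature")
                start = int(rng.integers(_EDGE_PAD, hi))
            if not self.collides(c, start, start + length):
                self.claim(c, start, start + length)
                return c, start
        raise RuntimeError(
            f"could not place a {length}-bp feature after {MAX_PLACEMENT_RETRIES} tries")


def generate_reference(config: SimulationConfig) -> SimulatedGenome:
    """Background chromosomes with planted, independently diverged TE copies.

    Copy layout per family: the first copy gets a proximal partner
    1.5-8 kb downstream, further copies go to random positions (some on
    other chromosomes), so proximal, distal and interarm donor geometries
    all exist.  One family additionally receives ``n_exact_duplicates``
    byte-identical copies of one realized copy (one of them on the reverse
    strand) to create multiple-donor conversion events.
    """
    config.validate()
    rng = _rng(config, _S_REFERENCE)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {name: _random_seq(rng, config.chromosome_length, config.gc_content)
              for name in chrom_names}
    families = config.te_families
    if families is None:
        families = default_te_families(rng, config.gc_content)
    genome = SimulatedGenome(
        chromosomes=dict(chroms),
        te_families={f.name: f for f in families},
        original_lengths={c: len(s) for c, s in chroms.items()},
    )
    if config.copies_per_family == 0:
        return genome
    placer = _Placer({c: len(s) for c, s in chroms.items()})
    dup_family = families[min(1, len(families) - 1)].name if config.n_exact_duplicates else None
    for fam in families:
        L = len(fam.consensus)
        realized: list[tuple[str, str, int, str, float]] = []  # chrom,seq,start,strand,div
        anchor: Optional[TECopy] = None
        for k in range(config.copies_per_family):
            seq, div = _mutate(rng, fam.consensus, config.te_copy_divergence)
            if k == 1 and anchor is not None:
                try:
                    chrom, start = placer.place(rng, L, near=(anchor.chrom, anchor.end))
                except (RuntimeError, ValueError):
                    chrom, start = placer.place(rng, L)
            else:
                chrom, start = placer.place(rng, L)
            copy = TECopy(f"{fam.name}_{k}", fam.name, chrom, start, start + L,
                          "+", div)
            if k == 0:
                anchor = copy
            genome.te_registry.append(copy)
            realized.append((chrom, seq, start, "+", div))
            genome.chromosomes[chrom] = (
                genome.chromosomes[chrom][:start] + seq
                + genome.chromosomes[chrom][start + L:])
        if fam.name == dup_family:
            # byte-identical duplicates of the last realized copy
            src_chrom, src_seq, src_start, _, src_div = realized[-1]
            group = f"{fam.name}_dupgroup"
            base_idx = config.copies_per_family - 1
            genome.te_registry[-1] = replace(genome.te_registry[-1],
                                             duplicate_group=group)
            for j in range(config.n_exact_duplicates):
                strand = "-" if j == config.n_exact_duplicates - 1 else "+"
                seq = revcomp(src_seq) if strand == "-" else src_seq
                chrom, start = placer.place(rng, L)
                genome.te_registry.append(
                    TECopy(f"{fam.name}_{base_idx + 1 + j}", fam.name, chrom,
                           start, start + L, strand, src_div, duplicate_group=group))
                genome.chromosomes[chrom] = (
                    genome.chromosomes[chrom][:start] + seq
                    + genome.chromosomes[chrom][start + L:])
    return genome


def _interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in bp between two intervals; 0 if they touch or overlap."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def _copy_oriented_window(genome: SimulatedGenome, copy: TECopy,
                          off: int, length: int) -> str:
    """Window of a copy in consensus orientation (reverse copies flipped)."""
    seq = genome.copy_sequence(copy)
    if copy.strand == "-":
        seq = revcomp(seq)
    return seq[off : off + length]


def _identical_donors(genome: SimulatedGenome, acceptor: TECopy,
                      donor_window: str, off: int) -> list[TECopy]:
    """All copies (excluding the acceptor) carrying the donor window exactly."""
    out = []
    for copy in genome.te_registry:
        if copy.copy_id == acceptor.copy_id:
            continue
        if copy.end - copy.start < off + len(donor_window):
            continue
        if _copy_oriented_window(genome, copy, off, len(donor_window)) == donor_window:
            out.append(copy)
    return out


def _donor_window_span(copy: TECopy, off: int, length: int) -> tuple[int, int]:
    """Genomic span of a consensus-orientation window inside a copy."""
    if copy.strand == "+":
        return copy.start + off, copy.start + off + length
    return copy.end - off - length, copy.end - off


def _classify_distance(
    acceptor_span: tuple[str, int, int],
    donors: Sequence[TECopy],
    off: int,
    length: int,
) -> tuple[str, Optional[int], TECopy, tuple[int, int]]:
    """Distance class of the nearest identical donor window (chromosome = arm)."""
    chrom, s, e = acceptor_span
    spans = [(d, _donor_window_span(d, off, length)) for d in donors]
    same = [(d, sp, _interval_gap((s, e), sp)) for d, sp in spans if d.chrom == chrom]
    if same:
        donor, sp, dist = min(same, key=lambda t: (t[2], t[1][0]))
        return ("proximal" if dist <= 10_000 else "distal"), dist, donor, sp
    donor, sp = min(spans, key=lambda t: (t[0].chrom, t[1][0]))
    return "interarm", None, donor, sp


def spike_conversions(genome: SimulatedGenome, n_events: int,
                      config: SimulationConfig) -> SimulatedGenome:
    """Plant gene-conversion events between same-family TE paralogs.

    Each event picks an (acceptor, donor) copy pair, draws a tract length
    from the log-normal tract distribution, and records the donor alleles
    at the diagnostic sites inside the tract as derived SNPs of the
    individuals (the reference sequence itself is not edited: a conversion
    is a difference between the sequenced individual and the reference).
    Tracts are placed so that at least two diagnostic sites lie >= 25 bp
    inside the tract and consecutive converted sites are <= 1000 bp apart,
    the geometry required for the event to be recoverable in principle.
    Events that cannot be placed are skipped with a warning.
    """
    rng = _rng(config, _S_CONVERSION)
    if n_events == 0:
        return genome
    pairs = []
    for a in genome.te_registry:
        if a.strand != "+":
            continue
        for b in genome.te_registry:
            if b.copy_id == a.copy_id or b.family != a.family:
                continue
            if a.duplicate_group is not None and a.duplicate_group == b.duplicate_group:
                continue  # identical copies have no diagnostic sites
            pairs.append((a, b))
    if not pairs:
        raise ValueError("no eligible TE copy pairs: need >= 2 diverged copies")
    order = rng.permutation(len(pairs))
    used_spans: dict[str, list[tuple[int, int]]] = {}
    planted = 0
    attempts = 0
    pair_idx = 0
    while planted < n_events and attempts < n_events * MAX_PLACEMENT_RETRIES:
        attempts += 1
        acceptor, donor = pairs[order[pair_idx % len(order)]]
        pair_idx += 1
        diag = genome.diagnostic_sites(acceptor, donor)
        if len(diag) < 2:
            continue
        L_copy = acceptor.end - acceptor.start
        tract = int(round(rng.lognormal(math.log(config.tract_median),
                                        config.tract_sigma)))
        tract = max(60, min(tract, L_copy))
        margin = 25
        # anchor the window on a random diagnostic site
        d0 = int(diag[rng.integers(len(diag))])
        lo = max(0, d0 - tract + margin + 1)
        hi = min(L_copy - tract, d0 - margin)
        if hi < lo:
            continue
        w = int(rng.integers(lo, hi + 1))
        inner = [d for d in diag if w + margin <= d < w + tract - margin]
        if len(inner) < 2:
            continue
        if any(b - a > 1000 for a, b in zip(inner, inner[1:])):
            continue
        # non-converted diagnostic sites must stay clear of the 50-bp pad a
        # detector may add around the outermost converted sites
        outside = [d for d in diag if d not in inner]
        if any(abs(d - inner[0]) <= 2 * margin or abs(d - inner[-1]) <= 2 * margin
               for d in outside):
            continue
        span = (acceptor.start + w, acceptor.start + w + tract)
        spans = used_spans.setdefault(acceptor.copy_id, [])
        if any(span[0] < e + 1100 and s < span[1] + 1100 for s, e in spans):
            continue
        spans.append(span)
        acc_seq = genome.copy_sequence(acceptor)
        donor_window = _copy_oriented_window(genome, donor, w, tract)
        sites = tuple(
            (acceptor.start + d, acc_seq[d], donor_window[d - w]) for d in inner
        )
        donors = _identical_donors(genome, acceptor, donor_window, w)
        if not donors:
            continue
        tract_span = (acceptor.chrom, acceptor.start + w, acceptor.start + w + tract)
        klass, dist, nearest, donor_span = _classify_distance(tract_span, donors,
                                                              w, tract)
        event = TruthConversion(
            event_id=f"conv_{planted}",
            chrom=acceptor.chrom,
            tract_start=span[0],
            tract_end=span[1],
            acceptor_copy=acceptor.copy_id,
            donor_copy=nearest.copy_id,
            donor_chrom=nearest.chrom,
            donor_start=donor_span[0],
            donor_end=donor_span[1],
            converted_sites=sites,
            distance_class=klass,
            donor_distance=dist,
            n_identical_donors=len(donors),
        )
        genome.truth_conversions.append(event)
        for pos, ref, alt in sites:
            genome.truth_snps.append(
                TruthSNP(acceptor.chrom, pos, ref, alt, "homozygous", "conversion"))
        planted += 1
    if planted < n_events:
        logger.warning("planted %d of %d requested conversion events", planted,
                       n_events)
    return genome


def spike_background_snps(genome: SimulatedGenome, n_snps: int,
                          config: SimulationConfig,
                          shared_fraction: float = 0.95,
                          het_fraction: float = 0.1,
                          clustered_fraction: float = 0.25,
                          te_fraction: float = 0.2) -> SimulatedGenome:
    """Plant background SNPs unrelated to gene conversion.

    A ``clustered_fraction`` of the SNPs is planted as same-individual
    pairs with log-uniform spacing over 1-1000 bp, emulating clustered
    mutations from sources other than conversion (secondary mutations,
    error-prone polymerase tracts); the rest are isolated (> 1.1 kb from
    anything).  A ``te_fraction`` is placed inside TE copies so that
    conversion accounts for only part of the TE SNP pool.  A
    ``shared_fraction`` of the planted sites is carried by both
    individuals; the rest alternate between the two.
    """
    rng = _rng(config, _S_BGSNP)
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    for copy in genome.te_registry:
        forbidden[copy.chrom].append((copy.start - 1100, copy.end + 1100))
    for snp in genome.truth_snps:
        forbidden[snp.chrom].append((snp.pos - 1100, snp.pos + 1101))
    names = list(genome.chromosomes)
    te_copies = list(genome.te_registry)
    planted = 0
    spec_toggle = 0

    def _free(chrom: str, pos: int) -> bool:
        return not any(s <= pos < e for s, e in forbidden[chrom])

    def _mk(chrom: str, pos: int, individuals: tuple, genotype: str) -> None:
        ref = genome.chromosomes[chrom][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        genome.truth_snps.append(
            TruthSNP(chrom, pos, ref, alt, genotype, "background", individuals))

    for _ in range(n_snps * MAX_PLACEMENT_RETRIES):
        if planted >= n_snps:
            break
        in_te = rng.random() < te_fraction and te_copies
        if in_te:
            copy = te_copies[int(rng.integers(len(te_copies)))]
            pos = int(rng.integers(copy.start, copy.end))
            chrom = copy.chrom
            # TE copies are globally forbidden; only require clearance from
            # other planted SNPs and conversion tracts
            near_snp = any(abs(pos - s.pos) < 1100 for s in genome.truth_snps
                           if s.chrom == chrom)
            near_tract = any(ev.chrom == chrom
                             and ev.tract_start - 1100 <= pos < ev.tract_end + 1100
                             for ev in genome.truth_conversions)
            if near_snp or near_tract:
                continue
        else:
            chrom = names[rng.integers(len(names))]
            L = len(genome.chromosomes[chrom])
            pos = int(rng.integers(_EDGE_PAD, L - _EDGE_PAD))
            if not _free(chrom, pos):
                continue
        if genome.chromosomes[chrom][pos] not in "ACGT":
            continue
        shared = rng.random() < shared_fraction
        if shared:
            individuals: tuple = ("A", "B")
        else:
            individuals = ("A",) if spec_toggle % 2 == 0 else ("B",)
            spec_toggle += 1
        genotype = "heterozygous" if rng.random() < het_fraction else "homozygous"
        paired = rng.random() < clustered_fraction and planted + 1 < n_snps
        pos2 = None
        if paired:
            d = int(rng.integers(1, 1001))
            pos2 = pos + d
            L = len(genome.chromosomes[chrom])
            ok2 = (pos2 < L - _EDGE_PAD
                   and genome.chromosomes[chrom][pos2] in "ACGT"
                   and (_free(chrom, pos2) if not in_te else
                        copy.start <= pos2 < copy.end))
            if not ok2:
                pos2 = None
        _mk(chrom, pos, individuals, genotype)
        forbidden[chrom].append((pos - 1100, pos + 1101))
        planted += 1
        if pos2 is not None:
            _mk(chrom, pos2, individuals, genotype)
            forbidden[chrom].append((pos2 - 1100, pos2 + 1101))
            planted += 1
    if planted < n_snps:
        logger.warning("planted %d of %d requested background SNPs", planted, n_snps)
    return genome


@dataclass(frozen=True)
class _Edit:
    chrom: str
    pos: int  # original coordinate
    del_len: int
    ins_seq: str
    meta: dict


import re as _re


def _find_motif_sites(seq: str, motif: str, rng: np.random.Generator,
                      n_wanted: int) -> list[int]:
    """Positions p where seq[p-3:p+5] matches the degenerate 8-mer."""
    pattern = _re.compile("(?=" + "".join("." if m == "N" else m for m in motif) + ")")
    hits = [m.start() + 3 for m in pattern.finditer(seq)
            if _EDGE_PAD <= m.start() + 3 < len(seq) - _EDGE_PAD]
    rng.shuffle(hits)
    return hits[: n_wanted * MAX_PLACEMENT_RETRIES]


def spike_insertions(genome: SimulatedGenome, n_simple: int, n_complex: int,
                     config: SimulationConfig) -> SimulatedGenome:
    """Plant TE insertions, editing the chromosome sequences.

    Simple insertions carry an exact TSD of the family's ``tsd_length``.
    Complex insertions additionally carry an immediate flanking deletion
    drawn from ``deletion_size_range`` (which destroys the TSD on that
    side) and/or a templated duplication with >= 1 bp of junction
    microhomology; duplication-only events keep their TSD.  Existing truth
    coordinates are shifted to the edited frame.  Insertions are placed at
    transposase-motif-matching sites for families that define a motif.
    """
    rng = _rng(config, _S_INSERTION)
    if n_simple == 0 and n_complex == 0:
        return genome
    if not genome.te_families:
        raise ValueError("no TE family models available")
    families = list(genome.te_families.values())
    # protected original-coordinate intervals: TE copies, tracts, SNPs (+1100 bp)
    protected: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    for copy in genome.te_registry:
        protected[copy.chrom].append((copy.start - 1100, copy.end + 1100))
    for snp in genome.truth_snps:
        protected[snp.chrom].append((snp.pos - 1100, snp.pos + 1101))
    motif_sites: dict[str, dict[str, list[int]]] = {}
    for fam in families:
        if fam.recognition_motif:
            motif_sites[fam.name] = {
                c: _find_motif_sites(seq, fam.recognition_motif, rng,
                                     n_simple + n_complex)
                for c, seq in genome.chromosomes.items()
            }
    edits: list[_Edit] = []
    names = list(genome.chromosomes)

    def _free(chrom: str, lo: int, hi: int) -> bool:
        if lo < _EDGE_PAD or hi > len(genome.chromosomes[chrom]) - _EDGE_PAD:
            return False
        if any(lo < e and s < hi for s, e in protected[chrom]):
            return False
        return not any(e.chrom == chrom and lo < e.pos + e.del_len + 40
                       and e.pos - 40 < hi for e in edits)

    def _pick_site(fam: TEFamilyModel) -> tuple[str, int]:
        for _ in range(MAX_PLACEMENT_RETRIES):
            if fam.recognition_motif:
                chrom = names[rng.integers(len(names))]
                sites = motif_sites[fam.name][chrom]
                if not sites:
                    continue
                p = sites[rng.integers(len(sites))]
            else:
                chrom = names[rng.integers(len(names))]
                L = len(genome.chromosomes[chrom])
                p = int(rng.integers(_EDGE_PAD, L - _EDGE_PAD))
            if _free(chrom, p - fam.tsd_length - 420, p + 420):
                return chrom, p
        raise RuntimeError("could not place a TE insertion after bounded retries")

    complex_kinds = ["del", "del", "del", "dup", "del", "del", "del", "del+dup"]
    planned = [("simple", None)] * n_simple + [
        ("complex", complex_kinds[i % len(complex_kinds)]) for i in range(n_complex)
    ]
    for idx, (klass, kind) in enumerate(planned):
        fam = families[int(rng.integers(len(families)))]
        chrom, p = _pick_site(fam)
        seq = genome.chromosomes[chrom]
        kmer = seq[p - 3 : p + 5]
        t = fam.tsd_length
        if klass == "simple" or kind == "dup":
            ins = fam.consensus
            dup: Optional[DuplicationTruth] = None
            if kind == "dup":
                dlen = int(rng.integers(config.duplication_size_range[0],
                                        config.duplication_size_range[1] + 1))
                mh = int(rng.integers(1, 6))
                tail = fam.consensus[-mh:]
                src_chrom = names[rng.integers(len(names))]
                src_seq = genome.chromosomes[src_chrom]
                cands = []
                s0 = src_seq.find(tail, _EDGE_PAD)
                while s0 != -1 and len(cands) < 50:
                    if s0 + dlen < len(src_seq) - _EDGE_PAD:
                        cands.append(s0)
                    s0 = src_seq.find(tail, s0 + 1)
                if not cands:
                    mh, cands = 1, [int(rng.integers(_EDGE_PAD,
                                                     len(src_seq) - dlen - _EDGE_PAD))]
                s0 = cands[int(rng.integers(len(cands)))]
                de_novo = int(rng.integers(1, 28)) if rng.random() < 0.5 else 0
                dup_seq = src_seq[s0 + mh : s0 + dlen] + _random_seq(rng, de_novo,
                                                                     config.gc_content)
                ins = fam.consensus + dup_seq
                dup = DuplicationTruth(src_chrom, s0, dlen, mh, de_novo)
            # TSD: duplicate target seq[p-t:p] -> single insertion at p of (ins + TSD)
            tsd_seq = seq[p - t : p] if t > 0 else ""
            edits.append(_Edit(chrom, p, 0, ins + tsd_seq, {
                "id": f"ins_{idx}", "family": fam.name, "classification": klass,
                "tsd": tsd_seq if t > 0 else None, "block_len": len(ins) + 0,
                "flank_del": 0, "dup": dup, "kmer": kmer,
            }))
        else:  # deletion-bearing complex insertion (kind "del" or "del+dup")
            d = int(rng.integers(config.deletion_size_range[0],
                                 config.deletion_size_range[1] + 1))
            ins = fam.consensus
            dup = None
            if kind == "del+dup":
                dlen = int(rng.integers(config.duplication_size_range[0],
                                        config.duplication_size_range[1] + 1))
                src_chrom = names[rng.integers(len(names))]
                src_seq = genome.chromosomes[src_chrom]
                s0 = int(rng.integers(_EDGE_PAD, len(src_seq) - dlen - _EDGE_PAD))
                ins = fam.consensus + src_seq[s0 + 1 : s0 + dlen]
                dup = DuplicationTruth(src_chrom, s0, dlen, 1, 0)
            edits.append(_Edit(chrom, p, d, ins, {
                "id": f"ins_{idx}", "family": fam.name, "classification": "complex",
                "tsd": None, "block_len": len(ins), "flank_del": d, "dup": dup,
                "kmer": kmer,
            }))

    # apply edits and shift coordinates
    by_chrom: dict[str, list[_Edit]] = {}
    for e in edits:
        by_chrom.setdefault(e.chrom, []).append(e)
    shifts: dict[str, list[tuple[int, int]]] = {}  # chrom -> [(orig_pos, delta)]
    for chrom, ce in by_chrom.items():
        ce.sort(key=lambda e: e.pos)
        seq = genome.chromosomes[chrom]
        cum = 0
        deltas = []
        for e in ce:
            delta = len(e.ins_seq) - e.del_len
            # for TSD events the inserted block excludes the trailing TSD copy
            start = e.pos + cum
            genome.truth_insertions.append(TruthInsertion(
                insertion_id=e.meta["id"], chrom=chrom,
                start=start, end=start + e.meta["block_len"],
                family=e.meta["family"], classification=e.meta["classification"],
                tsd_sequence=e.meta["tsd"], flank_deletion_length=e.meta["flank_del"],
                duplication=e.meta["dup"], breakpoint_kmer=e.meta["kmer"],
            ))
            deltas.append((e.pos, delta))
            cum += delta
            genome.inserted_bases += len(e.ins_seq)
            genome.deleted_bases += e.del_len
        for e in sorted(ce, key=lambda e: -e.pos):
            seq = seq[: e.pos] + e.ins_seq + seq[e.pos + e.del_len:]
        genome.chromosomes[chrom] = seq
        shifts[chrom] = deltas

    def _shift(chrom: str, x: int) -> int:
        return x + sum(d for p, d in shifts.get(chrom, []) if p <= x)

    genome.te_registry = [
        replace(c, start=_shift(c.chrom, c.start), end=_shift(c.chrom, c.end))
        for c in genome.te_registry
    ]
    genome.truth_snps = [
        replace(s, pos=_shift(s.chrom, s.pos)) for s in genome.truth_snps
    ]
    genome.truth_conversions = [
        replace(ev, tract_start=_shift(ev.chrom, ev.tract_start),
                tract_end=_shift(ev.chrom, ev.tract_end),
                donor_start=_shift(ev.donor_chrom, ev.donor_start),
                donor_end=_shift(ev.donor_chrom, ev.donor_end),
                converted_sites=tuple((_shift(ev.chrom, p), r, a)
                                      for p, r, a in ev.converted_sites))
        for ev in genome.truth_conversions
    ]
    return genome


@dataclass
class ReadSupport:
    """Per-individual read support for truth SNPs plus per-read tallies."""

    calls: list  # list[SNPCall]
    support_table: pd.DataFrame  # columns: snp_id, read_id
    tallies: pd.DataFrame  # columns: read_id, M, X, D, I, length
    reads: list  # (chrom, start, end, read_id)


def simulate_read_support(genome: SimulatedGenome,
                          config: SimulationConfig,
                          individual: str = "A",
                          genotypes: Optional[dict] = None) -> ReadSupport:
    """Simulate read coverage, per-SNP supporting reads, and CIGAR tallies.

    Reads of the median length are tiled uniformly at the configured mean
    coverage.  A homozygous SNP is carried by every covering read, a
    heterozygous one by each covering read independently with probability
    one half; sequencing error flips support with probability
    ``per_base_error``.  Per-read tallies draw substitution/deletion/
    insertion counts summing to the per-base error rate (80/10/10 split).
    """
    tag = int.from_bytes(individual.encode(), "little") % 997
    rng = np.random.default_rng([int(config.seed), _S_READS, tag])
    if config.coverage <= 0:
        logger.warning("coverage is zero: empty support table")
        empty = pd.DataFrame(columns=["snp_id", "read_id"])
        tal = pd.DataFrame(columns=["read_id", "M", "X", "D", "I", "length"])
        return ReadSupport([], empty, tal, [])
    e = config.per_base_error
    rl = config.read_length_median
    reads: list[tuple[str, int, int, str]] = []
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        n_reads = max(1, int(round(L * config.coverage / rl)))
        starts = np.sort(rng.integers(0, max(1, L - rl + 1), size=n_reads))
        for i, s in enumerate(starts):
            reads.append((chrom, int(s), int(s) + rl, f"{individual}_{chrom}_r{i}"))
    reads_by_chrom: dict[str, list] = {}
    for r in reads:
        reads_by_chrom.setdefault(r[0], []).append(r)
    starts_by_chrom = {c: np.array([r[1] for r in rs])
                       for c, rs in reads_by_chrom.items()}
    calls: list[SNPCall] = []
    rows = []
    for snp in genome.truth_snps:
        if individual not in snp.individuals:
            continue
        chrom_reads = reads_by_chrom.get(snp.chrom, [])
        starts = starts_by_chrom.get(snp.chrom, np.empty(0, dtype=int))
        lo = int(np.searchsorted(starts, snp.pos - rl, side="right"))
        hi = int(np.searchsorted(starts, snp.pos, side="right"))
        covering = [r for r in chrom_reads[lo:hi] if r[1] <= snp.pos < r[2]]
        total = len(covering)
        if total == 0:
            continue
        gt = (genotypes or {}).get(snp.key, snp.genotype)
        if gt == "homozygous":
            carrier = np.ones(total, dtype=bool)
        else:
            carrier = rng.random(total) < 0.5
        supports = np.where(
            carrier, rng.random(total) >= e, rng.random(total) < e / 3
        )
        support_ids = frozenset(r[3] for r, s in zip(covering, supports) if s)
        chrom_class = ("sex" if snp.chrom in config.sex_chromosomes else "autosome")
        calls.append(SNPCall(snp.chrom, snp.pos, snp.ref, snp.alt, support_ids,
                             total, chrom_class))
        rows.extend({"snp_id": f"{snp.chrom}:{snp.pos}:{snp.ref}:{snp.alt}",
                     "read_id": rid} for rid in sorted(support_ids))
    n = len(reads)
    x = rng.binomial(rl, e * 0.8, size=n)
    d = rng.binomial(rl, e * 0.1, size=n)
    i_ = rng.binomial(rl, e * 0.1, size=n)
    tallies = pd.DataFrame({
        "read_id": [r[3] for r in reads],
        "M": rl - x - i_,
        "X": x,
        "D": d,
        "I": i_,
        "length": rl,
    })
    support = pd.DataFrame(rows, columns=["snp_id", "read_id"])
    return ReadSupport(calls, support, tallies, reads)
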