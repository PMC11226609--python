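"""SNP-call filtering, VAF-based binomial genotyping, and sharing status.

A call is kept only if it is supported by at least three reads, passes the
chromosome-class VAF threshold (0.3 on autosomes, 0.9 on sex chromosomes,
where hemizygosity makes intermediate VAFs suspect), maps uniquely, and
does not sit inside a long (> 1500 bp) VNTR.  Genotypes come from a
one-sided lower-tail binomial test of the alt-read count against a
near-one homozygous expectation: an inbred line should be homozygous, so
failing to reject homozygosity calls the site homozygous and rejecting it
calls it heterozygous.  The homozygous expectation defaults to 0.95 rather
than the idealised 1.0, which is degenerate under an exact binomial (a
single non-alt read would force p = 0); the slack absorbs mapping errors
and depth fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from scipy import stats as sps

__all__ = [
    "SNPCall",
    "GenotypeResult",
    "SharingStatus",
    "FilterDecision",
    "filter_snp_calls",
    "genotype_by_binomial",
    "classify_sharing",
    "MIN_SUPPORT",
    "VAF_AUTOSOME",
    "VAF_SEX",
    "VNTR_MAX_LEN",
]

MIN_SUPPORT = 3  # minimum supporting reads for a genuine SNP
VAF_AUTOSOME = 0.3
VAF_SEX = 0.9
VNTR_MAX_LEN = 1500  # bp; SNPs inside longer VNTRs are excluded
P_HOM_DEFAULT = 0.95
ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class SNPCall:
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    supporting_reads: frozenset
    total_reads: int
    chrom_class: str  # "autosome" | "sex"
    mapping_unique: bool = True
    in_long_vntr: bool = False

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def n_support(self) -> int:
        return len(self.supporting_reads)

    @property
    def vaf(self) -> float:
        if self.total_reads <= 0:
            return 0.0
        return self.n_support / self.total_reads

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class FilterDecision:
    call: SNPCall
    kept: bool
    reason: Optional[str]  # first failing rule, None if kept


def filter_snp_calls(
    calls: Sequence[SNPCall],
    min_support: int = MIN_SUPPORT,
    vaf_autosome: float = VAF_AUTOSOME,
    vaf_sex: float = VAF_SEX,
) -> tuple[list[SNPCall], list[FilterDecision]]:
    """Partition calls into kept and rejected, tagging each rejection.

    Rules are applied in order (support, VAF, unique mapping, long VNTR)
    and the first failing rule is recorded.  Thresholds are inclusive.
    """
    kept: list[SNPCall] = []
    rejected: list[FilterDecision] = []
    for call in calls:
        if call.chrom_class not in ("autosome", "sex"):
            raise ValueError(f"call at {call.chrom}:{call.pos}: missing or invalid "
                             f"chrom_class {call.chrom_class!r}")
        reason = None
        if call.n_support < min_support:
            reason = "support"
        elif call.vaf < (vaf_autosome if call.chrom_class == "autosome" else vaf_sex):
            reason = "vaf"
        elif not call.mapping_unique:
            reason = "mapping"
        elif call.in_long_vntr:
            reason = "vntr"
        if reason is None:
            kept.append(call)
        else:
            rejected.append(FilterDecision(call, False, reason))
    return kept, rejected


@dataclass(frozen=True)
class GenotypeResult:
    genotype: str  # "homozygous" | "heterozygous" | "filtered"
    p_value: float
    n_alt: int
    n_total: int


def genotype_by_binomial(
    n_alt: int,
    n_total: int,
    p_hom: float = P_HOM_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> GenotypeResult:
    """Genotype a variant from its alt-read count.

    One-sided lower-tail binomial test of ``n_alt`` in ``n_total`` against
    the homozygous expectation ``p_hom``: p >= alpha keeps the homozygous
    null, p < alpha rejects it towards heterozygous.  Fewer than three
    spanning reads cannot be genotyped and return "filtered".
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_alt <= n_total):
        raise ValueError("n_alt outside [0, n_total]")
    if not (0.0 < p_hom <= 1.0):
        raise ValueError("p_hom outside (0, 1]")
    if n_total < MIN_SUPPORT:
        return GenotypeResult("filtered", 1.0, n_alt, n_total)
    if p_hom == 1.0:
        # Degenerate limit: any non-alt read makes the lower tail 0.
        p = 1.0 if n_alt == n_total else 0.0
    else:
        p = float(sps.binom.cdf(n_alt, n_total, p_hom))
    genotype = "homozygous" if p >= alpha else "heterozygous"
    return GenotypeResult(genotype, p, n_alt, n_total)


@dataclass(frozen=True)
class SharingStatus:
    status: str  # "shared" | "specific_A" | "specific_B"
    evidence: str  # "assembly" | "read_level"


def classify_sharing(
    calls_a: Sequence[SNPCall],
    calls_b: Sequence[SNPCall],
    read_presence: Callable[[str, SNPCall], bool],
) -> dict[tuple, SharingStatus]:
    """Shared vs. individual-specific status for the union of two call sets.

    A variant called in both individuals is shared with assembly-level
    evidence.  A variant called in one individual but supported by at least
    one read at the same position and allele in the other is shared with
    read-level evidence.  Otherwise it is specific to the individual that
    carries it.  ``read_presence(individual, call)`` answers whether the
    named individual ("A" or "B") has read-level support for the call.
    """
    a_by_key = {c.key: c for c in calls_a}
    b_by_key = {c.key: c for c in calls_b}
    out: dict[tuple, SharingStatus] = {}
    for key in set(a_by_key) | set(b_by_key):
        in_a, in_b = key in a_by_key, key in b_by_key
        if in_a and in_b:
            out[key] = SharingStatus("shared", "assembly")
        elif in_a:
            if read_presence("B", a_by_key[key]):
                out[key] = SharingStatus("shared", "read_level")
            else:
                out[key] = SharingStatus("specific_A", "assembly")
        else:
            if read_presence("A", b_by_key[key]):
                out[key] = SharingStatus("shared", "read_level")
            else:
                out[key] = SharingStatus("specific_B", "assembly")
    return out
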