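"""Readers/writers for the pipeline's external formats.

FASTA goes through Biopython; tables are TSV via pandas; truth SNPs are
exported as minimal 1-based VCF; TE registries and spans as BED.  Configs
are YAML key-value files.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qc import AlignmentStats
from .variants import SNPCall

__all__ = [
    "write_fasta", "read_fasta", "write_bed", "read_bed",
    "write_vcf", "write_tsv", "read_tsv",
    "read_alignment_tallies", "read_snp_calls", "load_config", "dump_config",
]


def write_fasta(chromosomes: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in
               chromosomes.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Intervals are (chrom, start, end, name) 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "."))
    return out


def write_vcf(snps: Sequence, path) -> None:
    """Truth SNPs as minimal VCF (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GT0,Number=1,Type=String,Description="Planted genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t"
                     f"GT0={s.genotype}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_alignment_tallies(path) -> list[AlignmentStats]:
    df = read_tsv(path)
    return [AlignmentStats(str(r.read_id), int(r.M), int(r.X), int(r.D), int(r.I),
                           int(r.length)) for r in df.itertuples()]


def write_snp_calls(calls: Sequence[SNPCall], path) -> None:
    rows = [{
        "chrom": c.chrom, "pos": c.pos, "ref": c.ref_allele, "alt": c.alt_allele,
        "n_support": c.n_support, "total_reads": c.total_reads, "vaf": c.vaf,
        "chrom_class": c.chrom_class, "mapping_unique": c.mapping_unique,
        "in_long_vntr": c.in_long_vntr,
        "supporting_reads": ",".join(sorted(c.supporting_reads)),
    } for c in calls]
    write_tsv(pd.DataFrame(rows), path)


def read_snp_calls(path) -> list[SNPCall]:
    df = read_tsv(path)
    calls = []
    for r in df.itertuples():
        reads = frozenset(str(r.supporting_reads).split(",")) \
            if isinstance(r.supporting_reads, str) and r.supporting_reads else frozenset()
        calls.append(SNPCall(str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
                             reads, int(r.total_reads), str(r.chrom_class),
                             bool(r.mapping_unique), bool(r.in_long_vntr)))
    return calls


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
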