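# lrmut

Mutational-process analysis for single-individual long-read genomes.

High-accuracy long reads (PacBio HiFi-class CCS reads) from one or two
individual *Drosophila*-scale genomes make whole classes of mutation
analysable that short reads cannot resolve: clustered SNPs inside
near-identical transposable-element (TE) paralogs, gene-conversion tracts
copied between TE copies, target-site duplications (TSDs) at transposon
insertions, and complex transpositions with extra flanking deletions or
duplications.  `lrmut` implements the analysis layer for such data —
read-quality and GC-bias metrics, VAF-based genotyping, clustered-SNP
statistics with a Monte Carlo null, iterative TE gene-conversion detection,
and structural classification of insertions and duplications — together
with a synthetic-genome simulator that plants all of these features with a
known truth ledger, so every detector can be tested by parameter recovery.

## Core methods

**Read concordance and QV.**  For a read with CIGAR tallies *M* (matches),
*X* (mismatches), *D*/*I* (deleted/inserted bases),

    concordance = M / (M + X + D + I)
    QV = min( −10·log10(1 − concordance), −10·log10(1 / (1 + read length)) )

so a perfect read reports the read-length cap rather than infinity.
GC bias is the median of window depth / median(all window depths) per
5-point GC bin over 20–65% GC, in 500-bp windows.

**Genotyping.**  A variant with `k` supporting reads out of `n` spanning
reads is tested one-sided (lower tail) against a near-one homozygous
expectation `p_hom` (default 0.95): failing to reject calls it homozygous,
rejecting calls it heterozygous; fewer than 3 spanning reads cannot be
genotyped.  SNP calls are kept only with ≥ 3 supporting reads, VAF ≥ 0.3
(autosomes) or ≥ 0.9 (sex chromosomes), unique mapping, and no long-VNTR
overlap.

**Clustered SNPs (cSNPs).**  A SNP is clustered when another SNP lies
within 1–1000 bp on the same chromosome and the two share a supporting
read.  Clustered SNPs are binned by nearest-neighbour distance (1–9,
10–99, 100–299, 300–1000 bp) and compared with a Monte Carlo null that
redraws the same number of positions uniformly per chromosome;
exceedance p-values use the add-one estimator.

**TE gene conversion.**  Nearest cSNP pairs seed sequence fragments
(padded to ≥ 50 bp) whose derived alleles are substituted in; all exact
genomic occurrences of the fragment on either strand are candidate donors.
Fragments merge iteratively with the nearest SNP (≤ 1 kb) while a donor
survives; the last donor-positive extent is the event.  Events are
classified proximal (donor ≤ 10 kb), distal (> 10 kb), or interarm, and the
weak→strong vs. strong→weak direction of converted sites tests GC-biased
conversion.

**TE structural analysis.**  TSD = longest identical 4–30-bp flank on both
sides of an inserted block; insertions with immediate flanking deletions
and/or linked duplications are *complex*; *hobo* breakpoints are checked
against the nTnnnnAn transposase motif; duplications with ≥ 62 bp of
breakpoint homology are attributed to NAHR, the rest to error-prone repair.
Seven non-B DNA motif classes (A-phased repeats, G-quadruplexes, direct /
inverted / mirror repeats, short tandem repeats, Z-DNA) are scanned under a
documented grammar and compared between insertion-site windows and random
windows with one-sided rank-sum tests.

## Worked example

```python
from lrmut.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=1, outdir="demo",
    params={"simulate": {"chromosome_length": 1_000_000, "n_conversions": 10,
                         "n_background_snps": 120},
            "csnp": {"reps": 5000}, "tes": {"n_random": 200}},
)
manifest, ctx = run_pipeline(config)

print(f"median read QV            {ctx['median_qv']:.2f}")
print(f"planted / detected events {len(ctx['genome'].truth_conversions)} / "
      f"{len(ctx['conversion_events'])}")
hist, null = ctx["histogram"], ctx["mc_null"]
for (lo, hi), obs, exp, p in zip(hist.bins, hist.counts, null.expected,
                                 null.p_values):
    print(f"cSNP bin {lo:>4}-{hi:<4}  observed {obs:>3}  null {exp:7.2f}  p {p:.2e}")
for f in ctx["report"].fractions:
    print(f"{f.name:<35} {f.numerator:>4}/{f.denominator:<4} = {f.percent}%")
```

prints

```
median read QV            36.53
planted / detected events 10 / 10
cSNP bin    1-9     observed  28  null    0.15  p 2.00e-04
cSNP bin   10-99    observed  20  null    1.61  p 2.00e-04
cSNP bin  100-299   observed  12  null    3.60  p 6.80e-03
cSNP bin  300-1000  observed  38  null   12.01  p 2.00e-04
conversion_fraction_of_te_snps        46/62   = 74.2%
conversion_fraction_of_csnps          46/98   = 46.9%
conversion_fraction_of_snps           46/166  = 27.7%
shared_snp_fraction                  157/166  = 94.6%
proximal_fraction_unique_donor         3/8    = 37.5%
remote_fraction_unique_donor           5/8    = 62.5%
proximal_fraction_multiple_donor       0/2    = 0.0%
remote_fraction_multiple_donor         2/2    = 100.0%
```

The median read QV of ~36.5 reflects the simulator's 2.5×10⁻⁴ per-base
error through the concordance formula; all ten planted conversion events
are recovered; clustered SNPs exceed the positional null in all four
distance bins; and the report fractions recompute exactly from their
numerators and denominators.

The same stages are available from a shell:

```bash
lrmut run --seed 1 --outdir demo          # full pipeline
lrmut simulate --seed 1 --outdir demo     # genome + truth tables only
```

Every run writes `manifest.json` recording versions, per-stage seeds and
parameters, and SHA-256 digests of all outputs; reruns with the same seed
are byte-identical.

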