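# Methods

This note documents the models implemented in `lrmut`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that a maintainer would otherwise have
to reverse-engineer from the code.

## Read quality and GC bias (`lrmut.qc`)

Concordance of an aligned consensus read is M/(M+X+D+I) over its CIGAR
tallies; QV is the Phred scale of concordance, capped at
−10·log10(1/(1+read length)) so that an error-free alignment reports the
lowest error rate its length can witness rather than an infinite QV.  Logs
are base 10 throughout; QV is written to 2 decimals in tabular output.
Note that a QV of 36 corresponds to an error rate of 10^−3.6 ≈ 2.5×10⁻⁴,
which prints as "0.02%" only after rounding — the two are not exactly
equal and no code asserts they are.

GC bias uses fixed 500-bp windows.  Relative depth is window depth divided
by the median depth of **all** windows, summarised as the median per 5-point
GC bin across 20–65% GC.  The 5-point bin width is a presentation choice;
windows containing any non-ACGT base are dropped because their GC content
is undefined.  Computing M/X/D/I from raw SAM/BAM CIGARs is an upstream
extraction step, not part of this package.

## Variant filtering and genotyping (`lrmut.variants`)

Filters (inclusive thresholds, applied in order: support, VAF, mapping,
VNTR): ≥ 3 supporting reads; VAF ≥ 0.3 on autosomes or ≥ 0.9 on sex
chromosomes (a hemizygous male X should be near-pure for a real variant);
unique mapping; not inside a VNTR longer than 1500 bp.  Each rejected call
is tagged with the first rule it failed, so kept ∪ rejected always
partitions the input and filtering is idempotent.

Genotyping tests the alt-read count against a homozygous expectation with
a one-sided lower-tail binomial test at alpha = 0.05.  An idealised
expectation of 1.0 is degenerate under an exact binomial — a single
non-alt read forces p = 0 — so the default `p_hom = 0.95` operationalises
"homozygous up to mapping errors and depth fluctuations".  Both `p_hom`
and alpha are caller-configurable, and the degenerate `p_hom = 1` limit is
implemented and documented.  Sites spanned by fewer than 3 reads are
reported as ungenotyped ("filtered") and excluded downstream.

Sharing: a variant called in both individuals is shared
(assembly evidence); called in one and read-supported at the same position
and allele in the other, shared (read-level evidence); otherwise
individual-specific.

## Clustered SNPs and the Monte Carlo null (`lrmut.csnp`)

A SNP is clustered iff another SNP lies within 1–1000 bp on the same
chromosome *and* the two share at least one supporting read; the
read-sharing condition suppresses clusters assembled from different
haplotypes or mapping noise.  Each clustered SNP is counted once, in the
bin (1–9, 10–99, 100–299, 300–1000 bp; boundaries inclusive) of its
nearest-neighbour distance — the module counts clustered *SNPs*, not
clustered pairs, and multi-allelic records collapse to one position.

The null redraws the observed number of SNP positions per chromosome
uniformly without replacement (default 100,000 replicates) and counts
clustered SNPs **by position only**: read identity is not simulable from
positions, so the read-sharing condition is waived under the null, making
the null conservative in the direction of *more* null clustering.
Exceedance p-values use the add-one estimator
(1 + #{null ≥ observed})/(reps + 1), which cannot return 0 at finite
replication.  The type-I error of this test is calibrated in the
acceptance suite on 200 null datasets at 2000 replicates each.

## Gene-conversion detection (`lrmut.conversion`)

Seeding pairs each clustered SNP with its nearest clustered neighbour
(1–1000 bp); the pair's span, padded symmetrically to at least 50 bp
(clipped and flagged at chromosome edges), becomes a fragment.  The
fragment sequence substitutes the derived allele of **every** known SNP
inside the span — not only the seeding pair — because an unsubstituted
derived site would misrepresent the converted haplotype and spuriously
destroy exact donor matches.

Donor search is exact string matching of the fragment sequence over the
whole genome, both strands, excluding any occurrence overlapping the
acceptor span.  "Perfect match" is strict: one mismatch anywhere,
diagnostic or not, disqualifies a donor.  Fragments with a donor grow
greedily: merge the nearest SNP within 1 kb, re-check donors, stop when
donors vanish; the pre-merge extent is the event boundary.  Because any
occurrence of an extended fragment must extend an occurrence of the
current one, merges are verified locally at the known donor loci instead
of rescanning the genome — an optimisation with identical semantics.
Events need ≥ 2 converted SNPs; events whose converted-SNP set is a subset
of another's are duplicates of the same tract and are dropped.
`min_tract_length` is the span between the outermost converted SNPs
(inclusive), invariant to seeding order.

Donor selection: minimum same-chromosome gap between interval ends (0 when
adjacent; ties by coordinate); if all candidates lie on other chromosomes,
a seeded random choice.  Each chromosome is treated as one arm — the
simulator has no metacentric chromosomes — so interarm = interchromosomal.
Classes: proximal ≤ 10 kb, distal > 10 kb, interarm.  Donor multiplicity is
"multiple" when ≥ 2 exact candidates survive (all candidates are
sequence-identical by construction of the exact search).  GC direction
counts A/T→G/C vs. G/C→A/T over converted sites, excludes W↔W and S↔S
changes, and reports a two-sided binomial p against 0.5.

Polarity limitation: the reference allele is treated as ancestral, as
reference-relative calls imply; a derived reference allele would invert a
site's direction and hide donors carrying it.

## TE structural analysis (`lrmut.te`)

TSD: longest identical flank of 4–30 bp immediately on both sides of the
inserted block (the bounds are this module's choice; shorter identities are
indistinguishable from chance).  Complex = any immediate flanking deletion
(breakpoint gap 0) and/or a linked duplication.  The *hobo* motif check
tests positions 2 (= T) and 7 (= A) of the breakpoint 8-mer; other families
skip the check.  Duplications: ≥ 62 bp of breakpoint homology → NAHR;
otherwise error-prone repair, annotated with microhomology and de novo
insertion lengths.

Non-B DNA grammar (re-implemented rather than delegated to an external
predictor, so absolute counts are tool-specific and not comparable across
tools):

* G-quadruplex: ≥ 4 maximal G-tracts (≥ 3 G) chained greedily by the
  shortest 1–7-nt loop; C-tract pattern reported on the minus strand.
* Short tandem repeat: unit 1–9 bp, stretch ≥ max(5·unit, 10) bp under the
  self-alignment s[j] = s[j−unit] (partial trailing copies count).
* Direct repeat: unit ≥ 10 bp repeated once with spacer ≤ 10 bp; the widest
  legal unit is reported for each start pair.
* Inverted / mirror repeat: arms ≥ 6 bp (reverse-complementary /
  mirror-symmetric), spacer ≤ 100 bp.
* Z-DNA: ≥ 10 bp in which every dinucleotide step is GC/CG/GT/TG/AC/CA —
  alternating purine–pyrimidine with AT/TA steps excluded, the
  operationalisation of "rich in GC/GT steps".
* A-phased repeat: ≥ 3 A-tracts of 3–9 bp with centre spacing 8–12 bp
  (T-tracts on the minus strand).

Non-ACGT characters break all motifs.  Within a class the reported hits are
a maximum-cardinality non-overlapping subset (earliest-end greedy); this
makes per-class totals invariant under reverse complementation, which a
leftmost-greedy rule would not be.  Overlaps *across* classes count once
per class, so a window's total is the sum over classes.

Window enrichment extracts ± flank (200 or 1000 bp) around each breakpoint,
draws seeded random control windows of matching width (default 1000), and
compares total motif counts with one-sided rank-sum tests
(complex > simple, complex > random, simple > random); all-equal inputs
degenerate to p = 1 with a flag.

## Statistics (`lrmut.stats`)

Fisher's exact test, one-sided binomial, Wilcoxon rank-sum (exact null for
combined n ≤ 20 without ties, tie-corrected normal approximation
otherwise), and Pearson chi-square on 2×k tables sit behind one
`TestResult` surface; one-sided directions are always passed explicitly by
callers.  The standard distributions come from scipy; the test suite
cross-checks every exact test against independent enumeration oracles
(full hypergeometric sums, exhaustive rank permutations).  Report
percentages are rounded half-up to one decimal to match printed-report
style.  No multiple-testing correction is applied anywhere.

On the proximal-vs-remote × unique-vs-multiple donor contrast, note that
the natural 2×2 table [[15, 19], [4, 20]] gives a one-sided exact
p ≈ 0.026 (the suite verifies this against exhaustive enumeration); the
report prints the recomputed p next to the table it used.

## Synthetic-data generator (`lrmut.simulate`)

The generator emulates the statistical structure the analyses assume, with
one seed reproducing everything byte-for-byte (per-stage RNG streams are
derived from the seed plus fixed offsets).

* Background: i.i.d. nucleotides at 42% GC (fly-like); the simplest null
  for motif scans and donor searches.
* TE families: a 3-kb DNA transposon with the nTnnnnAn target motif and an
  8-bp TSD (hobo-like), a 5-kb LTR element (Copia-like, 5-bp TSD), and a
  4-kb non-LTR element (Jockey-like).  Four copies per family, each
  independently mutated at 2% per site; one family receives two extra
  byte-identical donor copies (one reverse-strand) to create multiple-donor
  events; the first copy of each family gets a partner 1.5–8 kb downstream
  so proximal, distal, and interarm donor geometries all exist.
* Conversions: tract lengths are log-normal with median 135 bp
  (sigma 0.6 — the distribution family is this package's choice; only the
  median is anchored).  A tract must contain ≥ 2 diagnostic sites at least
  25 bp inside its edges, consecutive converted sites ≤ 1 kb apart, and no
  unconverted diagnostic site within 50 bp of the outermost converted
  sites; these are exactly the geometries under which an exact-match
  detector can in principle recover the event, so recovery failures
  indicate detector defects rather than unplantable truths.  Conversions do
  not edit the reference sequence: they exist as derived SNP calls of the
  individuals.
* Insertions: simple insertions duplicate the target site (exact TSD);
  complex insertions carry an immediate flanking deletion of 3–380 bp
  (destroying the TSD) and/or a templated duplication of 45–600 bp with
  1–5 bp of junction microhomology and an optional 1–27-bp de novo
  insertion, in an 8:1:1 del/dup/del+dup rotation.  Edits never overlap
  (bounded resampling, then failure) and all prior truth coordinates are
  shifted into the edited frame; chromosome length satisfies
  original + inserted − deleted.
* Background SNPs: ~95% shared between the two individuals, 10%
  heterozygous; 25% planted as same-individual pairs with uniform 1–1000-bp
  spacing (clustered mutations from sources other than conversion) and 20%
  inside TE copies (so conversion explains only part of the TE SNP pool).
  All other placements stay > 1.1 kb from existing features so truth
  assignments stay unambiguous.
* Read support: reads of the 4.5-kb median length tiled uniformly at 50×
  mean coverage; homozygous SNPs are carried by every covering read,
  heterozygous ones by each read with probability one half; support flips
  with the per-base error (default 2.5×10⁻⁴, split 80/10/10 into
  substitutions, deletions, insertions), which places the median read QV
  near 36.

Default problem size is a 3 × 5 Mb genome with 20 conversion events,
30 simple + 9 complex insertions, and 240 background SNPs, giving a SNP
density at which observed clustering exceeds the positional null in all
four distance bins while a full pipeline run stays under a minute.
Not emulated: realistic chromatin or recombination landscapes, diploid
phasing, instrument-specific error profiles beyond i.i.d. errors,
metacentric arms, and nested/truncated TE copies.  Passing tests therefore
demonstrate algorithmic correctness under the stated generative model, not
performance on real fly data, where mapping artifacts, assembly errors and
segmental duplications add failure modes the generator does not produce.

## Pipeline and problem sizes

`run_pipeline` derives a stable per-stage seed from the global seed, runs
stages in dependency order, and writes a manifest with versions,
parameters, seeds and SHA-256 output digests; reruns differ only in
timestamps.  The unit-test suite uses a 3 × 300 kb fixture; parameter
recovery runs at the full 3 × 5 Mb default; the acceptance script uses
20,000 Monte Carlo replicates for the cSNP null, 200 random enrichment
windows, and a 200-dataset × 2000-replicate calibration — sizes chosen so
the whole acceptance run completes in well under a minute while keeping
Monte Carlo error far below the assertion tolerances.
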