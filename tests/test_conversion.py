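"""Gene-conversion detection: fragment seeding, exact donor search,
iterative event growth, classification, and GC direction."""

import numpy as np
import pytest

from lrmut.conversion import (
    ConversionEvent,
    DonorCandidate,
    Fragment,
    build_conversion_events,
    classify_conversion,
    conversion_gc_direction,
    find_perfect_donors,
    seed_fragments,
)
from lrmut.csnp import identify_csnps
from lrmut.simulate import revcomp
from lrmut.variants import filter_snp_calls


def test_close_pair_padded_to_50bp():
    chroms = {"c": "A" * 1000}
    frags = seed_fragments([("c", 500, "A", "T"), ("c", 505, "A", "G")], chroms)
    assert len(frags) == 1
    f = frags[0]
    assert f.end - f.start == 50
    assert f.start <= 500 and 505 < f.end
    assert len(f.member_snps) == 2


def test_distant_pair_spans_both_snps():
    chroms = {"c": "A" * 2000}
    frags = seed_fragments([("c", 100, "A", "T"), ("c", 700, "A", "G")], chroms)
    assert len(frags) == 1
    assert (frags[0].start, frags[0].end) == (100, 701)


def test_no_csnps_no_fragments():
    assert seed_fragments([], {"c": "ACGT"}) == []


def test_fragment_clipped_at_chromosome_edge():
    chroms = {"c": "A" * 30}
    frags = seed_fragments([("c", 2, "A", "T"), ("c", 5, "A", "G")], chroms)
    assert frags[0].clipped
    assert frags[0].start == 0


def sliding_window_donor_oracle(fragment, chromosomes):
    """Brute force: compare every genomic window of fragment length on both
    strands against the derived-allele fragment sequence."""
    target = fragment.sequence(chromosomes)
    L = len(target)
    rc = revcomp(target)
    hits = set()
    for chrom, seq in chromosomes.items():
        for s in range(len(seq) - L + 1):
            window = seq[s : s + L]
            if chrom == fragment.chrom and s < fragment.end and fragment.start < s + L:
                continue
            if window == target:
                hits.add((chrom, s, "+"))
            if window == rc and rc != target:
                hits.add((chrom, s, "-"))
    return hits


def test_donor_search_equals_sliding_window_oracle():
    rng = np.random.default_rng(4)
    base = "".join(rng.choice(list("ACGT"), size=30_000))
    paralog = base[5000:5060]
    chroms = {"c1": base, "c2": base[10_000:20_000] + paralog + base[3000:6000]}
    frag = Fragment("c1", 5000, 5060,
                    [(5010, base[5010], base[5010]), (5030, base[5030], base[5030])])
    found = {(d.chrom, d.start, d.strand) for d in find_perfect_donors(frag, chroms)}
    assert found == sliding_window_donor_oracle(frag, chroms)
    assert found  # the planted paralog must be recovered


def test_acceptor_locus_excluded_from_donors():
    chroms = {"c": "ACGTACGTACGT" * 20}
    frag = Fragment("c", 0, 12, [(0, "A", "A")])
    donors = find_perfect_donors(frag, chroms)
    assert all(not (d.chrom == "c" and d.start < 12 and 0 < d.end)
               for d in donors)
    assert donors  # periodic sequence has many true occurrences


def test_reverse_strand_donor_found():
    rng = np.random.default_rng(8)
    left = "".join(rng.choice(list("ACGT"), size=500))
    core = "".join(rng.choice(list("ACGT"), size=60))
    right = "".join(rng.choice(list("ACGT"), size=500))
    chroms = {"c1": left + core + right,
              "c2": "".join(rng.choice(list("ACGT"), size=300)) + revcomp(core)}
    frag = Fragment("c1", 500, 560, [(510, core[10], core[10])])
    donors = find_perfect_donors(frag, chroms)
    assert any(d.strand == "-" and d.chrom == "c2" for d in donors)


def _detect(genome, support, seed=7):
    kept, _ = filter_snp_calls(support.calls)
    clustered, _ = identify_csnps(kept)
    csnps = [c.key for c in kept if c.key in clustered]
    frags = seed_fragments(csnps, genome.chromosomes)
    return build_conversion_events(frags, [c.key for c in kept],
                                   genome.chromosomes, seed=seed)


def test_planted_events_recovered_with_boundaries(small_genome):
    """Error-free planted events are recovered with exactly the planted
    converted-SNP sets; detected donors carry the derived alleles."""
    _cfg, genome, support = small_genome
    events = _detect(genome, support)
    truth = {frozenset(p for p, _r, _a in ev.converted_sites): ev
             for ev in genome.truth_conversions}
    detected = {frozenset(p for p, _r, _a in ev.converted_snps): ev
                for ev in events}
    assert set(truth) <= set(detected)
    for key, ev in detected.items():
        if key in truth:
            t = truth[key]
            assert ev.min_tract_length == t.min_tract_length


def test_event_boundary_stops_when_merge_loses_donors():
    """A fragment whose merge with the next SNP loses all donors keeps its
    pre-merge extent."""
    rng = np.random.default_rng(12)
    base = "".join(rng.choice(list("ACGT"), size=4000))
    # acceptor region 1000-1100 duplicated at 3000; a stray SNP at 1150 that
    # the duplicate does not carry
    seq = base[:3000] + base[1000:1100] + base[3100:]
    chroms = {"c": seq}
    snps = [("c", 1020, seq[1020], seq[1020]), ("c", 1040, seq[1040], seq[1040]),
            ("c", 1150, seq[1150], "A" if seq[1150] != "A" else "C")]
    frags = seed_fragments(snps[:2], chroms)
    events = build_conversion_events(frags, snps, chroms, seed=0)
    assert len(events) == 1
    assert {p for p, _r, _a in events[0].converted_snps} == {1020, 1040}
    assert events[0].end <= 1150


def donor(distance, chrom="c1"):
    return DonorCandidate(chrom, 0, 10, "+", distance)


def test_distance_classification_boundaries():
    assert classify_conversion(_event(donor(10_000))) == "proximal"
    assert classify_conversion(_event(donor(10_001))) == "distal"
    assert classify_conversion(_event(donor(50_000))) == "distal"
    assert classify_conversion(_event(DonorCandidate("c2", 0, 10, "+", None))) \
        == "interarm"


def _event(chosen):
    return ConversionEvent("c1", 0, 10, [(1, "A", "G"), (2, "A", "G")], [chosen],
                           chosen, "unique", "proximal", 2)


def test_missing_donor_raises():
    ev = _event(donor(5))
    ev.chosen_donor = None
    with pytest.raises(ValueError):
        classify_conversion(ev)


def test_donor_tie_break_reproducible(small_genome):
    _cfg, genome, support = small_genome
    e1 = _detect(genome, support, seed=99)
    e2 = _detect(genome, support, seed=99)
    assert [ev.chosen_donor for ev in e1] == [ev.chosen_donor for ev in e2]


def test_gc_direction_counts():
    events = [_event(donor(5))]
    events[0].converted_snps = [(1, "A", "G"), (2, "T", "C"), (3, "G", "A")]
    summary = conversion_gc_direction(events)
    assert (summary.n_weak_to_strong, summary.n_strong_to_weak) == (2, 1)


def test_gc_direction_symmetric_counts_p_one():
    events = [_event(donor(5))]
    events[0].converted_snps = ([(i, "A", "G") for i in range(5)]
                                + [(i + 10, "G", "A") for i in range(5)])
    summary = conversion_gc_direction(events)
    assert summary.p_value == pytest.approx(1.0)


def test_gc_direction_excludes_weak_weak_and_strong_strong():
    events = [_event(donor(5))]
    events[0].converted_snps = [(1, "A", "T"), (2, "G", "C"), (3, "A", "G")]
    summary = conversion_gc_direction(events)
    assert summary.n_excluded == 2
    assert (summary.n_weak_to_strong, summary.n_strong_to_weak) == (1, 0)


def test_gc_direction_calibrated_under_neutral_simulation():
    """Direction-neutral converted sites reject symmetry at alpha = 0.05
    about 5% of the time."""
    rng = np.random.default_rng(17)
    rejections = 0
    n_sim = 400
    for _ in range(n_sim):
        ev = _event(donor(5))
        ev.converted_snps = [
            (i, "A", "G") if rng.random() < 0.5 else (i, "G", "A")
            for i in range(30)
        ]
        rejections += conversion_gc_direction([ev]).p_value <= 0.05
    rate = rejections / n_sim
    assert abs(rate - 0.05) <= 0.035  # binomial CI around the nominal level
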