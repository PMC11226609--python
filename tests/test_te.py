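"""TSD detection, transposition classes, non-B motif grammar vs. a
brute-force oracle, window enrichment, duplication mechanisms."""

import itertools
import re

import numpy as np
import pytest

from lrmut.simulate import revcomp
from lrmut.te import (
    DuplicationCall,
    LinkedDuplication,
    MOTIF_CLASSES,
    TEInsertionCall,
    classify_duplication_mechanism,
    classify_transposition,
    detect_tsd,
    hobo_motif_match,
    scan_nonb_motifs,
    window_motif_enrichment,
)

# --- TSD -------------------------------------------------------------------


def _genome_with_insertion(tsd, te="GATTACA" * 30, left=None, right=None):
    rng = np.random.default_rng(2)
    left = left or "".join(rng.choice(list("ACGT"), size=200))
    right = right or "".join(rng.choice(list("ACGT"), size=200))
    seq = left + tsd + te + tsd + right
    start = len(left) + len(tsd)
    return {"c": seq}, TEInsertionCall("c", start, start + len(te), "hobo")


def test_exact_tsd_recovered():
    chroms, call = _genome_with_insertion("ACGTTGCA")
    assert detect_tsd(chroms, call) == "ACGTTGCA"


def test_short_flanking_identity_below_minimum_is_absent():
    chroms, call = _genome_with_insertion("TAG")  # 3 bp < 4 bp minimum
    assert detect_tsd(chroms, call) is None


def test_tsd_absent_with_flanking_deletion():
    rng = np.random.default_rng(3)
    left = "".join(rng.choice(list("ACGT"), size=200))
    te = "GATTACA" * 30
    right = "".join(rng.choice(list("ACGT"), size=200))
    chroms = {"c": left + te + right}  # deletion destroyed the duplicate
    call = TEInsertionCall("c", 200, 200 + len(te), "hobo",
                           flank_deletion_length=50)
    assert detect_tsd(chroms, call) is None


def test_tsd_at_contig_edge_flagged_absent():
    chroms = {"c": "GATTACA" * 10}
    call = TEInsertionCall("c", 0, 20, "hobo")
    assert detect_tsd(chroms, call) is None


# --- classification ----------------------------------------------------------


def test_hobo_motif_pattern():
    assert hobo_motif_match("ATAGCTAG")
    assert not hobo_motif_match("AAAGCTAG")


def test_classification_partition():
    simple = TEInsertionCall("c", 0, 10, "hobo", breakpoint_kmer="ATAGCTAG")
    deleted = TEInsertionCall("c", 0, 10, "Jockey", flank_deletion_length=190)
    dup = TEInsertionCall("c", 0, 10, "hobo",
                          linked_duplication=LinkedDuplication(("c", 50, 95), 1, 7))
    assert classify_transposition(simple) == ("simple", True)
    assert classify_transposition(deleted)[0] == "complex"
    assert classify_transposition(deleted)[1] is None  # motif only for hobo
    assert classify_transposition(dup)[0] == "complex"


# --- non-B motif oracle ------------------------------------------------------


def _oracle_nonoverlap(cands):
    out, last = [], -1
    for s, e, strand in sorted(cands, key=lambda c: (c[1], c[0])):
        if s >= last:
            out.append((s, e, strand))
            last = e
    return out


def _oracle_runs(seq, base):
    runs, i = [], 0
    while i < len(seq):
        if seq[i] == base:
            j = i
            while j < len(seq) and seq[j] == base:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _oracle_g4(seq):
    cands = []
    for base, strand in (("G", "+"), ("C", "-")):
        runs = [(s, e) for s, e in _oracle_runs(seq, base) if e - s >= 3]
        by_start = dict(runs)
        for s, e in runs:
            cursor, tracts = e, 1
            while True:
                step = next((cursor + g for g in range(1, 8)
                             if cursor + g in by_start), None)
                if step is None:
                    break
                cursor, tracts = by_start[step], tracts + 1
            if tracts >= 4:
                cands.append((s, cursor, strand))
    return cands


def _oracle_str(seq):
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    cands = []
    best = np.zeros(n, dtype=int)
    for u in range(1, 10):
        eq = arr[u:] == arr[:-u]
        false_idx = np.flatnonzero(~eq)
        for i in range(n - u):
            k = np.searchsorted(false_idx, i)
            nxt = false_idx[k] if k < len(false_idx) else n - u
            stretch = u + (nxt - i)
            if stretch >= max(5 * u, 10) and stretch > best[i]:
                best[i] = stretch
    for i in range(n):
        if best[i]:
            cands.append((i, i + best[i], "+"))
    return cands


def _oracle_direct(seq):
    n, cands = len(seq), []
    for i in range(n):
        for d in range(10, n - i):
            m = 0
            while i + m < i + d and i + d + m < n and seq[i + m] == seq[i + d + m]:
                m += 1
            u = min(m, d)
            if u >= 10 and d - u <= 10:
                cands.append((i, i + d + u, "+"))
    return cands


def _oracle_palindrome(seq, mirror):
    n, cands = len(seq), []
    for center in range(n + 1):
        for g in range(0, 101):
            a = 0
            while center - a - 1 >= 0 and center + g + a < n:
                left = seq[center - a - 1]
                right = seq[center + g + a]
                if mirror:
                    ok = left == right
                else:
                    ok = left == revcomp(right)
                if not ok:
                    break
                a += 1
            if a >= 6:
                cands.append((center - a, center + g + a, "+"))
    return cands


_Z_OK = {"GC", "CG", "GT", "TG", "AC", "CA"}


def _oracle_zdna(seq):
    flags = [seq[i : i + 2] in _Z_OK for i in range(len(seq) - 1)]
    cands, i = [], 0
    for ok, grp in itertools.groupby(enumerate(flags), key=lambda t: t[1]):
        grp = list(grp)
        if ok and len(grp) + 1 >= 10:
            cands.append((grp[0][0], grp[-1][0] + 2, "+"))
    return cands


def _oracle_aphased(seq):
    cands = []
    for base, strand in (("A", "+"), ("T", "-")):
        tracts = [(s, e) for s, e in _oracle_runs(seq, base) if 3 <= e - s <= 9]
        i = 0
        while i < len(tracts):
            j = i
            while (j + 1 < len(tracts)
                   and 8 <= ((tracts[j + 1][0] + tracts[j + 1][1])
                             - (tracts[j][0] + tracts[j][1])) / 2 <= 12):
                j += 1
            if j - i + 1 >= 3:
                cands.append((tracts[i][0], tracts[j][1], strand))
            i = j + 1
    return cands


_ORACLES = {
    "G_Quadruplex_Motif": _oracle_g4,
    "Short_Tandem_Repeat": _oracle_str,
    "Direct_Repeat": _oracle_direct,
    "Inverted_Repeat": lambda s: _oracle_palindrome(s, mirror=False),
    "Mirror_Repeat": lambda s: _oracle_palindrome(s, mirror=True),
    "Z_DNA_Motif": _oracle_zdna,
    "A_Phased_Repeat": _oracle_aphased,
}


def oracle_scan(seq):
    hits = set()
    for m in re.finditer("[ACGT]+", seq.upper()):
        seg, off = m.group(), m.start()
        for cls, fn in _ORACLES.items():
            for s, e, strand in _oracle_nonoverlap(fn(seg)):
                hits.add((cls, off + s, off + e, strand))
    return hits


SPIKED = (
    "GGGACGGGTGGGAGGGT"  # G4
    + "ATATATATATATAT"  # STR
    + "ACGTACGTCGTA"
    + "GCGCGTGCACGC"  # Z-DNA
    + "AAAGCTTTAAAACGGTAAAG"  # phased A-tracts
    + "TTTACGCATTTTGACGTTTC"
    + "CAGGTCAGGTX"
)


def test_g4_and_str_hits_present():
    classes = {h.motif_class for h in scan_nonb_motifs(SPIKED)}
    assert "G_Quadruplex_Motif" in classes
    assert "Short_Tandem_Repeat" in classes
    assert "Z_DNA_Motif" in classes


def test_empty_sequence_empty_hits():
    assert scan_nonb_motifs("") == []


def test_n_breaks_motifs():
    hits = scan_nonb_motifs("GGGAGGGAGGGAGGG" + "N" + "GGGAGGGAGGGAGGG")
    g4 = [h for h in hits if h.motif_class == "G_Quadruplex_Motif"]
    assert len(g4) == 2
    assert all(not (h.start < 16 <= h.end) for h in g4)


def test_scan_matches_brute_force_oracle_on_random_sequences():
    rng = np.random.default_rng(11)
    for trial in range(4):
        seq = "".join(rng.choice(list("ACGT"), size=600,
                                 p=[0.3, 0.25, 0.25, 0.2]))
        if trial % 2:
            insert = SPIKED * 1
            pos = int(rng.integers(0, len(seq) - len(insert)))
            seq = seq[:pos] + insert + seq[pos + len(insert):]
        got = {(h.motif_class, h.start, h.end, h.strand)
               for h in scan_nonb_motifs(seq)}
        assert got == oracle_scan(seq)


def test_total_counts_invariant_under_reverse_complement():
    rng = np.random.default_rng(13)
    seq = "".join(rng.choice(list("ACGT"), size=800)) + SPIKED
    fwd = scan_nonb_motifs(seq)
    rev = scan_nonb_motifs(revcomp(seq))
    for cls in MOTIF_CLASSES:
        assert (sum(h.motif_class == cls for h in fwd)
                == sum(h.motif_class == cls for h in rev)), cls


# --- window enrichment -------------------------------------------------------

G4_CLUSTER = "GGGAGGGAGGGAGGGAA" * 3 + "CACACACACACACACA" + "GGGTGGGTGGGTGGG"
ONE_STR = "ATATATATATAT"


def _enrichment_genome():
    rng = np.random.default_rng(21)
    seq = "".join(rng.choice(list("ACGT"), size=80_000))

    def plant(s, p, block):
        return s[: p - len(block) // 2] + block + s[p - len(block) // 2 + len(block):]

    complex_sites, simple_sites = [], []
    for k in range(6):
        p = 5000 + 6000 * k
        seq = plant(seq, p, G4_CLUSTER)
        seq = plant(seq, p + 500, G4_CLUSTER)  # inside the 1000-bp flank only
        complex_sites.append(("c", p))
    for k in range(6):
        p = 45_000 + 3000 * k
        seq = plant(seq, p, ONE_STR)
        simple_sites.append(("c", p + 5))
    return {"c": seq}, complex_sites, simple_sites


def test_enrichment_ordering_on_spiked_sites():
    """Complex sites planted in G4/STR clusters score above simple sites,
    which score above random windows; the ordering survives the larger
    window size."""
    chroms, complex_sites, simple_sites = _enrichment_genome()
    orderings = []
    for flank in (200, 1000):
        rows, tests = window_motif_enrichment(
            {"complex": complex_sites, "simple": simple_sites}, chroms,
            flank=flank, n_random=60, seed=5)
        med = {g: np.median([r.total_motif_count for r in rows if r.group == g])
               for g in ("complex", "simple", "random")}
        orderings.append(med["complex"] > med["simple"] >= med["random"])
        assert tests["complex_gt_simple"].p_value < 0.05
        assert tests["complex_gt_random"].p_value < 0.05
    assert all(orderings)


def test_enrichment_degenerate_on_motif_free_genome():
    chroms = {"c": "ACGT" * 3000}  # STR-free? no: ACGT repeats are STRs of unit 4
    chroms = {"c": ("ACGTTGCAAC" * 1200)[:12_000]}
    rows, tests = window_motif_enrichment(
        {"complex": [("c", 6000)], "simple": [("c", 3000)]}, chroms,
        flank=100, n_random=20, seed=1)
    # identical constant counts in every group degenerate to p = 1
    for t in tests.values():
        if "degenerate_constant" in t.flags:
            assert t.p_value == 1.0


def test_enrichment_requires_nonempty_groups():
    with pytest.raises(ValueError):
        window_motif_enrichment({"complex": []}, {"c": "ACGT" * 100}, seed=0)


# --- duplication mechanism ---------------------------------------------------


def test_duplication_mechanism_boundary():
    nahr = classify_duplication_mechanism(
        DuplicationCall(("c", 0, 100), "tandem", 62))
    assert nahr["mechanism"] == "NAHR"
    repair = classify_duplication_mechanism(
        DuplicationCall(("c", 0, 100), "tandem", 1, de_novo_insertion_length=7))
    assert repair["mechanism"] == "repair"
    assert repair["de_novo_insertion_length"] == 7
    zero = classify_duplication_mechanism(DuplicationCall(("c", 0, 9), "inverted", 0))
    assert zero["mechanism"] == "repair"


def test_duplication_mechanism_rejects_negative_lengths():
    with pytest.raises(ValueError):
        classify_duplication_mechanism(DuplicationCall(("c", 0, 9), "tandem", -1))
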