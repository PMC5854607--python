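"""Composition statistics, local alignment, ANI, hit filtering, BBH,
aligned fraction and gene presence — each against a brute-force oracle
where the operation's contract allows one."""

import itertools

import numpy as np
import pytest

from strainsieve import genomecmp as gc, simulate as sim
from strainsieve.genomecmp import AlignScoring
from strainsieve.model import (
    AlignmentRecord,
    GeneModel,
    GenomeSequence,
    PairwiseHit,
)

# ---------------------------------------------------------------------------
# Composition


def test_gc_percent_simple():
    st = gc.genome_stats(GenomeSequence("g", "ATGC"))
    assert st.gc_percent == 50.0


def test_gc_skew_example():
    st = gc.genome_stats(GenomeSequence("g", "GGGC"), window=4)
    assert st.windows[0].gc_skew == pytest.approx(0.5)


def test_n_excluded_from_gc_denominator():
    st = gc.genome_stats(GenomeSequence("g", "GGNN"))
    assert st.gc_percent == 100.0


def test_skew_undefined_flagged():
    st = gc.genome_stats(GenomeSequence("g", "AATT"), window=4)
    assert st.windows[0].gc_skew == 0.0 and not st.windows[0].skew_defined


def test_window_stats_match_recount_oracle(rng):
    g = sim.random_genome(10_000, rng, id="g")
    st = gc.genome_stats(g, window=1000)
    for w in st.windows:
        piece = g.residues[w.start : w.end]
        expect_gc = 100 * (piece.count("G") + piece.count("C")) / len(piece)
        assert w.gc_percent == pytest.approx(expect_gc)
        gcsum = piece.count("G") + piece.count("C")
        if gcsum:
            assert w.gc_skew == pytest.approx((piece.count("G") - piece.count("C")) / gcsum)
    assert st.windows[-1].full == (len(g) % 1000 == 0)


def test_gc_deviant_window_arithmetic():
    # three full windows at GC 40/50/41, genome mean ~43.67 -> one deviant
    parts = []
    for frac in (0.40, 0.50, 0.41):
        n_gc = int(100 * frac)
        parts.append("G" * n_gc + "A" * (100 - n_gc))
    g = GenomeSequence("g", "".join(parts))
    n, windows = gc.gc_deviant_windows(g, window=100, threshold_pp=5.0)
    assert n == 1 and windows == [(100, 200)]


def test_uniform_genome_has_no_deviant_windows():
    g = GenomeSequence("g", "ACGT" * 1000)
    n, _ = gc.gc_deviant_windows(g, window=1000)
    assert n == 0


def test_deviant_windows_match_scan_oracle(rng):
    pieces = [
        sim.random_genome(500, rng, gc=float(rng.uniform(0.2, 0.7))).residues
        for _ in range(12)
    ]
    g = GenomeSequence("g", "".join(pieces))
    n, windows = gc.gc_deviant_windows(g, window=500, threshold_pp=5.0)
    mean_gc = 100 * (g.residues.count("G") + g.residues.count("C")) / len(g)
    expected = []
    for s in range(0, len(g), 500):
        w = g.residues[s : s + 500]
        if len(w) < 500:
            continue
        wgc = 100 * (w.count("G") + w.count("C")) / 500
        if abs(wgc - mean_gc) >= 5.0:
            expected.append((s, s + 500))
    assert windows == expected and n == len(expected)


# ---------------------------------------------------------------------------
# Local alignment vs exhaustive enumeration


def global_affine_enumeration(a, b, sc):
    """Best global alignment score of a vs b by exhaustive recursion:
    every monotone column sequence, affine gaps (open = first gap base,
    extend = each further)."""

    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            col = sc.match if a[i] == b[j] else sc.mismatch
            best = max(best, col + rec(i + 1, j + 1, "m"))
        if i < len(a):
            gap = sc.gap_extend if state == "ga" else sc.gap_open
            best = max(best, gap + rec(i + 1, j, "ga"))
        if j < len(b):
            gap = sc.gap_extend if state == "gb" else sc.gap_open
            best = max(best, gap + rec(i, j + 1, "gb"))
        return best

    return rec(0, 0, "m")


def local_oracle(a, b, sc):
    best = 0.0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, global_affine_enumeration(a[i1:i2], b[j1:j2], sc))
    return best


def test_local_align_identity_case():
    aln = gc.local_align("ACGT", "ACGT")
    assert (aln.score, aln.identity) == (4.0, 100.0)


def test_local_align_empty_alignment_convention():
    aln = gc.local_align("AAAA", "TTTT")
    assert aln.score == 0.0 and aln.columns == 0


def test_local_align_rejects_empty_and_oversized():
    with pytest.raises(ValueError):
        gc.local_align("", "ACGT")
    with pytest.raises(ValueError):
        gc.local_align("A" * 3000, "A" * 3000, size_cap=1000)


@pytest.mark.parametrize("seed", range(6))
def test_local_align_matches_enumeration_oracle(seed):
    """Sequence pairs over {A,C} up to length 6: exact scores equal the
    exhaustive alignment enumeration."""
    rng = np.random.default_rng(seed)
    sc = AlignScoring()
    for _ in range(4):
        a = "".join(rng.choice(["A", "C"], size=rng.integers(1, 7)))
        b = "".join(rng.choice(["A", "C"], size=rng.integers(1, 7)))
        assert gc.local_align(a, b, scoring=sc).score == pytest.approx(
            local_oracle(a, b, sc)
        )


def test_protein_alignment_uses_substitution_matrix():
    aln = gc.local_align("MKV", "MKV", alphabet="protein")
    assert aln.identity == 100.0 and aln.score > 10


# ---------------------------------------------------------------------------
# OrthoANI


def test_orthoani_self_identity(rng):
    g = sim.random_genome(20_000, rng, id="g")
    res = gc.orthoani(g, g)
    assert res.ani == 100.0
    assert res.n_fragment_pairs == len(g) // 1020


def test_orthoani_substitution_band(rng):
    g = sim.random_genome(30_000, rng, id="A")
    arr = np.frombuffer(g.residues.encode(), np.uint8).copy()
    bases = np.frombuffer(b"ACGT", np.uint8)
    lut = np.zeros(256, np.int64)
    lut[bases] = np.arange(4)
    hit = rng.random(len(arr)) < 0.01
    arr[hit] = bases[(lut[arr[hit]] + rng.integers(1, 4, int(hit.sum()))) % 4]
    g2 = GenomeSequence("B", arr.tobytes().decode())
    res = gc.orthoani(g, g2)
    assert 98.5 <= res.ani <= 99.5


def test_orthoani_symmetric_by_construction(rng):
    g = sim.random_genome(12_000, rng, id="A")
    h = sim.random_genome(12_000, rng, id="B")
    cfg = sim.StrainSimConfig(backbone_len=12_000, unique_region_len=1000, seed=2)
    assert gc.orthoani(g, g).ani == gc.orthoani(g, g).ani
    ab = gc.orthoani(g, h, fragment_len=1020)
    ba = gc.orthoani(h, g, fragment_len=1020)
    if ab.defined and ba.defined:
        assert ab.ani == pytest.approx(ba.ani)


def test_orthoani_short_genome_undefined(rng):
    g = sim.random_genome(500, rng, id="s")
    res = gc.orthoani(g, g)
    assert not res.defined and res.n_fragment_pairs == 0


def test_orthoani_finds_reverse_complement_homology(rng):
    g = sim.random_genome(5_100, rng, id="A")
    g2 = GenomeSequence("B", sim.revcomp(g.residues))
    res = gc.orthoani(g, g2)
    assert res.defined and res.ani == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# Hit filtering / BBH / unique genes


def hit(q, s, identity, qcov, bitscore=100.0, evalue=1e-10):
    qlen = 100
    return PairwiseHit(
        query_id=q, subject_id=s, identity=identity,
        aln_len=int(qcov * qlen), query_len=qlen, subject_len=100,
        bitscore=bitscore, evalue=evalue,
    )


def test_filter_hits_boundaries():
    assert gc.filter_hits([hit("a", "b", 92, 0.80)])
    assert not gc.filter_hits([hit("a", "b", 92, 0.75)])
    assert not gc.filter_hits([hit("a", "b", 92, 1.20)])
    assert not gc.filter_hits([hit("a", "b", 89.9, 0.80)])
    assert gc.filter_hits([hit("a", "b", 90.0, 0.80)])


def test_filter_hits_matches_predicate_oracle(rng):
    hits = [
        hit(f"q{i}", "s", float(rng.uniform(80, 100)), float(rng.uniform(0.5, 1.4)))
        for i in range(300)
    ]
    got = gc.filter_hits(hits)
    oracle = [
        h for h in hits if h.identity >= 90 and 0.75 < h.aln_len / h.query_len < 1.20
    ]
    assert got == oracle


def test_filter_hits_shrinks_as_filters_tighten(rng):
    hits = [
        hit(f"q{i}", "s", float(rng.uniform(80, 100)), float(rng.uniform(0.5, 1.4)))
        for i in range(200)
    ]
    loose = gc.filter_hits(hits, min_identity=85)
    tight = gc.filter_hits(hits, min_identity=95)
    narrow = gc.filter_hits(hits, min_identity=85, qcov_low=0.9, qcov_high=1.1)
    assert set(h.query_id for h in tight) <= set(h.query_id for h in loose)
    assert len(narrow) <= len(loose)


def test_bbh_single_reciprocal_pair():
    ab = [hit("a1", "b1", 95, 1.0)]
    ba = [hit("b1", "a1", 95, 1.0)]
    assert gc.best_bidirectional_hits(ab, ba) == [("a1", "b1")]


def test_bbh_requires_reciprocity():
    ab = [hit("a1", "b1", 95, 1.0, bitscore=100)]
    ba = [hit("b1", "a2", 95, 1.0, bitscore=200), hit("b1", "a1", 95, 1.0, bitscore=50)]
    assert gc.best_bidirectional_hits(ab, ba) == []


def test_bbh_matches_exhaustive_reciprocal_oracle(rng):
    genes_a = [f"a{i}" for i in range(40)]
    genes_b = [f"b{i}" for i in range(40)]
    def table(qs, ss):
        out = []
        for q in qs:
            for s in rng.choice(ss, size=8, replace=False):
                out.append(
                    hit(q, str(s), float(rng.uniform(85, 100)), 1.0,
                        bitscore=float(rng.integers(50, 500)),
                        evalue=float(rng.uniform(1e-50, 1e-5)))
                )
        return out

    ab, ba = table(genes_a, genes_b), table(genes_b, genes_a)
    got = gc.best_bidirectional_hits(ab, ba, min_identity=90)

    def best(hits, q):
        cands = [h for h in hits if h.query_id == q and h.identity >= 90]
        if not cands:
            return None
        return min(cands, key=lambda h: (-h.bitscore, h.evalue, h.subject_id)).subject_id

    oracle = sorted(
        (a, b)
        for a in genes_a
        for b in [best(ab, a)]
        if b is not None and best(ba, b) == a
    )
    assert got == oracle
    # partial matching: no gene twice
    assert len({a for a, _ in got}) == len(got)
    assert len({b for _, b in got}) == len(got)


def test_unique_genes_partition(rng):
    genes = {f"g{i}" for i in range(30)}
    hits = [hit(f"g{i}", "s", 95, 1.0) for i in range(0, 30, 2)]
    filtered = gc.filter_hits(hits)
    unique = gc.unique_genes(genes, filtered)
    with_hit = {h.query_id for h in filtered}
    assert unique | with_hit == genes and not unique & with_hit


# ---------------------------------------------------------------------------
# Aligned fraction & gene presence


def galn(qs, qe, identity=0.96, qlen=1000, target="B", tlen=2000):
    m = int((qe - qs) * identity)
    return AlignmentRecord(
        read_id="A", read_len=qlen, read_start=qs, read_end=qe, strand="+",
        target_id=target, target_len=tlen, target_start=0, target_end=qe - qs,
        matches=m, block_len=qe - qs,
    )


def test_aligned_fraction_simple_and_union():
    assert gc.aligned_fraction([galn(0, 500)], query_len=1000) == 0.5
    two = [galn(0, 600), galn(400, 800)]
    assert gc.aligned_fraction(two, query_len=1000) == pytest.approx(0.8)


def test_aligned_fraction_identity_floor():
    low = galn(0, 500, identity=0.90)
    assert gc.aligned_fraction([low], query_len=1000, min_identity=95) == 0.0


def test_aligned_fraction_matches_per_base_oracle(rng):
    alns = []
    for _ in range(60):
        s = int(rng.integers(0, 900))
        alns.append(galn(s, s + int(rng.integers(10, 100)),
                         identity=float(rng.uniform(0.90, 1.0))))
    frac = gc.aligned_fraction(alns, query_len=1000, min_identity=95)
    covered = np.zeros(1000, bool)
    for a in alns:
        if a.identity * 100 >= 95:
            covered[a.read_start : a.read_end] = True
    assert frac == pytest.approx(covered.mean())


def test_aligned_fraction_monotone_in_identity(rng):
    alns = [galn(int(s), int(s) + 50, identity=float(rng.uniform(0.9, 1.0)))
            for s in rng.integers(0, 950, 40)]
    fracs = [gc.aligned_fraction(alns, query_len=1000, min_identity=m)
             for m in (90, 93, 96, 99)]
    assert all(b <= a for a, b in zip(fracs, fracs[1:]))
    assert all(0 <= f <= 1 for f in fracs)


def raln(target_start, target_end, rid="r", target="chr", tlen=5000):
    return AlignmentRecord(
        read_id=rid, read_len=target_end - target_start, read_start=0,
        read_end=target_end - target_start, strand="+", target_id=target,
        target_len=tlen, target_start=target_start, target_end=target_end,
        matches=target_end - target_start, block_len=target_end - target_start,
    )


def test_gene_presence_classification():
    genes = [
        GeneModel("absent", "chr", 0, 100, "+"),
        GeneModel("partial", "chr", 1000, 2000, "+"),  # 70% covered
        GeneModel("present", "chr", 3000, 4000, "+"),  # 90% covered
    ]
    alns = [raln(1000, 1700, "r1"), raln(3000, 3900, "r2")]
    out = {p.gene_id: p for p in gc.gene_presence(genes, alns)}
    assert out["absent"].status == "absent" and out["absent"].covered_fraction == 0
    assert out["partial"].status == "partial"
    assert out["partial"].covered_fraction == pytest.approx(0.7)
    assert out["present"].status == "present"


def test_gene_presence_boundary_is_partial_only_above_threshold():
    genes = [GeneModel("g", "chr", 0, 100, "+")]
    # exactly 25% uncovered -> still present (strict >)
    out = gc.gene_presence(genes, [raln(0, 75)])
    assert out[0].status == "present"
    out = gc.gene_presence(genes, [raln(0, 74)])
    assert out[0].status == "partial"
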