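"""Depth, binning, refinement, low-coverage regions, circularization
and junction-spanning reads, each against an independent oracle."""

import numpy as np
import pytest

from strainsieve import covbin, simulate as sim
from strainsieve.covbin import CoverageBinSpec, DepthInterval
from strainsieve.model import AlignmentRecord, GenomeSequence


def aln(start, end, read_id="r", target_len=2000, target="t"):
    return AlignmentRecord(
        read_id=read_id, read_len=end - start, read_start=0, read_end=end - start,
        strand="+", target_id=target, target_len=target_len,
        target_start=start, target_end=end,
        matches=end - start, block_len=end - start,
    )


# ---------------------------------------------------------------------------
# Depth


def test_depth_interval_counting_example():
    prof = covbin.compute_depth([aln(0, 10, target_len=20), aln(5, 15, target_len=20)], 20)
    expected = [1] * 5 + [2] * 5 + [1] * 5 + [0] * 5
    assert prof.depth.tolist() == expected


def test_depth_no_alignments_all_zero():
    assert covbin.compute_depth([], 50).depth.tolist() == [0] * 50


def test_depth_out_of_bounds_is_error():
    with pytest.raises(ValueError):
        covbin.compute_depth([aln(1990, 2010, target_len=2000)], 2000)


def test_depth_matches_membership_scan_oracle(rng):
    alns = []
    for i in range(500):
        s = int(rng.integers(0, 1990))
        alns.append(aln(s, s + int(rng.integers(1, 2000 - s + 1)), f"r{i}"))
    prof = covbin.compute_depth(alns, 2000)
    oracle = np.array(
        [sum(a.target_start <= i < a.target_end for a in alns) for i in range(2000)]
    )
    assert (prof.depth == oracle).all()


def test_depth_conservation_invariant(rng):
    alns = [aln(int(s), int(s) + 50, f"r{i}") for i, s in enumerate(rng.integers(0, 1950, 80))]
    prof = covbin.compute_depth(alns, 2000)
    assert prof.depth.sum() == sum(a.target_end - a.target_start for a in alns)


# ---------------------------------------------------------------------------
# Footprint statistic


def test_footprint_median_and_mean():
    prof = covbin.DepthProfile("t", np.array([1, 2, 2, 3, 10, 0, 0, 0, 0, 0, 5]))
    a = aln(0, 5, target_len=11)
    assert covbin.footprint_stat(a, prof, "median") == 2
    b = aln(10, 11, target_len=11)
    assert covbin.footprint_stat(b, prof, "median") == 5  # single base
    prof2 = covbin.DepthProfile("t", np.arange(11))
    assert covbin.footprint_stat(aln(0, 11, target_len=11), prof2, "mean") == 5


# ---------------------------------------------------------------------------
# Binning


def specs():
    return covbin.default_bin_specs()


@pytest.mark.parametrize(
    "stat,expected",
    [(250, {"high", "low"}), (60, {"low"}), (150, {"high"}), (20, set()),
     (115, {"high", "low"}), (110, set() | {"low"})],
)
def test_default_bin_thresholds(stat, expected):
    # 110 is not ">110" but sits inside [25,120]; (110,120] joins both bins
    got = {s.name for s in specs() if s.contains(stat)}
    assert got == expected


def test_assign_bins_matches_interval_membership_oracle(rng):
    alns = []
    depth = rng.integers(0, 300, size=3000)
    prof = covbin.DepthProfile("t", depth)
    for i in range(150):
        s = int(rng.integers(0, 2900))
        alns.append(aln(s, s + int(rng.integers(1, 100)), f"r{i}", target_len=3000))
    out = covbin.assign_bins(alns, prof, specs())
    for a, assignment in zip(alns, out):
        stat = float(np.median(depth[a.target_start : a.target_end]))
        expected = set()
        if stat > 110:
            expected.add("high")
        if 25 <= stat <= 120 or stat > 225:
            expected.add("low")
        assert assignment.bins == expected
        assert assignment.footprint_stat == stat


def test_binning_is_permutation_invariant(rng):
    depth = rng.integers(0, 300, size=1000)
    prof = covbin.DepthProfile("t", depth)
    alns = [aln(int(s), int(s) + 40, f"r{i}", target_len=1000)
            for i, s in enumerate(rng.integers(0, 960, 60))]
    fwd = {a.read_id: a.bins for a in covbin.assign_bins(alns, prof, specs())}
    rev = {a.read_id: a.bins for a in covbin.assign_bins(alns[::-1], prof, specs())}
    assert fwd == rev


def test_bins_overlap_above_225(rng):
    """Every footprint statistic above 225 lands in both bins — shared
    high-abundance regions feed both assemblies."""
    prof = covbin.DepthProfile("t", np.full(500, 300))
    alns = [aln(0, 500, "r0", target_len=500)]
    (assignment,) = covbin.assign_bins(alns, prof, specs())
    assert assignment.bins == {"high", "low"}


def test_relative_specs_rescale_with_median_depth():
    prof = covbin.DepthProfile("t", np.full(1000, 400))
    # at median 400 the scaled cutoffs are high > 183, very-high > 375
    alns = [aln(0, 1000, "r0", target_len=1000)]
    (assignment,) = covbin.assign_bins(alns, prof, covbin.default_bin_specs(relative=True))
    assert assignment.bins == {"high", "low"}


def test_refine_bin_partition(rng):
    assignments = [
        covbin.BinAssignment(f"r{i}", float(stat), frozenset({"high"}))
        for i, stat in enumerate(rng.integers(50, 200, 100))
    ]
    kept, excluded = covbin.refine_bin(assignments, min_depth=100)
    assert {a.read_id for a in kept} | {a.read_id for a in excluded} == {
        a.read_id for a in assignments
    }
    assert not ({a.read_id for a in kept} & {a.read_id for a in excluded})
    assert all(a.footprint_stat >= 100 for a in kept)
    assert all(a.footprint_stat < 100 for a in excluded)
    # direct-filter oracle
    assert {a.read_id for a in excluded} == {
        a.read_id for a in assignments if a.footprint_stat < 100
    }


def test_refine_bin_boundary_and_empty():
    a95 = covbin.BinAssignment("a", 95.0)
    a100 = covbin.BinAssignment("b", 100.0)
    kept, excluded = covbin.refine_bin([a95, a100], min_depth=100)
    assert excluded == [a95] and kept == [a100]
    kept, excluded = covbin.refine_bin([a100], min_depth=100)
    assert excluded == []


def test_select_contigs_by_depth():
    assert covbin.select_contigs_by_depth({"c1": 200, "c2": 150}) == {"c1"}
    assert covbin.select_contigs_by_depth({}) == set()
    assert covbin.select_contigs_by_depth({"c1": 200, "c2": 150}, 0) == {"c1", "c2"}
    assert covbin.select_contigs_by_depth({"c1": 190.0}) == set()  # strict


# ---------------------------------------------------------------------------
# Low-coverage regions


def test_low_coverage_region_example():
    prof = covbin.DepthProfile("t", np.array([30, 30, 10, 10, 10, 30]))
    assert covbin.low_coverage_regions(prof, 25, min_len=2) == [(2, 5)]


def test_low_coverage_min_len_filter():
    prof = covbin.DepthProfile("t", np.array([30, 10, 30]))
    assert covbin.low_coverage_regions(prof, 25, min_len=2) == []
    assert covbin.low_coverage_regions(prof, 25, min_len=1) == [(1, 2)]


def test_low_coverage_matches_scan_oracle(rng):
    depth = rng.integers(0, 60, size=4000)
    prof = covbin.DepthProfile("t", depth)
    got = covbin.low_coverage_regions(prof, 25, min_len=3, max_len=50)
    runs, start = [], None
    for i, d in enumerate(depth):
        if d < 25 and start is None:
            start = i
        elif d >= 25 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(depth)))
    assert got == [(s, e) for s, e in runs if 3 <= e - s <= 50]


# ---------------------------------------------------------------------------
# Circularization


def test_circularize_trivial_overlap():
    res = covbin.circularize(GenomeSequence("x", "ATGCCGATG"), min_overlap=3)
    assert res.circularized and res.overlap_len == 3
    assert res.genome.residues == covbin.least_rotation("ATGCCG")
    assert not res.ambiguous


def test_circularize_homopolymer_is_ambiguous():
    res = covbin.circularize(GenomeSequence("x", "A" * 12), min_overlap=2)
    assert res.circularized and res.ambiguous
    assert res.overlap_len == 6  # longest allowed (half the sequence)


def test_not_circularizable_is_a_result_not_an_error():
    res = covbin.circularize(GenomeSequence("x", "ACGTACGGTTAC"), min_overlap=5)
    assert not res.circularized and res.genome is None and res.overlap_len == 0


def test_circularize_recovers_canonical_form_from_two_cuts(rng):
    circ = GenomeSequence("c", sim.random_genome(6000, rng).residues, circular=True)
    canonical = covbin.least_rotation(circ.residues)
    for cut in (977, 4203):
        lin = covbin.linearize(circ, cut, overlap=500)
        res = covbin.circularize(lin, min_overlap=300)
        assert res.circularized and not res.ambiguous
        assert res.overlap_len == 500
        assert res.genome.residues == canonical


def test_circularize_tolerates_mismatches_in_overlap(rng):
    circ = GenomeSequence("c", sim.random_genome(4000, rng).residues, circular=True)
    lin = covbin.linearize(circ, 100, overlap=400)
    residues = list(lin.residues)
    # corrupt 4 bases inside the duplicated overlap (1%)
    for pos in (-350, -200, -100, -20):
        residues[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[residues[pos]]
    res = covbin.circularize(
        GenomeSequence("c", "".join(residues)), min_overlap=300, max_mismatch_frac=0.02
    )
    assert res.circularized and res.overlap_len == 400


# ---------------------------------------------------------------------------
# Spanning reads


def test_spanning_read_counting_rules():
    over = aln(95, 105)
    short = aln(98, 103)
    assert covbin.spanning_reads([over], junction=100, flank=5) == 1
    assert covbin.spanning_reads([short], junction=100, flank=5) == 0
    assert covbin.spanning_reads([over, short], junction=100, flank=5) == 1


def test_spanning_reads_within_poisson_band(rng):
    """On a circular genome, reads spanning the junction with 2*flank
    overlap follow the analytic coverage expectation."""
    genome = sim.random_genome(30_000, rng, id="circ")
    cfg = sim.StrainSimConfig(backbone_len=30_000, unique_region_len=500,
                              read_len_median=2558, seed=13)
    doubled = covbin.doubled_reference(genome, 28_000)
    _reads, alns, _ = sim.simulate_reads([(doubled, 50.0)], cfg, sequences=False)
    junction = len(genome)  # the wrap point in the doubled representation
    flank = 100
    count = covbin.spanning_reads(alns, junction, flank)
    # expected spanning reads ~ depth * (1 - 2*flank/mean_len)
    mean_len = np.mean([a.target_end - a.target_start for a in alns])
    expect = 50.0 * (mean_len - 2 * flank) / mean_len
    sd = np.sqrt(expect)
    assert abs(count - expect) < 5 * sd
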