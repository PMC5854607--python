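"""Truth-table evaluation studies.

End-to-end parameter-recovery experiments that run the pipeline over
the synthetic community and measure how well each stage recovers the
planted structure.  These are the package's own benchmarks: every
number they return is recomputed from scratch at call time.
"""

from __future__ import annotations

import numpy as np

from . import covbin, genomecmp, methylome, simulate as sim
from .model import GenomeSequence, IUPACMotif


def binning_recovery(
    seed: int,
    backbone_len: int = 300_000,
    dominant_depth: float = 300.0,
    minor_depth: float = 100.0,
    n_unique_regions: int = 4,
    unique_region_len: int = 8_000,
) -> dict:
    """Strain-assignment precision/recall for reads truly inside
    strain-unique regions.

    Simulates a two-strain community, projects the truth alignments
    onto the collapsed metagenome reference (shared backbone on the
    dominant chromosome, minor-unique contigs separate), bins reads
    with the relative coverage geometry, and scores reads whose true
    origin interval lies wholly inside a strain-unique region: the
    dominant strain's bin is "high", the minor strain's is "low".
    """
    cfg = sim.StrainSimConfig(
        backbone_len=backbone_len,
        n_unique_regions_per_strain=n_unique_regions,
        unique_region_len=unique_region_len,
        total_depth=dominant_depth + minor_depth,
        abundance_ratio=dominant_depth / minor_depth,
        seed=seed,
    )
    pair = sim.simulate_strain_pair(cfg)
    _reads, truth_alns, truth = sim.simulate_reads(
        [(pair.dominant, dominant_depth), (pair.minor, minor_depth)],
        cfg, pair.truth, sequences=False,
    )
    projected = sim.project_truth_alignments(pair, truth_alns)
    reference = sim.collapse_reference(pair)
    assignments, _profiles = covbin.bin_reads(
        projected,
        {g.id: len(g) for g in reference},
        covbin.default_bin_specs(relative=True),
    )
    bins_by_read = {a.read_id: a.bins for a in assignments}

    truth_by_read = {a.read_id: a for a in truth_alns}
    inside: dict[str, set[str]] = {"dominant": set(), "minor": set()}
    for rid, strain in truth.read_origin.items():
        aln = truth_by_read[rid]
        for s, e in truth.unique_intervals[strain]:
            if s <= aln.target_start and aln.target_end <= e:
                inside[strain].add(rid)
                break

    bin_of = {"dominant": "high", "minor": "low"}
    scores = {}
    evaluated = inside["dominant"] | inside["minor"]
    for strain, rids in inside.items():
        predicted = {
            rid for rid in evaluated if bin_of[strain] in bins_by_read.get(rid, ())
        }
        tp = len(predicted & rids)
        scores[strain] = {
            "n_reads": len(rids),
            "precision": tp / len(predicted) if predicted else 0.0,
            "recall": tp / len(rids) if rids else 0.0,
        }
    return {
        "dominant": scores["dominant"],
        "minor": scores["minor"],
        "precision": min(s["precision"] for s in scores.values()),
        "recall": min(s["recall"] for s in scores.values()),
        "n_evaluated": len(evaluated),
    }


def methylome_recovery(
    seed: int,
    genome_len: int = 100_000,
    per_strand_depth: float = 200.0,
    gatc_fraction: float = 0.99,
    ggncc_fraction: float = 0.60,
) -> dict:
    """Motif recovery on planted GATC 6mA and GGNCC 4mC methylation.

    Returns the discovered motif set, the estimated methylated fraction
    per planted motif, and the motif count on an unmethylated control
    genome of the same length.
    """
    rng = np.random.default_rng(seed)
    genome = sim.random_genome(genome_len, rng, id="chr")
    gatc = IUPACMotif("GATC", 1, "6mA")
    ggncc = IUPACMotif("GGNCC", 3, "4mC")
    table, _truth = sim.simulate_kinetics(
        genome, [(gatc, gatc_fraction), (ggncc, ggncc_fraction)],
        per_strand_depth, seed=seed,
    )
    scored = methylome.score_sites(table)
    called = methylome.call_sites(scored)
    motifs = methylome.discover_motifs(genome, called)
    rows = {
        r.motif: r
        for r in methylome.motif_summary(
            genome, motifs, called, scored, count_per_strand=True
        )
    }

    control = sim.random_genome(genome_len, rng, id="ctrl")
    ctrl_table, _ = sim.simulate_kinetics(control, [], per_strand_depth, seed=seed + 1)
    ctrl_called = methylome.call_sites(methylome.score_sites(ctrl_table))
    ctrl_motifs = methylome.discover_motifs(control, ctrl_called)

    return {
        "motifs": sorted(m.pattern for m in motifs),
        "n_motifs": len(motifs),
        "gatc_recovered": gatc in rows,
        "ggncc_recovered": ggncc in rows,
        "gatc_frac_methylated": rows[gatc].frac_methylated if gatc in rows else None,
        "ggncc_frac_methylated": rows[ggncc].frac_methylated if ggncc in rows else None,
        "n_called_sites": len(called),
        "control_n_motifs": len(ctrl_motifs),
        "control_n_called": len(ctrl_called),
    }


def ani_calibration(seed: int, genome_len: int = 60_000, sub_rate: float = 0.01) -> dict:
    """Self-ANI (must be exactly 100) and ANI after i.i.d. substitutions."""
    rng = np.random.default_rng(seed)
    genome = sim.random_genome(genome_len, rng, id="A")
    arr = np.frombuffer(genome.residues.encode(), np.uint8).copy()
    bases = np.frombuffer(b"ACGT", np.uint8)
    lut = np.zeros(256, np.int64)
    lut[bases] = np.arange(4)
    hit = rng.random(len(arr)) < sub_rate
    arr[hit] = bases[(lut[arr[hit]] + rng.integers(1, 4, int(hit.sum()))) % 4]
    mutated = GenomeSequence("B", arr.tobytes().decode())
    self_ani = genomecmp.orthoani(genome, genome)
    pair_ani = genomecmp.orthoani(genome, mutated)
    return {
        "self_ani": self_ani.ani,
        "mutated_ani": pair_ani.ani,
        "n_fragment_pairs": pair_ani.n_fragment_pairs,
        "sub_rate": sub_rate,
    }


def circularization_recovery(
    seed: int, genome_len: int = 20_000, overlap: int = 500, cuts: tuple[int, int] = (977, 13_250)
) -> dict:
    """Recover one circular genome from two different linearizations."""
    rng = np.random.default_rng(seed)
    circ = sim.random_genome(genome_len, rng, id="chr")
    circ.circular = True
    canonical = covbin.least_rotation(circ.residues)
    results = []
    for cut in cuts:
        lin = covbin.linearize(circ, cut, overlap)
        results.append(covbin.circularize(lin, min_overlap=overlap // 2))
    identical = (
        all(r.circularized and not r.ambiguous for r in results)
        and len({r.genome.residues for r in results}) == 1
        and results[0].genome.residues == canonical
    )
    return {
        "identical_canonical_form": identical,
        "overlap_recovered": [r.overlap_len for r in results],
        "planted_overlap": overlap,
    }


def spanning_read_check(
    seed: int, genome_len: int = 50_000, depth: float = 50.0, flank: int = 100
) -> dict:
    """Junction-spanning read count on a doubled circular reference vs
    the analytic coverage expectation."""
    rng = np.random.default_rng(seed)
    genome = sim.random_genome(genome_len, rng, id="circ")
    cfg = sim.StrainSimConfig(
        backbone_len=genome_len, unique_region_len=500, seed=seed
    )
    doubled = covbin.doubled_reference(genome, 28_000)
    _reads, alns, _ = sim.simulate_reads([(doubled, depth)], cfg, sequences=False)
    count = covbin.spanning_reads(alns, junction=genome_len, flank=flank)
    mean_len = float(np.mean([a.target_end - a.target_start for a in alns]))
    expected = depth * (mean_len - 2 * flank) / mean_len
    return {"spanning_reads": count, "expected": expected}
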