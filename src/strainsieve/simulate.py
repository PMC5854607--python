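"""Synthetic two-strain long-read community with ground truth.

Emulates the statistical structure the downstream analysis assumes: two
near-identical strain genomes sharing a conserved backbone with
strain-unique insertions and rearrangements; long reads at unequal
strain abundance with a log-normal length model (median 2,558 bp,
admitted range 500 bp - 27 kb) and uniform substitution/indel errors;
and per-site polymerase-kinetics summaries with planted methylation
motifs on the log-IPD scale, so the downstream t-test is exactly
calibrated.

Every generator is deterministic per seed.  ``TruthTables`` record read
origins, strain-unique intervals, rearrangements and planted methylated
sites — the acceptance oracle for every stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    AlignmentRecord,
    GenomeSequence,
    IUPACMotif,
    ReadRecord,
    TruthTables,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT_STRAND_BASE = str.maketrans("ACGT", "TGCA")


class SimulationError(RuntimeError):
    """Raised when a requested structure cannot be placed."""


@dataclass(slots=True)
class StrainSimConfig:
    """Two-strain community parameters.

    Depths are per-strain mean sequencing depths; ``abundance_ratio`` is
    dominant:minor and must exceed 1.  Read lengths follow a log-normal
    with the given median and shape ``read_len_sigma``, clipped above at
    ``read_len_max``; reads shorter than ``read_len_min`` are discarded
    before output (the admission rule of the study design).
    """

    backbone_len: int = 300_000
    n_unique_regions_per_strain: int = 6
    unique_region_len: int = 2_000
    n_inversions: int = 2
    n_relocations: int = 2
    substitution_rate_backbone: float = 0.001
    abundance_ratio: float = 3.0
    total_depth: float = 400.0
    read_len_median: int = 2_558
    read_len_min: int = 500
    read_len_max: int = 27_000
    read_len_sigma: float = 0.55
    read_error_rate: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone_len <= 10 * self.unique_region_len:
            raise ValueError("backbone_len must exceed 10 x unique_region_len")
        if self.abundance_ratio <= 1:
            raise ValueError("abundance_ratio must be > 1 (dominant:minor)")
        if not self.read_len_min <= self.read_len_median <= self.read_len_max:
            raise ValueError("need read_len_min <= median <= max")


def random_genome(
    length: int,
    rng: np.random.Generator,
    gc: float = 0.41,
    id: str = "genome",
) -> GenomeSequence:
    """I.i.d. random genome at the given GC fraction (default matches a
    typical anammox chromosome, ~41%)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = _BASES[rng.choice(4, size=length, p=p)]
    return GenomeSequence(id=id, residues=arr.tobytes().decode())


# ---------------------------------------------------------------------------
# Strain-pair construction


@dataclass(slots=True)
class _Segment:
    kind: str  # "backbone" | "unique"
    length: int
    b_start: int = -1  # backbone coordinate (backbone segments)
    orient: int = 1
    seq: str = ""
    region_index: int = -1  # unique-region index (unique segments)


class _Builder:
    """Segment-list genome under construction, in current coordinates."""

    def __init__(self, backbone_len: int):
        self.segments: list[_Segment] = [
            _Segment("backbone", backbone_len, b_start=0)
        ]

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def _split(self, pos: int) -> int:
        """Ensure a boundary at ``pos``; return the index following it."""
        off = 0
        for i, seg in enumerate(self.segments):
            if off + seg.length > pos:
                cut = pos - off
                if cut == 0:
                    return i
                left = _Segment(
                    seg.kind, cut, seg.b_start, seg.orient, seg.seq[:cut],
                    seg.region_index,
                )
                right_b = seg.b_start
                if seg.kind == "backbone":
                    if seg.orient == 1:
                        right_b = seg.b_start + cut
                    else:
                        left = _Segment(seg.kind, cut, seg.b_start + seg.length - cut, -1)
                right = _Segment(
                    seg.kind, seg.length - cut, right_b, seg.orient, seg.seq[cut:],
                    seg.region_index,
                )
                self.segments[i : i + 1] = [left, right]
                return i + 1
            off += seg.length
        return len(self.segments)

    def invert(self, start: int, end: int) -> None:
        i, j = self._split(start), self._split(end)
        chunk = self.segments[i:j][::-1]
        for seg in chunk:
            if seg.kind == "backbone":
                seg.orient = -seg.orient
            else:
                seg.seq = revcomp(seg.seq)
        self.segments[i:j] = chunk

    def relocate(self, start: int, end: int, dest: int) -> None:
        if start <= dest < end:
            raise SimulationError("relocation destination inside source")
        i, j = self._split(start), self._split(end)
        chunk = self.segments[i:j]
        del self.segments[i:j]
        dest_adj = dest if dest < start else dest - (end - start)
        k = self._split(dest_adj)
        self.segments[k:k] = chunk

    def insert(self, pos: int, seq: str, region_index: int) -> None:
        i = self._split(pos)
        self.segments[i:i] = [
            _Segment("unique", len(seq), seq=seq, region_index=region_index)
        ]

    def layout(self) -> list[tuple[int, int, _Segment]]:
        out, off = [], 0
        for seg in self.segments:
            out.append((off, off + seg.length, seg))
            off += seg.length
        return out

    def realize(self, backbone: str) -> str:
        parts = []
        for seg in self.segments:
            if seg.kind == "unique":
                parts.append(seg.seq)
            else:
                piece = backbone[seg.b_start : seg.b_start + seg.length]
                parts.append(piece if seg.orient == 1 else revcomp(piece))
        return "".join(parts)


def _place_disjoint(
    rng: np.random.Generator,
    n: int,
    length: int,
    genome_len: int,
    taken: list[tuple[int, int]],
    max_attempts: int = 1000,
) -> list[tuple[int, int]]:
    placed = []
    for _ in range(n):
        for attempt in range(max_attempts):
            start = int(rng.integers(0, genome_len - length))
            iv = (start, start + length)
            if all(iv[1] <= s or iv[0] >= e for s, e in taken + placed):
                placed.append(iv)
                break
        else:
            raise SimulationError(
                f"could not place a {length} bp region after {max_attempts} attempts"
            )
    return placed


@dataclass(slots=True)
class StrainPair:
    """Simulated strain pair plus truth and the internal layout needed
    to project truth alignments onto a collapsed reference."""

    dominant: GenomeSequence
    minor: GenomeSequence
    truth: TruthTables
    dominant_layout: list = field(repr=False, default_factory=list)
    minor_layout: list = field(repr=False, default_factory=list)

    def __iter__(self):
        return iter((self.dominant, self.minor, self.truth))


def simulate_strain_pair(config: StrainSimConfig) -> StrainPair:
    """Build the dominant and minor strain genomes from one backbone.

    The dominant strain is backbone + its unique insertions; the minor
    strain additionally carries inversions, relocations and backbone
    substitutions, so the backbone->dominant coordinate map stays
    monotone.  Unique-region and rearrangement placements reject
    overlaps (1000 attempts, then :class:`SimulationError`).
    """
    rng = np.random.default_rng(config.seed)
    backbone = random_genome(config.backbone_len, rng, id="backbone").residues
    truth = TruthTables()

    builders = {"dominant": _Builder(config.backbone_len), "minor": _Builder(config.backbone_len)}

    # Rearrangements: minor strain only, disjoint backbone intervals.
    minor = builders["minor"]
    sv_len = max(config.unique_region_len, 1000)
    taken: list[tuple[int, int]] = []
    for kind, count in (("inversion", config.n_inversions), ("relocation", config.n_relocations)):
        for iv in _place_disjoint(rng, count, sv_len, config.backbone_len, taken):
            taken.append(iv)
            if kind == "inversion":
                minor.invert(*iv)
                truth.sv_list.append({"type": "inversion", "start": iv[0], "end": iv[1]})
            else:
                for _ in range(1000):
                    dest = int(rng.integers(0, minor.length))
                    if not iv[0] <= dest < iv[1]:
                        break
                minor.relocate(iv[0], iv[1], dest)
                truth.sv_list.append(
                    {"type": "relocation", "start": iv[0], "end": iv[1], "dest": dest}
                )

    # Strain-unique insertions.
    for strain in ("dominant", "minor"):
        b = builders[strain]
        positions = sorted(
            int(rng.integers(0, b.length))
            for _ in range(config.n_unique_regions_per_strain)
        )
        for idx, pos in enumerate(reversed(positions)):
            region = random_genome(config.unique_region_len, rng).residues
            b.insert(pos, region, config.n_unique_regions_per_strain - 1 - idx)

    genomes = {}
    for strain in ("dominant", "minor"):
        seq = builders[strain].realize(backbone)
        if strain == "minor" and config.substitution_rate_backbone > 0:
            seq = _substitute(seq, builders[strain], config.substitution_rate_backbone, rng)
        genomes[strain] = GenomeSequence(id=strain, residues=seq)
        truth.unique_intervals[strain] = [
            (s, e)
            for s, e, seg in builders[strain].layout()
            if seg.kind == "unique"
        ]

    return StrainPair(
        dominant=genomes["dominant"],
        minor=genomes["minor"],
        truth=truth,
        dominant_layout=builders["dominant"].layout(),
        minor_layout=builders["minor"].layout(),
    )


def _substitute(
    seq: str, builder: _Builder, rate: float, rng: np.random.Generator
) -> str:
    """I.i.d. substitutions over the backbone-derived portions only."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    backbone_mask = np.zeros(len(arr), dtype=bool)
    for s, e, seg in builder.layout():
        if seg.kind == "backbone":
            backbone_mask[s:e] = True
    hit = backbone_mask & (rng.random(len(arr)) < rate)
    idx = np.flatnonzero(hit)
    lut = {65: 0, 67: 1, 71: 2, 84: 3}
    orig = np.vectorize(lut.get)(arr[idx]) if len(idx) else np.array([], dtype=int)
    arr[idx] = _BASES[(orig + rng.integers(1, 4, size=len(idx))) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Read simulation


def _draw_lengths(
    rng: np.random.Generator, n: int, config: StrainSimConfig
) -> np.ndarray:
    raw = rng.lognormal(mean=math.log(config.read_len_median), sigma=config.read_len_sigma, size=n)
    return np.minimum(raw, config.read_len_max).astype(np.int64)


def _mutate(
    template: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int, int, int]:
    """Uniform substitutions (rate/2) and insertions/deletions (rate/4
    each); returns (read array, n_sub, n_ins, n_del)."""
    n = len(template)
    u = rng.random(n)
    sub = u < rate / 2
    dele = (u >= rate / 2) & (u < 0.75 * rate)
    ins = (u >= 0.75 * rate) & (u < rate)
    out = template.copy()
    idx = np.flatnonzero(sub)
    if len(idx):
        lut = np.zeros(256, dtype=np.int64)
        lut[_BASES] = np.arange(4)
        out[idx] = _BASES[(lut[out[idx]] + rng.integers(1, 4, size=len(idx))) % 4]
    keep = ~dele
    pieces = out[keep]
    # map insertion positions onto the post-deletion array
    ins_pos = np.flatnonzero(ins)
    ins_pos_kept = np.searchsorted(np.flatnonzero(keep), ins_pos, side="left")
    ins_bases = _BASES[rng.integers(0, 4, size=len(ins_pos_kept))]
    read = np.insert(pieces, np.clip(ins_pos_kept, 0, len(pieces)), ins_bases)
    return read, int(sub.sum()), int(ins.sum()), int(dele.sum())


def simulate_reads(
    strains: Sequence[tuple[GenomeSequence, float]],
    config: StrainSimConfig,
    truth: TruthTables | None = None,
    sequences: bool = True,
) -> tuple[list[ReadRecord], list[AlignmentRecord], TruthTables]:
    """Simulate long reads from each (genome, depth) at the configured
    length and error model.

    Each read carries a truth alignment against its origin genome
    (identity = 1 - realized error fraction).  With ``sequences=False``
    residues are not realized (coverage-only studies); error counts are
    still drawn so truth identities keep their distribution.
    """
    if any(depth <= 0 for _, depth in strains):
        raise ValueError("requested depth must be > 0")
    rng = np.random.default_rng(config.seed + 1)
    truth = truth if truth is not None else TruthTables()
    reads: list[ReadRecord] = []
    alignments: list[AlignmentRecord] = []
    for genome, depth in strains:
        garr = np.frombuffer(genome.residues.encode(), dtype=np.uint8)
        L = len(genome)
        target_bases = depth * L
        # over-draw, trim to the depth budget
        n_guess = int(target_bases / config.read_len_median * 1.6) + 10
        lengths = _draw_lengths(rng, n_guess, config)
        cum = np.cumsum(lengths)
        n_reads = int(np.searchsorted(cum, target_bases)) + 1
        lengths = np.minimum(lengths[:n_reads], L)
        starts = rng.integers(0, L - lengths + 1)
        strand_flags = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            tlen = int(lengths[i])
            start = int(starts[i])
            template = garr[start : start + tlen]
            strand = "-" if strand_flags[i] else "+"
            if sequences:
                if strand == "-":
                    template = _revcomp_arr(template)
                read_arr, n_sub, n_ins, n_del = _mutate(
                    template, config.read_error_rate, rng
                )
                residues = read_arr.tobytes().decode()
            else:
                r = config.read_error_rate
                n_sub = int(rng.binomial(tlen, r / 2))
                n_ins = int(rng.binomial(tlen, r / 4))
                n_del = int(rng.binomial(tlen, r / 4))
                residues = None
            read_len = tlen + n_ins - n_del
            if read_len < config.read_len_min:
                continue
            rid = f"rd_{genome.id}_{len(reads)}"
            matches = tlen - n_sub - n_del
            block_len = tlen + n_ins
            alignments.append(
                AlignmentRecord(
                    read_id=rid,
                    read_len=read_len,
                    read_start=0,
                    read_end=read_len,
                    strand=strand,
                    target_id=genome.id,
                    target_len=L,
                    target_start=start,
                    target_end=start + tlen,
                    matches=matches,
                    block_len=block_len,
                    mapq=60,
                )
            )
            reads.append(
                ReadRecord(
                    id=rid,
                    residues=residues if residues is not None else "N",
                    predicted_accuracy=matches / block_len,
                )
            )
            truth.read_origin[rid] = genome.id
    return reads, alignments, truth


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    comp = np.zeros(256, dtype=np.uint8)
    comp[ord("A")], comp[ord("C")] = ord("T"), ord("G")
    comp[ord("G")], comp[ord("T")] = ord("C"), ord("A")
    comp[ord("N")] = ord("N")
    return comp[arr[::-1]]


# ---------------------------------------------------------------------------
# Collapsed metagenome reference + truth-alignment projection


def collapse_reference(pair: StrainPair) -> list[GenomeSequence]:
    """The metagenome as the assembler would collapse it: the dominant
    chromosome (carrying the shared backbone) plus one contig per
    minor-unique region."""
    contigs = [pair.dominant]
    for s, e, seg in pair.minor_layout:
        if seg.kind == "unique":
            contigs.append(
                GenomeSequence(
                    id=f"minor_unique_{seg.region_index}",
                    residues=pair.minor.residues[s:e],
                )
            )
    return contigs


def project_truth_alignments(
    pair: StrainPair,
    alignments: Sequence[AlignmentRecord],
    min_piece: int = 200,
) -> list[AlignmentRecord]:
    """Project per-strain truth alignments onto the collapsed reference.

    Dominant-strain alignments pass through unchanged.  A minor-strain
    alignment is clipped to its largest piece lying within a single
    minor segment: unique pieces go to that region's contig, backbone
    pieces are lifted through backbone coordinates onto the dominant
    chromosome.  Pieces shorter than ``min_piece`` are dropped
    (unmappable read).
    """
    dom_len = len(pair.dominant)
    # backbone coordinate -> dominant coordinate, monotone segment list
    b2d = [
        (seg.b_start, seg.b_start + seg.length, s)
        for s, e, seg in pair.dominant_layout
        if seg.kind == "backbone"
    ]
    unique_contig_len = {
        seg.region_index: seg.length
        for _, _, seg in pair.minor_layout
        if seg.kind == "unique"
    }
    out = []
    for aln in alignments:
        if aln.target_id == pair.dominant.id:
            out.append(aln)
            continue
        best = None  # (piece_len, new_target, new_start, new_end, flip)
        for s, e, seg in pair.minor_layout:
            lo, hi = max(aln.target_start, s), min(aln.target_end, e)
            if hi - lo < max(min_piece, 1):
                continue
            if seg.kind == "unique":
                cand = (hi - lo, f"minor_unique_{seg.region_index}",
                        lo - s, hi - s, False, seg.region_index)
            else:
                if seg.orient == 1:
                    b_lo = seg.b_start + (lo - s)
                    b_hi = seg.b_start + (hi - s)
                else:
                    b_lo = seg.b_start + (e - hi)
                    b_hi = seg.b_start + (e - lo)
                hit = None
                for bs, be, ds in b2d:
                    if bs <= b_lo and b_hi <= be:
                        hit = (ds + (b_lo - bs), ds + (b_hi - bs))
                        break
                if hit is None:
                    continue
                cand = (hi - lo, pair.dominant.id, hit[0], hit[1],
                        seg.orient == -1, -1)
            if best is None or cand[0] > best[0]:
                best = cand
        if best is None:
            continue
        piece_len, target, t_start, t_end, flip, region = best
        frac = piece_len / (aln.target_end - aln.target_start)
        matches = max(1, int(round(aln.matches * frac)))
        block = max(matches, int(round(aln.block_len * frac)))
        tlen = dom_len if target == pair.dominant.id else unique_contig_len[region]
        strand = aln.strand if not flip else ("-" if aln.strand == "+" else "+")
        out.append(
            AlignmentRecord(
                read_id=aln.read_id,
                read_len=aln.read_len,
                read_start=0,
                read_end=min(piece_len, aln.read_len),
                strand=strand,
                target_id=target,
                target_len=tlen,
                target_start=t_start,
                target_end=t_end,
                matches=min(matches, block),
                block_len=block,
                mapq=aln.mapq,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Kinetics simulation


@dataclass(slots=True)
class KineticsModel:
    """Log-IPD signal model: unmethylated sites draw their sample mean
    around ``baseline``; methylated sites are shifted by ``delta``.
    ``sigma`` is the per-observation SD, so the Welch t-test downstream
    is exactly calibrated."""

    baseline: float = 0.0
    sigma: float = 0.5
    delta: float = 1.0
    ctrl_n: int = 500


def planted_motif_sites(
    genome: GenomeSequence,
    motif: IUPACMotif,
) -> list[tuple[int, str]]:
    """All (position, strand) of the motif's methylated base, per strand."""
    from .methylome import count_motif_occurrences

    return [
        (pos, strand)
        for pos, strand in count_motif_occurrences(genome, motif, count_per_strand=True)
    ]


def simulate_kinetics(
    genome: GenomeSequence,
    planted: Sequence[tuple[IUPACMotif, float]],
    per_strand_depth: float,
    model: KineticsModel | None = None,
    seed: int = 0,
    truth: TruthTables | None = None,
) -> tuple[pd.DataFrame, TruthTables]:
    """Per-site kinetics table: exactly one row per (position, strand).

    For each planted (motif, methylated_fraction), every genomic
    occurrence of the motif is methylated independently with that
    probability; methylated sites get a +delta shift of the observed
    log-IPD mean.  obs_n is Poisson(per_strand_depth) (min 2); sample
    SDs follow the exact chi distribution so t statistics are honest.
    """
    model = model or KineticsModel()
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else TruthTables()
    L = len(genome)
    fwd = genome.residues
    rev_bases = fwd.translate(_COMPLEMENT_STRAND_BASE)

    meth_mask = {"+": np.zeros(L, dtype=bool), "-": np.zeros(L, dtype=bool)}
    for motif, fraction in planted:
        for pos, strand in planted_motif_sites(genome, motif):
            if rng.random() < fraction:
                meth_mask[strand][pos] = True
                truth.methylated_sites.append(
                    (pos, strand, motif.pattern, motif.mod_type)
                )

    frames = []
    for strand, bases in (("+", fwd), ("-", rev_bases)):
        meth = meth_mask[strand]
        obs_n = np.maximum(rng.poisson(per_strand_depth, size=L), 2)
        obs_sd = model.sigma * np.sqrt(rng.chisquare(obs_n - 1) / (obs_n - 1))
        ctrl_sd = model.sigma * np.sqrt(
            rng.chisquare(model.ctrl_n - 1, size=L) / (model.ctrl_n - 1)
        )
        mu = model.baseline + model.delta * meth
        obs_mean = rng.normal(mu, model.sigma / np.sqrt(obs_n))
        ctrl_mean = rng.normal(model.baseline, model.sigma / math.sqrt(model.ctrl_n), size=L)
        frames.append(
            pd.DataFrame(
                {
                    "target_id": genome.id,
                    "position": np.arange(L),
                    "strand": strand,
                    "base": list(bases),
                    "obs_mean": obs_mean,
                    "obs_sd": obs_sd,
                    "obs_n": obs_n,
                    "ctrl_mean": ctrl_mean,
                    "ctrl_sd": ctrl_sd,
                    "ctrl_n": model.ctrl_n,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table, truth


def write_kinetics(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_kinetics(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
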