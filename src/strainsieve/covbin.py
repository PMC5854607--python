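"""Coverage-based strain separation and genome finishing.

The strain-deconvolution core: per-base depth from single-best read
alignments, routing of reads into named coverage bins, bin refinement,
depth-based contig selection, low-coverage region detection,
terminal-overlap circularization and junction-spanning read counting.

The default bin geometry follows the two-strain study design: reads over
deeply covered regions (>110x) assemble the dominant strain; reads over
low (25-120x) or very highly covered (>225x) regions assemble the minor
strain, the very-high class appearing in *both* bins so that the shared
backbone supports both assemblies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import AlignmentRecord, GenomeSequence, revcomp

#: Nominal backbone depth used to express the absolute cutoffs
#: (110 / 25-120 / 225) as fractions of the observed genome-wide median
#: depth M in relative mode.  The geometry must place the minor strain
#: inside the scaled 25-120 window, the dominant strain between the
#: scaled 120 and 225 cutoffs, and the shared backbone above the scaled
#: 225, for dominant:minor mixtures from ~1.75:1 up to 3:1.  At the
#: 3:1 extreme the dominant strain sits at 0.75M; the anchor places the
#: scaled 225 cutoff at the three-quarter point between 0.75M and M
#: (225/240 = 0.9375) because the two failure modes are not symmetric:
#: long-read coverage noise is autocorrelated over whole footprints, and
#: a dominant-strain read leaking above the cutoff corrupts the minor
#: strain's bin, whereas a backbone read dropping below it merely thins
#: the shared coverage that the high bin already supplies.
RELATIVE_ANCHOR_DEPTH = 240.0


@dataclass(slots=True)
class DepthProfile:
    """Per-base alignment depth over one target sequence."""

    target_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass(frozen=True, slots=True)
class DepthInterval:
    """One depth interval with explicit boundary semantics."""

    lo: float
    hi: float = math.inf
    lo_open: bool = False
    hi_open: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"empty depth interval [{self.lo},{self.hi}]")

    def contains(self, x: float) -> bool:
        above = x > self.lo if self.lo_open else x >= self.lo
        below = x < self.hi if self.hi_open else x <= self.hi
        return above and below

    def scaled(self, factor: float) -> "DepthInterval":
        return replace(
            self,
            lo=self.lo * factor,
            hi=self.hi * factor if math.isfinite(self.hi) else math.inf,
        )


@dataclass(frozen=True, slots=True)
class CoverageBinSpec:
    """A named union of depth intervals.

    With ``relative=True`` the interval bounds are fractions of the
    genome-wide median depth and are rescaled at assignment time, so a
    reduced-depth synthetic run reuses the full-depth geometry.
    """

    name: str
    intervals: tuple[DepthInterval, ...]
    relative: bool = False

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"bin {self.name!r}: no intervals")

    def contains(self, x: float) -> bool:
        return any(iv.contains(x) for iv in self.intervals)

    def resolved(self, median_depth: float) -> "CoverageBinSpec":
        if not self.relative:
            return self
        return replace(
            self,
            intervals=tuple(iv.scaled(median_depth) for iv in self.intervals),
            relative=False,
        )


def default_bin_specs(relative: bool = False) -> list[CoverageBinSpec]:
    """The two-strain bin geometry: high = (110, inf); low = [25, 120] u (225, inf).

    ">" cutoffs are strict; the 25-120 window is inclusive on both ends,
    so stats in (110, 120] join both bins, as does everything above 225.
    In relative mode the bounds are divided by ``RELATIVE_ANCHOR_DEPTH``
    and later multiplied by the observed genome-wide median depth.
    """
    scale = 1.0 / RELATIVE_ANCHOR_DEPTH if relative else 1.0
    high = CoverageBinSpec(
        "high",
        (DepthInterval(110 * scale, lo_open=True),),
        relative=relative,
    )
    low = CoverageBinSpec(
        "low",
        (
            DepthInterval(25 * scale, 120 * scale),
            DepthInterval(225 * scale, lo_open=True),
        ),
        relative=relative,
    )
    return [high, low]


@dataclass(slots=True)
class BinAssignment:
    """One read's footprint depth summary and the bins it entered."""

    read_id: str
    footprint_stat: float
    bins: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Depth


def compute_depth(
    alignments: Iterable[AlignmentRecord],
    target_len: int,
    target_id: str = "",
) -> DepthProfile:
    """Per-base depth d(i) = number of alignment footprints containing i.

    Difference-array accumulation; errors on footprints outside the
    target bounds.
    """
    diff = np.zeros(target_len + 1, dtype=np.int64)
    for aln in alignments:
        if aln.target_end > target_len:
            raise ValueError(
                f"alignment {aln.read_id!r} exceeds target bounds "
                f"({aln.target_end} > {target_len})"
            )
        if target_id and aln.target_id != target_id:
            raise ValueError(
                f"alignment {aln.read_id!r} is on {aln.target_id!r}, not {target_id!r}"
            )
        diff[aln.target_start] += 1
        diff[aln.target_end] -= 1
    return DepthProfile(target_id=target_id, depth=np.cumsum(diff[:-1]))


def footprint_stat(
    alignment: AlignmentRecord,
    profile: DepthProfile,
    statistic: str = "median",
) -> float:
    """Summary depth over the alignment's target footprint."""
    window = profile.depth[alignment.target_start : alignment.target_end]
    if statistic == "median":
        return float(np.median(window))
    if statistic == "mean":
        return float(np.mean(window))
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# Binning


def assign_bins(
    alignments: Sequence[AlignmentRecord],
    profiles: DepthProfile | Mapping[str, DepthProfile],
    bin_specs: Sequence[CoverageBinSpec],
    statistic: str = "median",
) -> list[BinAssignment]:
    """Route each read into every bin whose depth intervals contain its
    footprint statistic.  A read may enter 0, 1 or several bins.

    ``profiles`` may be a single DepthProfile or a mapping target_id ->
    profile for multi-target references (processed per target and
    aggregated).  Relative bin specs are resolved against the median
    depth pooled over all profiles.
    """
    if isinstance(profiles, DepthProfile):
        profile_map = {profiles.target_id: profiles}
        single = profiles
    else:
        profile_map = dict(profiles)
        single = None
    if any(spec.relative for spec in bin_specs):
        pooled = np.concatenate([p.depth for p in profile_map.values()])
        median_depth = float(np.median(pooled))
        bin_specs = [spec.resolved(median_depth) for spec in bin_specs]
    out = []
    for aln in alignments:
        prof = single if single is not None else profile_map[aln.target_id]
        stat = footprint_stat(aln, prof, statistic)
        out.append(
            BinAssignment(
                read_id=aln.read_id,
                footprint_stat=stat,
                bins=frozenset(s.name for s in bin_specs if s.contains(stat)),
            )
        )
    return out


def bin_reads(
    alignments: Sequence[AlignmentRecord],
    target_lens: Mapping[str, int],
    bin_specs: Sequence[CoverageBinSpec],
    statistic: str = "median",
) -> tuple[list[BinAssignment], dict[str, DepthProfile]]:
    """Convenience wrapper: depth per target, then bin assignment."""
    by_target: dict[str, list[AlignmentRecord]] = {t: [] for t in target_lens}
    for aln in alignments:
        by_target[aln.target_id].append(aln)
    profiles = {
        t: compute_depth(alns, target_lens[t], t) for t, alns in by_target.items()
    }
    return assign_bins(alignments, profiles, bin_specs, statistic), profiles


def refine_bin(
    assignments: Sequence[BinAssignment],
    min_depth: float = 100,
) -> tuple[list[BinAssignment], list[BinAssignment]]:
    """Split assignments into (kept, excluded) around a depth floor.

    Excluded reads are those whose footprint statistic on the bin's own
    assembly fell below ``min_depth``; kept and excluded partition the
    input.
    """
    kept = [a for a in assignments if a.footprint_stat >= min_depth]
    excluded = [a for a in assignments if a.footprint_stat < min_depth]
    return kept, excluded


def select_contigs_by_depth(
    contig_mean_depths: Mapping[str, float],
    threshold: float = 190,
) -> set[str]:
    """Contigs with mean depth strictly greater than the threshold."""
    return {c for c, d in contig_mean_depths.items() if d > threshold}


def low_coverage_regions(
    profile: DepthProfile,
    threshold: float = 25,
    min_len: int = 50,
    max_len: int | None = None,
) -> list[tuple[int, int]]:
    """Maximal runs of positions with depth < threshold, length-filtered."""
    below = profile.depth < threshold
    if not below.any():
        return []
    padded = np.concatenate(([False], below, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    hi = math.inf if max_len is None else max_len
    return [
        (int(s), int(e))
        for s, e in zip(starts, ends)
        if min_len <= e - s <= hi
    ]


# ---------------------------------------------------------------------------
# Circularization


@dataclass(slots=True)
class CircularizationResult:
    genome: GenomeSequence | None
    overlap_len: int
    circularized: bool
    ambiguous: bool


def least_rotation(s: str) -> str:
    """Lexicographically smallest rotation (Booth's algorithm)."""
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + len(s)]


def circularize(
    seq: GenomeSequence,
    min_overlap: int,
    max_mismatch_frac: float = 0.0,
    max_overlap: int | None = None,
) -> CircularizationResult:
    """Detect and trim a duplicated terminal overlap.

    Scans overlap lengths in [min_overlap, max_overlap]; an overlap
    qualifies when the suffix/prefix mismatch fraction is at most
    ``max_mismatch_frac``.  The longest qualifying overlap wins; if any
    other qualifying length ties its mismatch fraction the result is
    flagged ambiguous (no silent choice).  The circular output is
    canonicalized to its lexicographically smallest rotation.
    """
    if seq.circular:
        raise ValueError(f"{seq.id!r} is already circular")
    n = len(seq)
    cap = min(max_overlap if max_overlap is not None else n // 2, n - 1)
    arr = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
    qualifying: list[tuple[int, float]] = []
    for ov in range(min_overlap, cap + 1):
        mismatches = int((arr[:ov] != arr[n - ov :]).sum())
        frac = mismatches / ov
        if frac <= max_mismatch_frac:
            qualifying.append((ov, frac))
    if not qualifying:
        return CircularizationResult(None, 0, False, False)
    best_ov, best_frac = max(qualifying)
    ambiguous = sum(1 for _, frac in qualifying if frac == best_frac) > 1
    trimmed = seq.residues[: n - best_ov]
    canonical = least_rotation(trimmed)
    return CircularizationResult(
        GenomeSequence(id=seq.id, residues=canonical, circular=True),
        best_ov,
        True,
        ambiguous,
    )


def linearize(
    genome: GenomeSequence,
    cut: int,
    overlap: int,
    new_id: str | None = None,
) -> GenomeSequence:
    """Cut a circular genome at ``cut`` and re-duplicate ``overlap``
    leading bases at the end — the inverse of :func:`circularize`."""
    if not genome.circular:
        raise ValueError("linearize expects a circular genome")
    rotated = genome.residues[cut:] + genome.residues[:cut]
    return GenomeSequence(
        id=new_id or genome.id,
        residues=rotated + rotated[:overlap],
        circular=False,
    )


def doubled_reference(genome: GenomeSequence, extension: int) -> GenomeSequence:
    """Genome concatenated with its own first ``extension`` bases, so
    alignments crossing the circular junction stay linear."""
    return GenomeSequence(
        id=genome.id + "|doubled",
        residues=genome.residues + genome.residues[:extension],
        circular=False,
    )


def spanning_reads(
    alignments: Iterable[AlignmentRecord],
    junction: int,
    flank: int,
) -> int:
    """Count reads whose single best alignment covers the junction with
    at least ``flank`` bases on each side, contiguously."""
    return sum(
        1
        for a in alignments
        if a.target_start <= junction - flank and a.target_end >= junction + flank
    )
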