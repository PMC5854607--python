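"""Shared domain types for the strain-deconvolution pipeline.

Every coordinate in the package is 0-based, half-open on the forward
strand of its target; 1-based inclusive coordinates exist only at the
GFF3 boundary (see :mod:`strainsieve.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA (or IUPAC-degenerate) string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class GenomeSequence:
    """A named DNA sequence; the unit of all genome-level statistics.

    ``circular=True`` means the sequence is the canonical form of a
    circular chromosome: no duplicated terminal overlap remains and the
    string is the lexicographically smallest rotation.
    """

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if len(self.residues) < 1:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id!r}: non-DNA residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(slots=True)
class ReadRecord:
    """One sequencing read, optionally with per-base qualities."""

    id: str
    residues: str
    quality: list[int] | None = None
    predicted_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if len(self.residues) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.residues):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.residues)}"
            )
        if self.predicted_accuracy is not None and not 0.0 <= self.predicted_accuracy <= 1.0:
            raise ValueError(f"read {self.id!r}: predicted_accuracy outside [0,1]")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(slots=True)
class AlignmentRecord:
    """One read-to-target alignment interval (PAF semantics).

    Coordinates are 0-based half-open on the forward strand of both
    axes.  ``identity`` is matches / block_len.
    """

    read_id: str
    read_len: int
    read_start: int
    read_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int = 255

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"alignment {self.read_id!r}: strand must be + or -")
        for label, start, end, length in (
            ("read", self.read_start, self.read_end, self.read_len),
            ("target", self.target_start, self.target_end, self.target_len),
        ):
            if not (0 <= start < end <= length):
                raise ValueError(
                    f"alignment {self.read_id!r}: bad {label} interval "
                    f"[{start},{end}) on length {length}"
                )
        if self.matches > self.block_len:
            raise ValueError(f"alignment {self.read_id!r}: matches > block_len")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len


@dataclass(slots=True)
class GeneModel:
    """A gene/CDS interval on a contig, 0-based half-open."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id!r}: end <= start")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class KineticsSite:
    """Summary polymerase-kinetics statistics for one (position, strand).

    Means/SDs are on the log-IPD (interpulse duration) scale; ``obs``
    rows summarise the native sample, ``ctrl`` the unmethylated control
    model at the same sequence context.
    """

    target_id: str
    position: int
    strand: str
    base: str
    obs_mean: float
    obs_sd: float
    obs_n: int
    ctrl_mean: float
    ctrl_sd: float
    ctrl_n: int

    def __post_init__(self) -> None:
        if self.obs_sd <= 0 or self.ctrl_sd <= 0:
            raise ValueError(f"kinetics site {self.target_id}:{self.position}: sd <= 0")
        if self.obs_n < 2 or self.ctrl_n < 2:
            raise ValueError(f"kinetics site {self.target_id}:{self.position}: n < 2")


@dataclass(slots=True)
class ModificationCall:
    """A scored per-site base modification call.

    ``qv`` is the Phred-like modification quality value
    -10*log10(one-sided p), capped; only adenines (6mA) and cytosines
    (4mC) receive a typed call.
    """

    target_id: str
    position: int
    strand: str
    base: str
    mod_type: str
    qv: float
    coverage: int

    def __post_init__(self) -> None:
        if self.qv < 0:
            raise ValueError("qv must be >= 0")
        allowed = {"A": {"6mA", "unknown"}, "C": {"4mC", "unknown"}}
        if self.base in allowed:
            if self.mod_type not in allowed[self.base]:
                raise ValueError(f"base {self.base} cannot carry mod_type {self.mod_type}")
        elif self.mod_type != "unknown":
            raise ValueError(f"base {self.base} can only be mod_type 'unknown'")


@dataclass(frozen=True, slots=True)
class IUPACMotif:
    """A methyltransferase recognition motif in IUPAC ambiguity codes."""

    pattern: str
    methyl_index: int
    mod_type: str

    def __post_init__(self) -> None:
        from .methylome import IUPAC_SETS  # local import to avoid a cycle

        if not 0 <= self.methyl_index < len(self.pattern):
            raise ValueError("methyl_index outside pattern")
        if len(self.pattern) > 12:
            raise ValueError("motif longer than 12")
        base = {"6mA": "A", "4mC": "C"}[self.mod_type]
        code = self.pattern[self.methyl_index]
        if base not in IUPAC_SETS[code]:
            raise ValueError(f"pattern[{self.methyl_index}]={code} cannot be {base}")


@dataclass(slots=True)
class MotifSummaryRow:
    """One motif-table row: occurrence, methylation and context statistics."""

    motif: IUPACMotif
    n_detected: int
    n_methylated: int
    frac_methylated: float
    frac_intergenic: float
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.n_methylated > self.n_detected:
            raise ValueError("n_methylated > n_detected")


@dataclass(slots=True)
class PairwiseHit:
    """One 12-column tabular search hit (BLAST outfmt-6 semantics)."""

    query_id: str
    subject_id: str
    identity: float  # percent
    aln_len: int
    query_len: int
    subject_len: int
    bitscore: float
    evalue: float

    @property
    def query_cov(self) -> float:
        """aln_len / query_len; may exceed 1 through gap columns."""
        return self.aln_len / self.query_len


@dataclass(slots=True)
class ANIResult:
    """Fragment-based average nucleotide identity between two genomes."""

    ani: float | None
    n_fragment_pairs: int
    fragment_len: int

    @property
    def defined(self) -> bool:
        return self.ani is not None


@dataclass(slots=True)
class GenePresence:
    """Read-coverage support for one gene: present, partial or absent."""

    gene_id: str
    covered_fraction: float
    status: str


@dataclass(slots=True)
class TruthTables:
    """Simulator ground truth; the acceptance oracle for every stage.

    ``unique_intervals`` are in each strain's own final coordinates;
    ``methylated_sites`` are (position, strand, motif pattern, mod type)
    tuples on the simulated genome.
    """

    read_origin: dict[str, str] = field(default_factory=dict)
    unique_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    sv_list: list[dict] = field(default_factory=list)
    methylated_sites: list[tuple[int, str, str, str]] = field(default_factory=list)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def iter_windows(length: int, window: int) -> Iterator[tuple[int, int, bool]]:
    """Non-overlapping windows from 0; yields (start, end, full)."""
    for start in range(0, length, window):
        end = min(start + window, length)
        yield start, end, end - start == window
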