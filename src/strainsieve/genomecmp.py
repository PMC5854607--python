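"""Comparative genome analysis.

Composition statistics (GC%, GC skew, GC-deviant windows), fragment-
based average nucleotide identity (OrthoANI-style reciprocal best
fragments), exact local alignment for small gene sets, tabular-hit
filtering, best-bidirectional-hit ortholog pairing, unique-gene sets,
aligned fraction at an identity floor, and read-coverage gene
presence/partial/absence classification.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .covbin import compute_depth
from .model import (
    AlignmentRecord,
    ANIResult,
    GeneModel,
    GenePresence,
    GenomeSequence,
    PairwiseHit,
    interval_union_length,
    iter_windows,
    revcomp,
)

# ---------------------------------------------------------------------------
# Composition


@dataclass(slots=True)
class WindowStat:
    start: int
    end: int
    gc_percent: float
    gc_skew: float
    full: bool
    skew_defined: bool


@dataclass(slots=True)
class GenomeStats:
    length: int
    gc_percent: float
    windows: list[WindowStat]


def _base_counts(arr: np.ndarray) -> tuple[int, int, int, int]:
    return (
        int((arr == ord("A")).sum()),
        int((arr == ord("C")).sum()),
        int((arr == ord("G")).sum()),
        int((arr == ord("T")).sum()),
    )


def genome_stats(genome: GenomeSequence, window: int = 1000) -> GenomeStats:
    """Length, GC% and per-window GC%/GC skew.

    GC% = 100*(G+C)/(A+C+G+T), N excluded from the denominator.  Skew =
    (G-C)/(G+C) per window, reported as 0 with ``skew_defined=False``
    when G+C = 0.  Windows are non-overlapping from position 0; a
    partial final window is reported but flagged ``full=False``.
    """
    arr = np.frombuffer(genome.residues.encode(), dtype=np.uint8)
    a, c, g, t = _base_counts(arr)
    denom = a + c + g + t
    gc = 100.0 * (g + c) / denom if denom else 0.0
    windows = []
    for start, end, full in iter_windows(len(genome), window):
        wa, wc, wg, wt = _base_counts(arr[start:end])
        wdenom = wa + wc + wg + wt
        wgc = 100.0 * (wg + wc) / wdenom if wdenom else 0.0
        sdenom = wg + wc
        skew = (wg - wc) / sdenom if sdenom else 0.0
        windows.append(WindowStat(start, end, wgc, skew, full, sdenom > 0))
    return GenomeStats(length=len(genome), gc_percent=gc, windows=windows)


def gc_deviant_windows(
    genome: GenomeSequence,
    window: int = 1000,
    threshold_pp: float = 5.0,
) -> tuple[int, list[tuple[int, int]]]:
    """Full windows whose GC% deviates from the genome-wide GC% by at
    least ``threshold_pp`` percentage points."""
    st = genome_stats(genome, window)
    deviant = [
        (w.start, w.end)
        for w in st.windows
        if w.full and abs(w.gc_percent - st.gc_percent) >= threshold_pp
    ]
    return len(deviant), deviant


# ---------------------------------------------------------------------------
# Exact local alignment (small inputs)


@dataclass(slots=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    matrix: str = "BLOSUM62"  # protein mode


@dataclass(slots=True)
class LocalAlignment:
    score: float
    columns: int
    identity: float  # percent of columns
    query_range: tuple[int, int]
    subject_range: tuple[int, int]


_EXACT_SIZE_CAP = 4_000_000  # product of lengths


def local_align(
    a: str,
    b: str,
    alphabet: str = "dna",
    scoring: AlignScoring | None = None,
    size_cap: int = _EXACT_SIZE_CAP,
) -> LocalAlignment:
    """Optimal affine-gap local alignment of two sequences.

    DNA uses match/mismatch scores, protein a standard substitution
    matrix.  Deterministic tie-breaking among optimal alignments:
    shortest alignment, then leftmost start.  A best score <= 0 is
    reported as the empty alignment (score 0).
    """
    from Bio import Align

    if not a or not b:
        raise ValueError("empty sequence")
    if len(a) * len(b) > size_cap:
        raise ValueError(
            f"input size {len(a)}x{len(b)} exceeds the exact-mode cap; "
            "use the fragment/seeded route (orthoani) for genome-scale input"
        )
    scoring = scoring or AlignScoring()
    aligner = Align.PairwiseAligner(mode="local")
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    if alphabet == "dna":
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    elif alphabet == "protein":
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    score = aligner.score(a, b)
    if score <= 0:
        return LocalAlignment(0.0, 0, 0.0, (0, 0), (0, 0))
    best = None
    for aln in itertools.islice(aligner.align(a, b), 64):
        counts = aln.counts()
        columns = aln.length
        qr = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
        sr = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
        key = (columns, qr[0], sr[0])
        if best is None or key < best[0]:
            best = (key, columns, counts.identities, qr, sr)
    _, columns, identities, qr, sr = best
    return LocalAlignment(
        score=float(score),
        columns=columns,
        identity=100.0 * identities / columns if columns else 0.0,
        query_range=qr,
        subject_range=sr,
    )


def all_vs_all_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    alphabet: str = "protein",
    scoring: AlignScoring | None = None,
    min_score: float = 1.0,
) -> list[PairwiseHit]:
    """Exact-alignment hit table for small synthetic gene sets.

    The e-value is a Karlin-Altschul-style ranking proxy
    (m*n*2^-score); real-proteome searches should come from an external
    engine as a 12-column tabular file instead.
    """
    hits = []
    for qid, qseq in queries.items():
        for sid, sseq in subjects.items():
            aln = local_align(qseq, sseq, alphabet=alphabet, scoring=scoring)
            if aln.score < min_score or aln.columns == 0:
                continue
            hits.append(
                PairwiseHit(
                    query_id=qid,
                    subject_id=sid,
                    identity=aln.identity,
                    aln_len=aln.columns,
                    query_len=len(qseq),
                    subject_len=len(sseq),
                    bitscore=aln.score,
                    evalue=len(qseq) * len(sseq) * 2.0 ** (-aln.score),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Fragment-based ANI


def _cigar_columns(cigar: str) -> int:
    return sum(int(n) for n, _op in re.findall(r"(\d+)([=XIDM])", cigar))


def _best_fragment_hit(
    fragment: str, target: str, target_rc: str, max_dist: int
) -> tuple[float, int] | None:
    """Best infix alignment of fragment on either strand of target:
    (identity fraction, forward-strand midpoint) or None."""
    best = None
    for strand, tseq in (("+", target), ("-", target_rc)):
        res = edlib.align(fragment, tseq, mode="HW", task="path", k=max_dist)
        if res["editDistance"] == -1:
            continue
        loc = res["locations"][0]
        columns = _cigar_columns(res["cigar"])
        identity = 1.0 - res["editDistance"] / columns
        mid = (loc[0] + loc[1]) // 2
        if strand == "-":
            mid = len(target) - 1 - mid
        if best is None or identity > best[0]:
            best = (identity, mid)
    return best


def orthoani(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    fragment_len: int = 1020,
    min_identity: float = 0.70,
    min_cov: float = 0.50,
) -> ANIResult:
    """Fragment-based average nucleotide identity.

    Both genomes are cut into consecutive non-overlapping fragments of
    ``fragment_len`` (short tails discarded).  Each fragment is aligned
    against the full partner genome on both strands; fragment pairs that
    are reciprocal best matches at >= ``min_identity`` over >=
    ``min_cov`` of the fragment are retained, and the ANI is the mean
    retained identity averaged over both directions (symmetric by
    construction).
    """
    def frags(g: GenomeSequence) -> list[str]:
        return [
            g.residues[s : s + fragment_len]
            for s in range(0, len(g) - fragment_len + 1, fragment_len)
        ]

    fa, fb = frags(genome_a), frags(genome_b)
    if not fa or not fb:
        return ANIResult(ani=None, n_fragment_pairs=0, fragment_len=fragment_len)
    # identity >= min_identity bounds edit distance; pad generously for gaps
    max_dist = int(fragment_len * (1 - min_identity) * 1.5)
    a_seq, b_seq = genome_a.residues, genome_b.residues
    a_rc, b_rc = revcomp(a_seq), revcomp(b_seq)

    def direction(frs: list[str], target: str, target_rc: str):
        out = []
        for fr in frs:
            hit = _best_fragment_hit(fr, target, target_rc, max_dist)
            if hit is None or hit[0] < min_identity:
                out.append(None)
            else:
                out.append((hit[0], hit[1] // fragment_len))
            # HW mode aligns the whole fragment, so coverage is complete
            # whenever an alignment within max_dist exists (min_cov holds).
        return out

    ab = direction(fa, b_seq, b_rc)
    ba = direction(fb, a_seq, a_rc)
    identities = []
    n_pairs = 0
    for i, hit in enumerate(ab):
        if hit is None:
            continue
        j = min(hit[1], len(fb) - 1)
        back = ba[j]
        if back is not None and min(back[1], len(fa) - 1) == i:
            identities.append((hit[0] + back[0]) / 2)
            n_pairs += 1
    if not identities:
        return ANIResult(ani=None, n_fragment_pairs=0, fragment_len=fragment_len)
    return ANIResult(
        ani=100.0 * float(np.mean(identities)),
        n_fragment_pairs=n_pairs,
        fragment_len=fragment_len,
    )


# ---------------------------------------------------------------------------
# Hit filtering, BBH, unique genes


def filter_hits(
    hits: Iterable[PairwiseHit],
    min_identity: float = 90.0,
    qcov_low: float = 0.75,
    qcov_high: float = 1.20,
) -> list[PairwiseHit]:
    """Keep hits at identity >= min_identity with query coverage
    strictly inside (qcov_low, qcov_high); coverage of exactly 75% or
    120% of the query is excluded."""
    if not qcov_low < qcov_high:
        raise ValueError("qcov_low must be < qcov_high")
    return [
        h
        for h in hits
        if h.identity >= min_identity and qcov_low < h.query_cov < qcov_high
    ]


def _best_subject(hits: Iterable[PairwiseHit]) -> dict[str, str]:
    """Per query: subject with max bitscore, ties by min evalue then
    lexicographic subject id."""
    best: dict[str, tuple[float, float, str]] = {}
    for h in hits:
        key = (-h.bitscore, h.evalue, h.subject_id)
        if h.query_id not in best or key < best[h.query_id]:
            best[h.query_id] = key
    return {q: key[2] for q, key in best.items()}


def best_bidirectional_hits(
    hits_ab: Iterable[PairwiseHit],
    hits_ba: Iterable[PairwiseHit],
    min_identity: float = 90.0,
    filter_first: bool = True,
) -> list[tuple[str, str]]:
    """Ordered (a, b) pairs where b is a's best subject and a is b's,
    both at identity >= min_identity.

    With ``filter_first`` (default) the identity floor is applied before
    choosing the best subject; disable to pick the best first and
    discard sub-threshold pairs afterwards.
    """
    ab = list(hits_ab)
    ba = list(hits_ba)
    if filter_first:
        ab = [h for h in ab if h.identity >= min_identity]
        ba = [h for h in ba if h.identity >= min_identity]
    best_ab = _best_subject(ab)
    best_ba = _best_subject(ba)
    pairs = [
        (a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    if not filter_first:
        ident = {}
        for h in ab + ba:
            ident[(h.query_id, h.subject_id)] = h.identity
        pairs = [
            (a, b)
            for a, b in pairs
            if ident.get((a, b), 0) >= min_identity
            and ident.get((b, a), 0) >= min_identity
        ]
    return sorted(pairs)


def unique_genes(
    genes: Iterable[str], filtered_hits: Iterable[PairwiseHit]
) -> set[str]:
    """Genes with no surviving hit after filtering."""
    with_hits = {h.query_id for h in filtered_hits}
    return set(genes) - with_hits


# ---------------------------------------------------------------------------
# Aligned fraction & gene presence


def aligned_fraction(
    alignments: Sequence[AlignmentRecord],
    query_len: int | None = None,
    min_identity: float = 95.0,
) -> float:
    """Fraction of the query genome covered by alignments at identity
    >= ``min_identity`` percent; overlapping intervals merged first.

    The query genome occupies the read axis of the alignment records.
    """
    alns = list(alignments)
    if query_len is None:
        if not alns:
            raise ValueError("query_len required when no alignments are given")
        query_len = alns[0].read_len
    intervals = [
        (a.read_start, a.read_end)
        for a in alns
        if 100.0 * a.identity >= min_identity
    ]
    return interval_union_length(intervals) / query_len


def gene_presence(
    genes: Sequence[GeneModel],
    alignments: Sequence[AlignmentRecord],
    partial_uncovered_fraction: float = 0.25,
) -> list[GenePresence]:
    """Classify genes by read support: absent (no covered base),
    partial (uncovered fraction > threshold), else present.

    A base is covered when its depth is >= 1.
    """
    by_target: dict[str, list[AlignmentRecord]] = {}
    target_lens: dict[str, int] = {}
    for a in alignments:
        by_target.setdefault(a.target_id, []).append(a)
        target_lens[a.target_id] = a.target_len
    profiles = {
        t: compute_depth(alns, target_lens[t], t) for t, alns in by_target.items()
    }
    out = []
    for g in genes:
        prof = profiles.get(g.contig)
        if prof is None:
            covered = 0.0
        else:
            window = prof.depth[g.start : g.end]
            covered = float((window >= 1).mean()) if len(window) else 0.0
        if covered == 0.0:
            status = "absent"
        elif 1.0 - covered > partial_uncovered_fraction:
            status = "partial"
        else:
            status = "present"
        out.append(GenePresence(gene_id=g.gene_id, covered_fraction=covered, status=status))
    return out
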