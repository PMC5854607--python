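"""Methylome inference from polymerase-kinetics summaries.

Each genomic (position, strand) carries summary statistics of observed
log-IPD values and of an unmethylated control model.  A one-sided Welch
t-test of obs > ctrl is converted to a Phred-like modification quality
value qv = -10*log10(p), capped; sites at qv >= 100 are called
methylated (6mA on adenines, 4mC on cytosines — 5mC is never called,
since no Tet1 conversion signal is modelled).  Around the called sites
a greedy specific-to-degenerate search recovers IUPAC recognition
motifs, which are then summarised per motif: occurrences, methylated
fraction, intergenic fraction and mean per-strand coverage.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    GeneModel,
    GenomeSequence,
    IUPACMotif,
    KineticsSite,
    ModificationCall,
    MotifSummaryRow,
    revcomp,
)

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

DEFAULT_QV_CAP = 1000.0
DEFAULT_QV_THRESHOLD = 100.0

_LN10 = math.log(10)


# ---------------------------------------------------------------------------
# Scoring


def _welch(obs_mean, obs_sd, obs_n, ctrl_mean, ctrl_sd, ctrl_n):
    v1 = np.square(obs_sd) / obs_n
    v2 = np.square(ctrl_sd) / ctrl_n
    se2 = v1 + v2
    t = (obs_mean - ctrl_mean) / np.sqrt(se2)
    df = np.square(se2) / (np.square(v1) / (obs_n - 1) + np.square(v2) / (ctrl_n - 1))
    return t, df


def score_sites(
    table: pd.DataFrame,
    qv_cap: float = DEFAULT_QV_CAP,
    qv_threshold: float = DEFAULT_QV_THRESHOLD,
) -> pd.DataFrame:
    """Score every kinetics row: one-sided Welch t-test of
    obs_mean > ctrl_mean on the log-IPD scale.

    Returns a call table with columns target_id, position, strand,
    base, mod_type, qv, coverage.  mod_type is 6mA/4mC when the base is
    A/C and qv clears the call threshold, else "unknown".
    """
    if (table["obs_n"] < 2).any() or (table["ctrl_n"] < 2).any():
        raise ValueError("kinetics rows with n < 2 cannot be scored")
    if (table["obs_sd"] <= 0).any() or (table["ctrl_sd"] <= 0).any():
        raise ValueError("kinetics rows with sd <= 0 cannot be scored")
    t, df = _welch(
        table["obs_mean"].to_numpy(float),
        table["obs_sd"].to_numpy(float),
        table["obs_n"].to_numpy(float),
        table["ctrl_mean"].to_numpy(float),
        table["ctrl_sd"].to_numpy(float),
        table["ctrl_n"].to_numpy(float),
    )
    qv = np.minimum(-10.0 * stats.t.logsf(t, df) / _LN10, qv_cap)
    base = table["base"].to_numpy(str)
    typed = np.where(base == "A", "6mA", np.where(base == "C", "4mC", "unknown"))
    mod_type = np.where(qv >= qv_threshold, typed, "unknown")
    return pd.DataFrame(
        {
            "target_id": table["target_id"].to_numpy(),
            "position": table["position"].to_numpy(),
            "strand": table["strand"].to_numpy(),
            "base": base,
            "mod_type": mod_type,
            "qv": qv,
            "coverage": table["obs_n"].to_numpy(),
        }
    )


def score_site(
    site: KineticsSite,
    qv_cap: float = DEFAULT_QV_CAP,
    qv_threshold: float = DEFAULT_QV_THRESHOLD,
) -> ModificationCall:
    """Score a single kinetics site (see :func:`score_sites`)."""
    t, df = _welch(
        site.obs_mean, site.obs_sd, site.obs_n,
        site.ctrl_mean, site.ctrl_sd, site.ctrl_n,
    )
    qv = float(min(-10.0 * stats.t.logsf(t, df) / _LN10, qv_cap))
    if qv >= qv_threshold and site.base in ("A", "C"):
        mod_type = "6mA" if site.base == "A" else "4mC"
    else:
        mod_type = "unknown"
    return ModificationCall(
        target_id=site.target_id,
        position=site.position,
        strand=site.strand,
        base=site.base,
        mod_type=mod_type,
        qv=qv,
        coverage=site.obs_n,
    )


def call_sites(calls, qv_threshold: float = DEFAULT_QV_THRESHOLD):
    """Retain calls with qv >= threshold (boundary inclusive), order
    preserved.  Accepts a call DataFrame or a list of ModificationCall."""
    if isinstance(calls, pd.DataFrame):
        return calls[calls["qv"] >= qv_threshold].reset_index(drop=True)
    return [c for c in calls if c.qv >= qv_threshold]


# ---------------------------------------------------------------------------
# IUPAC matching


def _pattern_regex(pattern: str) -> re.Pattern:
    body = "".join(
        c if len(IUPAC_SETS[c]) == 1 else "[" + "".join(sorted(IUPAC_SETS[c])) + "]"
        for c in pattern
    )
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def is_palindromic(pattern: str) -> bool:
    return pattern == revcomp(pattern)


def count_motif_occurrences(
    genome: GenomeSequence,
    motif: IUPACMotif,
    count_per_strand: bool = False,
) -> list[tuple[int, str]]:
    """All motif matches on both strands as (methylated-base forward
    coordinate, strand).

    A palindromic (self-reverse-complementary) match is reported once
    per locus on the + strand unless ``count_per_strand`` is set, in
    which case both strand records are emitted.
    """
    pat = motif.pattern
    mi = motif.methyl_index
    fwd_hits = [m.start() for m in _pattern_regex(pat).finditer(genome.residues)]
    out = [(i + mi, "+") for i in fwd_hits]
    if is_palindromic(pat):
        if count_per_strand:
            out += [(i + len(pat) - 1 - mi, "-") for i in fwd_hits]
    else:
        rc = revcomp(pat)
        rev_hits = [m.start() for m in _pattern_regex(rc).finditer(genome.residues)]
        out += [(i + len(pat) - 1 - mi, "-") for i in rev_hits]
    return sorted(out)


# ---------------------------------------------------------------------------
# Motif discovery


def _called_tuples(called_sites) -> list[tuple[int, str, str]]:
    if isinstance(called_sites, pd.DataFrame):
        if called_sites.empty:
            return []
        return list(
            zip(
                called_sites["position"].astype(int),
                called_sites["strand"],
                called_sites["base"],
            )
        )
    return [(c.position, c.strand, c.base) for c in called_sites]


def _evaluate(
    genome: GenomeSequence,
    motif: IUPACMotif,
    called: set[tuple[int, str]],
) -> tuple[int, int, float]:
    occ = count_motif_occurrences(genome, motif, count_per_strand=True)
    n_det = len(occ)
    n_meth = sum(1 for site in occ if site in called)
    return n_det, n_meth, (n_meth / n_det if n_det else 0.0)


def _trim_n(pattern: str, methyl_index: int) -> tuple[str, int]:
    start, end = 0, len(pattern)
    while start < methyl_index and pattern[start] == "N":
        start += 1
    while end - 1 > methyl_index and pattern[end - 1] == "N":
        end -= 1
    return pattern[start:end], methyl_index - start


def _degeneracy(pattern: str) -> int:
    return sum(1 for c in pattern if len(IUPAC_SETS[c]) > 1)


def _find_one_motif(
    genome: GenomeSequence,
    base: str,
    mod_type: str,
    remaining: set[tuple[int, str]],
    max_len: int,
    max_degenerate: int,
    min_sites: int,
    min_frac: float,
    seed_lengths: Sequence[int],
    max_seed_candidates: int = 200,
) -> IUPACMotif | None:
    seq = genome.residues
    L = len(seq)
    flank = max_len - 1
    contexts = []
    for pos, strand in remaining:
        if pos - flank < 0 or pos + flank + 1 > L:
            continue
        window = seq[pos - flank : pos + flank + 1]
        contexts.append(window if strand == "+" else revcomp(window))
    from collections import Counter

    counter: Counter = Counter()
    for ctx in contexts:
        for wlen in seed_lengths:
            for mi in range(wlen):
                word = ctx[flank - mi : flank - mi + wlen]
                if len(word) == wlen and "N" not in word:
                    counter[(word, mi)] += 1
    candidates = [kc for kc in counter.items() if kc[1] >= min_sites]
    candidates.sort(key=lambda kc: -kc[1])
    best = None  # (n_meth, frac, -len, motif)
    for (word, mi), _count in candidates[:max_seed_candidates]:
        motif = IUPACMotif(pattern=word, methyl_index=mi, mod_type=mod_type)
        n_det, n_meth, frac = _evaluate(genome, motif, remaining)
        if frac >= min_frac and n_meth >= min_sites:
            key = (n_meth, frac, -len(word))
            if best is None or key > best[0]:
                best = (key, motif)
    if best is None:
        return None
    motif = best[1]
    n_det, n_meth, frac = _evaluate(genome, motif, remaining)

    # Greedy generalization: widen one position at a time while the
    # genome-wide methylated fraction stays above min_frac.
    improved = True
    while improved:
        improved = False
        best_step = None
        for p in range(len(motif.pattern)):
            if p == motif.methyl_index:
                continue
            current = IUPAC_SETS[motif.pattern[p]]
            for b in "ACGT":
                if b in current:
                    continue
                code = SET_TO_CODE[current | {b}]
                pattern = motif.pattern[:p] + code + motif.pattern[p + 1 :]
                trimmed, mi = _trim_n(pattern, motif.methyl_index)
                if _degeneracy(trimmed) > max_degenerate:
                    continue
                cand = IUPACMotif(pattern=trimmed, methyl_index=mi, mod_type=mod_type)
                c_det, c_meth, c_frac = _evaluate(genome, cand, remaining)
                if c_frac >= min_frac and c_meth > n_meth:
                    if best_step is None or c_meth > best_step[0]:
                        best_step = (c_meth, c_frac, cand)
        if best_step is not None:
            n_meth, frac, motif = best_step
            improved = True
    return motif


def discover_motifs(
    genome: GenomeSequence,
    called_sites,
    max_len: int = 12,
    max_degenerate: int = 3,
    min_sites: int = 20,
    min_frac: float = 0.3,
    seed_lengths: Sequence[int] = (4, 5, 6),
) -> list[IUPACMotif]:
    """Greedy specific-to-degenerate recognition-motif search.

    Separately for adenine and cytosine calls: seed with the most
    methylation-enriched exact word anchored at the methylated base,
    generalize positions to IUPAC codes while the genome-wide methylated
    fraction stays >= ``min_frac``, report the motif, remove the called
    sites it explains, and repeat until fewer than ``min_sites`` remain.
    Returned motifs are pairwise non-redundant.
    """
    calls = _called_tuples(called_sites)
    motifs: list[IUPACMotif] = []
    for base, mod_type in (("A", "6mA"), ("C", "4mC")):
        remaining = {(pos, strand) for pos, strand, b in calls if b == base}
        while len(remaining) >= min_sites:
            motif = _find_one_motif(
                genome, base, mod_type, remaining,
                max_len, max_degenerate, min_sites, min_frac, seed_lengths,
            )
            if motif is None:
                break
            motifs.append(motif)
            explained = set(
                count_motif_occurrences(genome, motif, count_per_strand=True)
            )
            remaining -= explained
    return _drop_redundant(genome, motifs)


def _drop_redundant(
    genome: GenomeSequence, motifs: list[IUPACMotif]
) -> list[IUPACMotif]:
    """Drop any motif whose match-locus set contains or is contained by
    an earlier (higher-priority) motif's."""
    kept: list[IUPACMotif] = []
    kept_sets: list[set] = []
    for motif in motifs:
        occ = set(count_motif_occurrences(genome, motif, count_per_strand=True))
        if any(occ <= prev or prev <= occ for prev in kept_sets):
            continue
        kept.append(motif)
        kept_sets.append(occ)
    return kept


# ---------------------------------------------------------------------------
# Motif summary


def motif_summary(
    genome: GenomeSequence,
    motifs: Sequence[IUPACMotif],
    called_sites,
    all_scored_sites: pd.DataFrame | None = None,
    genes: Sequence[GeneModel] = (),
    count_per_strand: bool = False,
) -> list[MotifSummaryRow]:
    """Per-motif occurrence/methylation statistics.

    n_detected counts genomic occurrences (palindromic loci once unless
    ``count_per_strand``); n_methylated counts occurrences whose
    methylated base carries a retained call; frac_intergenic is the
    percentage of detected occurrences whose methylated base lies
    outside every gene model; mean_coverage is the mean per-strand
    coverage over the methylated occurrences.
    """
    called = set()
    for pos, strand, _base in _called_tuples(called_sites):
        called.add((pos, strand))
    coverage: dict[tuple[int, str], float] = {}
    source = all_scored_sites if all_scored_sites is not None else called_sites
    if isinstance(source, pd.DataFrame):
        for pos, strand, cov in zip(
            source["position"].astype(int), source["strand"], source["coverage"]
        ):
            coverage[(pos, strand)] = float(cov)
    else:
        for c in source:
            coverage[(c.position, c.strand)] = float(c.coverage)

    genic = np.zeros(len(genome), dtype=bool)
    for g in genes:
        if g.contig == genome.id or not g.contig:
            genic[g.start : g.end] = True

    rows = []
    for motif in motifs:
        occ = count_motif_occurrences(genome, motif, count_per_strand)
        n_det = len(occ)
        meth = [site for site in occ if site in called]
        n_meth = len(meth)
        inter = sum(1 for pos, _s in occ if not genic[pos])
        covs = [coverage[site] for site in meth if site in coverage]
        rows.append(
            MotifSummaryRow(
                motif=motif,
                n_detected=n_det,
                n_methylated=n_meth,
                frac_methylated=100.0 * n_meth / n_det if n_det else 0.0,
                frac_intergenic=100.0 * inter / n_det if n_det else 0.0,
                mean_coverage=float(np.mean(covs)) if covs else 0.0,
            )
        )
    return rows


def summary_frame(rows: Iterable[MotifSummaryRow]) -> pd.DataFrame:
    """Motif summary as a DataFrame with the canonical output columns."""
    return pd.DataFrame(
        [
            {
                "motif": r.motif.pattern,
                "methyl_index": r.motif.methyl_index,
                "mod_type": r.motif.mod_type,
                "n_detected": r.n_detected,
                "n_methylated": r.n_methylated,
                "frac_methylated": round(r.frac_methylated, 2),
                "frac_intergenic": round(r.frac_intergenic, 2),
                "mean_coverage": round(r.mean_coverage, 1),
            }
            for r in rows
        ]
    )


def write_modifications(calls: pd.DataFrame, path) -> None:
    """Retained calls as GFF3-like text: one row per call with position,
    strand, modification type, qv and coverage."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in calls.itertuples(index=False):
            fh.write(
                f"{row.target_id}\tstrainsieve\tmodified_base\t"
                f"{int(row.position) + 1}\t{int(row.position) + 1}\t"
                f"{row.qv:.1f}\t{row.strand}\t.\t"
                f"mod_type={row.mod_type};coverage={int(row.coverage)}\n"
            )
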