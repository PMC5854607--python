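"""Readers and writers for the standard formats the pipeline consumes.

FASTA/FASTQ go through Biopython, minimal SAM through pysam.  PAF is the
canonical alignment dialect: the pipeline needs intervals plus identity,
not base-level alignments.  GFF3 is converted to 0-based half-open
coordinates at this boundary and nowhere else.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AlignmentRecord, GeneModel, GenomeSequence, ReadRecord


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_sequences(
    path: str | Path,
    format: str = "fasta",
    kind: str | None = None,
) -> list[GenomeSequence] | list[ReadRecord]:
    """Read FASTA/FASTQ records in file order.

    ``kind`` selects the container: "genome" (default for FASTA) or
    "read" (default, and forced qualities, for FASTQ).  Residues are
    uppercased.  An empty file yields an empty list.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported sequence format {format!r}")
    if kind is None:
        kind = "genome" if format == "fasta" else "read"
    out: list = []
    try:
        for rec in SeqIO.parse(str(path), format):
            if kind == "genome":
                out.append(GenomeSequence(id=rec.id, residues=str(rec.seq)))
            else:
                qual = rec.letter_annotations.get("phred_quality")
                out.append(
                    ReadRecord(
                        id=rec.id,
                        residues=str(rec.seq),
                        quality=list(qual) if qual is not None else None,
                    )
                )
    except ValueError as exc:  # Biopython's parse failure
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_sequences(
    records: Iterable[GenomeSequence | ReadRecord],
    path: str | Path,
    format: str = "fasta",
) -> None:
    seqrecs = []
    for rec in records:
        sr = SeqRecord(Seq(rec.residues), id=rec.id, description="")
        if format == "fastq":
            qual = getattr(rec, "quality", None)
            if qual is None:
                qual = [30] * len(rec.residues)
            sr.letter_annotations["phred_quality"] = list(qual)
        seqrecs.append(sr)
    SeqIO.write(seqrecs, str(path), format)


# ---------------------------------------------------------------------------
# PAF / minimal SAM


def best_per_read(alignments: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Retain one alignment per read_id: highest matches, ties by
    longest block, then first seen — the single-best-alignment contract."""
    best: dict[str, tuple[int, int, int, AlignmentRecord]] = {}
    for idx, aln in enumerate(alignments):
        key = (aln.matches, aln.block_len, -idx)
        prev = best.get(aln.read_id)
        if prev is None or key > prev[:3]:
            best[aln.read_id] = (*key, aln)
    return [entry[3] for entry in best.values()]


def _parse_paf_line(line: str, lineno: int, path) -> AlignmentRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ParseError(f"{path}:{lineno}: PAF needs >= 12 columns, got {len(fields)}")
    try:
        return AlignmentRecord(
            read_id=fields[0],
            read_len=int(fields[1]),
            read_start=int(fields[2]),
            read_end=int(fields[3]),
            strand=fields[4],
            target_id=fields[5],
            target_len=int(fields[6]),
            target_start=int(fields[7]),
            target_end=int(fields[8]),
            matches=int(fields[9]),
            block_len=int(fields[10]),
            mapq=int(fields[11]),
        )
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_alignments(
    path: str | Path,
    format: str = "paf",
    single_best: bool = True,
) -> list[AlignmentRecord]:
    """Read PAF or minimal SAM alignments.

    With ``single_best`` (the default) only the best record per read_id
    is retained (see :func:`best_per_read`).  Unmapped SAM records are
    skipped; SAM identity uses the NM tag when present, else assumes
    matches = block_len.
    """
    if format == "paf":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    records.append(_parse_paf_line(line, lineno, path))
    elif format in ("sam", "sam_minimal"):
        records = _read_sam(path)
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    return best_per_read(records) if single_best else records


def _read_sam(path: str | Path) -> list[AlignmentRecord]:
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            stats = rec.get_cigar_stats()[0]
            block_len = stats[0] + stats[1] + stats[2] + stats[7] + stats[8]  # M+I+D+=+X
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            matches = max(block_len - nm, 0)
            records.append(
                AlignmentRecord(
                    read_id=rec.query_name,
                    read_len=rec.infer_read_length() or rec.query_length,
                    read_start=rec.query_alignment_start,
                    read_end=rec.query_alignment_end,
                    strand="-" if rec.is_reverse else "+",
                    target_id=rec.reference_name,
                    target_len=sam.get_reference_length(rec.reference_name),
                    target_start=rec.reference_start,
                    target_end=rec.reference_end,
                    matches=matches,
                    block_len=block_len,
                    mapq=rec.mapping_quality,
                )
            )
    return records


def write_paf(alignments: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.read_id, a.read_len, a.read_start, a.read_end, a.strand,
                        a.target_id, a.target_len, a.target_start, a.target_end,
                        a.matches, a.block_len, a.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def read_annotation(
    path: str | Path,
    types: Sequence[str] = ("CDS", "gene"),
) -> list[GeneModel]:
    """Read GFF3 rows of the requested feature types as GeneModels.

    GFF 1-based inclusive coordinates become 0-based half-open here; the
    writer converts back exactly.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: GFF3 needs 9 columns")
            if fields[2] not in types:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{lineno}: bad interval {start1}..{end1}")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or f"{path}:{lineno}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig=fields[0],
                    start=start1 - 1,
                    end=end1,
                    strand=fields[6] if fields[6] in "+-" else "+",
                    product=attrs.get("product", ""),
                )
            )
    return genes


def write_annotation(
    genes: Iterable[GeneModel],
    path: str | Path,
    feature_type: str = "CDS",
    source: str = "strainsieve",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                "\t".join(
                    (
                        g.contig, source, feature_type,
                        str(g.start + 1), str(g.end), ".", g.strand, ".", attrs,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Interval / track output


def write_bed(
    intervals: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for target, start, end in intervals:
            fh.write(f"{target}\t{start}\t{end}\n")


def write_bedgraph(profiles, path: str | Path) -> None:
    """Depth track as bedGraph-style text: runs of equal depth merged.

    ``profiles`` is an iterable of DepthProfile.
    """
    with open(path, "w") as fh:
        for prof in profiles:
            depth = prof.depth
            run_start = 0
            for i in range(1, len(depth) + 1):
                if i == len(depth) or depth[i] != depth[run_start]:
                    fh.write(f"{prof.target_id}\t{run_start}\t{i}\t{int(depth[run_start])}\n")
                    run_start = i


def write_manifest(read_ids: Iterable[str], path: str | Path) -> None:
    """One read id per line."""
    with open(path, "w") as fh:
        for rid in read_ids:
            fh.write(f"{rid}\n")


def read_manifest(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# 12-column tabular hits (BLAST outfmt 6 plus query/subject lengths)


def read_hits(path: str | Path) -> list:
    """Read a 12-column tabular hit file.

    Standard outfmt-6 column order; query_len/subject_len, which the
    coverage filters need, are taken from columns 13/14 when present and
    must otherwise be supplied downstream.
    """
    from .model import PairwiseHit

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: need >= 12 columns")
            try:
                hits.append(
                    PairwiseHit(
                        query_id=f[0],
                        subject_id=f[1],
                        identity=float(f[2]),
                        aln_len=int(f[3]),
                        query_len=int(f[12]) if len(f) > 12 else 0,
                        subject_len=int(f[13]) if len(f) > 13 else 0,
                        bitscore=float(f[11]),
                        evalue=float(f[10]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits(hits: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.identity:.2f}", h.aln_len,
                        0, 0, 0, 0, 0, 0, f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                        h.query_len, h.subject_len,
                    )
                )
                + "\n"
            )
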