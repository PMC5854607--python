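"""Pipeline configuration and stage orchestration.

``PipelineConfig`` holds every printed threshold of the workflow in one
place; ``run_pipeline`` chains the stages (binning, circularization,
methylome, comparison) over whatever inputs are present and writes
per-stage tabular outputs plus a run log.  Outputs are deterministic
given the config seed and inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import covbin, genomecmp, io, methylome


class ConfigurationError(ValueError):
    """A requested stage is missing a required input or setting."""


@dataclass(slots=True)
class PipelineConfig:
    """All tunable thresholds of the pipeline.

    Defaults are the study values: QV >= 100 modification calls, 90%
    BBH identity, query-coverage exclusion at <=75% / >=120%, 1020 bp
    ANI fragments, 1 kb GC windows at 5 percentage-point deviation,
    <25x low-coverage regions (>=50 bp), >25% uncovered = partial gene,
    100x bin refinement floor, >190x contig selection.
    """

    rng_seed: int = 0
    bins_relative: bool = False
    footprint_statistic: str = "median"
    refine_min_depth: float = 100.0
    contig_select_depth: float = 190.0
    qv_threshold: float = 100.0
    bbh_min_identity: float = 90.0
    qcov_exclude_low: float = 0.75
    qcov_exclude_high: float = 1.20
    ani_fragment: int = 1020
    gc_window: int = 1000
    gc_deviation: float = 5.0
    lowcov_threshold: float = 25.0
    lowcov_min_len: int = 50
    partial_uncovered_fraction: float = 0.25
    circular_min_overlap: int = 100
    circular_max_mismatch_frac: float = 0.02

    def __post_init__(self) -> None:
        positive = (
            "refine_min_depth", "qv_threshold", "bbh_min_identity",
            "qcov_exclude_low", "qcov_exclude_high", "ani_fragment",
            "gc_window", "gc_deviation", "lowcov_threshold",
            "partial_uncovered_fraction", "circular_min_overlap",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not self.qcov_exclude_low < self.qcov_exclude_high:
            raise ConfigurationError("qcov_exclude_low must be < qcov_exclude_high")

    def bin_specs(self) -> list[covbin.CoverageBinSpec]:
        return covbin.default_bin_specs(relative=self.bins_relative)


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def parse_config(path: str | Path) -> PipelineConfig:
    """Flat key=value config file mirroring PipelineConfig field names."""
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    values = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected key=value")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
            ftype = fields[key].type
            if ftype == "bool":
                values[key] = _BOOL[raw.lower()]
            elif ftype == "int":
                values[key] = int(raw)
            elif ftype == "float":
                values[key] = float(raw)
            else:
                values[key] = raw
    return PipelineConfig(**values)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")


@dataclass(slots=True)
class PipelineInputs:
    """File paths per stage; a stage runs when its inputs are present."""

    alignments: str | None = None  # PAF, reads vs reference (binning)
    reference: str | None = None  # FASTA reference for binning/methylome
    assembly: str | None = None  # FASTA linear assembly to circularize
    kinetics: str | None = None  # kinetics table (methylome)
    annotation: str | None = None  # GFF3 (methylome/compare)
    genome_a: str | None = None  # FASTA (compare)
    genome_b: str | None = None  # FASTA (compare)
    hits_ab: str | None = None  # 12-column tabular (compare)
    hits_ba: str | None = None


STAGE_REQUIREMENTS = {
    "bin": ("alignments", "reference"),
    "circularize": ("assembly",),
    "methylome": ("kinetics", "reference"),
    "compare": ("genome_a", "genome_b"),
}


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
    stages: list[str] | None = None,
) -> dict:
    """Run the requested stages and write their outputs under ``outdir``.

    With ``stages=None`` every stage whose inputs are present runs;
    explicitly requested stages fail fast with
    :class:`ConfigurationError` when an input is missing.  The report
    dict records per-stage row counts; a run log (config, seed,
    version) is written alongside the outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is not None:
        for stage in stages:
            missing = [
                req for req in STAGE_REQUIREMENTS[stage]
                if getattr(inputs, req) is None
            ]
            if missing:
                raise ConfigurationError(
                    f"stage {stage!r} requires inputs: {', '.join(missing)}"
                )
        selected = stages
    else:
        selected = [
            stage
            for stage, reqs in STAGE_REQUIREMENTS.items()
            if all(getattr(inputs, req) is not None for req in reqs)
        ]
        if not selected:
            raise ConfigurationError("no stage has its required inputs")

    report: dict = {"stages": {}}
    for stage in selected:
        runner = globals()[f"_run_{stage}"]
        report["stages"][stage] = runner(config, inputs, outdir)

    log = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config": dataclasses.asdict(config),
        "stages": report["stages"],
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return report


def _run_bin(config: PipelineConfig, inputs: PipelineInputs, outdir: Path) -> dict:
    targets = io.read_sequences(inputs.reference)
    target_lens = {t.id: len(t) for t in targets}
    alignments = io.read_alignments(inputs.alignments)
    assignments, profiles = covbin.bin_reads(
        alignments, target_lens, config.bin_specs(), config.footprint_statistic
    )
    bin_names = sorted({s.name for s in config.bin_specs()})
    for name in bin_names:
        io.write_manifest(
            sorted(a.read_id for a in assignments if name in a.bins),
            outdir / f"bin_{name}.reads.txt",
        )
    io.write_bedgraph(profiles.values(), outdir / "depth.bedgraph")
    lowcov = [
        (t, s, e)
        for t, prof in profiles.items()
        for s, e in covbin.low_coverage_regions(
            prof, config.lowcov_threshold, config.lowcov_min_len
        )
    ]
    io.write_bed(lowcov, outdir / "low_coverage.bed")
    return {
        "n_alignments": len(alignments),
        "bin_sizes": {
            name: sum(1 for a in assignments if name in a.bins) for name in bin_names
        },
        "n_low_coverage_regions": len(lowcov),
    }


def _run_circularize(config: PipelineConfig, inputs: PipelineInputs, outdir: Path) -> dict:
    out_rows = []
    circular = []
    for seq in io.read_sequences(inputs.assembly):
        res = covbin.circularize(
            seq, config.circular_min_overlap, config.circular_max_mismatch_frac
        )
        out_rows.append(
            {
                "id": seq.id,
                "circularized": res.circularized,
                "overlap_len": res.overlap_len,
                "ambiguous": res.ambiguous,
            }
        )
        circular.append(res.genome if res.genome is not None else seq)
    io.write_sequences(circular, outdir / "circularized.fasta")
    (outdir / "circularization.json").write_text(json.dumps(out_rows, indent=2))
    return {"n_sequences": len(out_rows),
            "n_circularized": sum(r["circularized"] for r in out_rows)}


def _run_methylome(config: PipelineConfig, inputs: PipelineInputs, outdir: Path) -> dict:
    from .simulate import read_kinetics

    genome = io.read_sequences(inputs.reference)[0]
    table = read_kinetics(inputs.kinetics)
    scored = methylome.score_sites(table, qv_threshold=config.qv_threshold)
    called = methylome.call_sites(scored, config.qv_threshold)
    motifs = methylome.discover_motifs(genome, called)
    genes = io.read_annotation(inputs.annotation) if inputs.annotation else []
    rows = methylome.motif_summary(genome, motifs, called, scored, genes)
    methylome.write_modifications(called, outdir / "modifications.gff")
    methylome.summary_frame(rows).to_csv(outdir / "motif_summary.csv", index=False)
    return {
        "n_scored": len(scored),
        "n_called": len(called),
        "n_motifs": len(motifs),
    }


def _run_compare(config: PipelineConfig, inputs: PipelineInputs, outdir: Path) -> dict:
    import pandas as pd

    ga = io.read_sequences(inputs.genome_a)[0]
    gb = io.read_sequences(inputs.genome_b)[0]
    ani = genomecmp.orthoani(ga, gb, config.ani_fragment)
    (outdir / "ani.txt").write_text(
        f"{ga.id}\t{gb.id}\t"
        + (f"{ani.ani:.2f}" if ani.defined else "NA")
        + f"\t{ani.n_fragment_pairs}\t{ani.fragment_len}\n"
    )
    n_deviant, windows = genomecmp.gc_deviant_windows(
        ga, config.gc_window, config.gc_deviation
    )
    io.write_bed(((ga.id, s, e) for s, e in windows), outdir / "gc_deviant.bed")
    result = {"ani": ani.ani, "n_gc_deviant_windows": n_deviant}
    if inputs.hits_ab and inputs.hits_ba:
        hits_ab = io.read_hits(inputs.hits_ab)
        hits_ba = io.read_hits(inputs.hits_ba)
        pairs = genomecmp.best_bidirectional_hits(
            hits_ab, hits_ba, config.bbh_min_identity
        )
        pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(
            outdir / "bbh_pairs.csv", index=False
        )
        surviving = genomecmp.filter_hits(
            hits_ab, config.bbh_min_identity,
            config.qcov_exclude_low, config.qcov_exclude_high,
        )
        queries = {h.query_id for h in hits_ab}
        unique = sorted(genomecmp.unique_genes(queries, surviving))
        pd.DataFrame({"gene_id": unique}).to_csv(outdir / "unique_genes.csv", index=False)
        result.update({"n_bbh": len(pairs), "n_unique_genes": len(unique)})
    if inputs.annotation and inputs.alignments:
        genes = io.read_annotation(inputs.annotation)
        alns = io.read_alignments(inputs.alignments)
        presence = genomecmp.gene_presence(
            genes, alns, config.partial_uncovered_fraction
        )
        pd.DataFrame(
            [
                {"gene_id": p.gene_id,
                 "covered_fraction": round(p.covered_fraction, 4),
                 "status": p.status}
                for p in presence
            ]
        ).to_csv(outdir / "gene_presence.csv", index=False)
        result["presence_counts"] = {
            status: sum(1 for p in presence if p.status == status)
            for status in ("present", "partial", "absent")
        }
    return result
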