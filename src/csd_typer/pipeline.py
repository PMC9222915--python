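"""End-to-end orchestration: reads -> genotypes -> catalogue -> reports."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from csd_typer import assembler, catalog as catalog_mod, genotyper, io_formats
from csd_typer.genotyper import FunnelReport, Genotype
from csd_typer.io_formats import GenomicInterval, HVR_INTERVAL, SampleSheet
from csd_typer.translator import END_ANCHOR, START_ANCHOR

log = logging.getLogger("csd_typer")


@dataclass
class PipelineConfig:
    region: GenomicInterval = HVR_INTERVAL
    min_overlap: int = 40
    min_identity: float = 0.90
    mismatch_penalty: float = 2.0
    min_contig_depth: int = 0
    max_singletons: int = 1
    start_anchor: str = START_ANCHOR
    end_anchor: str = END_ANCHOR
    min_peptide_len: int = 20
    max_peptide_len: int = 80
    out_dir: str = "csd_typer_out"
    make_tree: bool = False
    outgroup_label: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class PipelineResult:
    genotypes: list[Genotype]
    catalog: catalog_mod.AlleleCatalog
    funnel: FunnelReport
    sample_status: dict[str, str]
    table_paths: dict[str, str] = field(default_factory=dict)
    newick: Optional[str] = None


def _load_sample_reads(path: str, region: GenomicInterval):
    ext = os.path.splitext(path)[1].lower()
    if ext in (".fastq", ".fq"):
        return io_formats.read_fastq(path)
    if ext in (".fasta", ".fa", ".fna"):
        return io_formats.read_fasta(path)
    if ext == ".sam":
        return io_formats.extract_region_reads(path, region)
    raise ValueError(f"unrecognized input extension for {path!r}")


def run_pipeline(sample_sheet: SampleSheet, config: PipelineConfig) -> PipelineResult:
    """Run extraction, assembly, typing and cataloguing over a cohort.

    Per-sample errors are recorded in ``sample_status`` and do not abort
    the run. Given identical inputs and configuration, all outputs are
    deterministic.
    """
    outcomes = []
    genotypes: list[Genotype] = []
    status: dict[str, str] = {}
    select_kwargs = dict(
        start_anchor=config.start_anchor,
        end_anchor=config.end_anchor,
        min_len=config.min_peptide_len,
        max_len=config.max_peptide_len,
    )
    for sample_id, subspecies, path in sample_sheet.rows:
        try:
            reads = _load_sample_reads(path, config.region)
            asm = assembler.assemble(
                reads,
                min_overlap=config.min_overlap,
                min_identity=config.min_identity,
                mismatch_penalty=config.mismatch_penalty,
                min_contig_depth=config.min_contig_depth,
            )
        except Exception as exc:  # sample-local failure, keep going
            log.warning("sample %s failed: %s", sample_id, exc)
            status[sample_id] = f"error: {exc}"
            continue
        verdict = genotyper.filter_sample(asm, max_singletons=config.max_singletons)
        if not verdict:
            outcomes.append((asm, None))
            status[sample_id] = f"filtered: {verdict.reason}"
            continue
        call = genotyper.call_genotype(sample_id, subspecies, asm, **select_kwargs)
        outcomes.append((asm, call))
        if isinstance(call, Genotype):
            genotypes.append(call)
            status[sample_id] = "genotyped"
        else:
            status[sample_id] = f"rejected: {call.reason}"

    funnel = genotyper.funnel_report(outcomes)
    cat = catalog_mod.cluster_alleles(genotypes)
    if cat.total_sequences:
        catalog_mod.frequencies(cat)
        catalog_mod.annotate_known(cat, catalog_mod.load_reference_peptides())

    result = PipelineResult(genotypes, cat, funnel, status)

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        if cat.total_sequences:
            result.table_paths = io_formats.write_report_tables(
                cat, genotypes, config.out_dir, funnel
            )

    if config.make_tree and len(cat.records) >= 3:
        from csd_typer import phylo_lite

        labels = [f"allele_{r.allele_id}" for r in cat.records]
        peptides = [r.aa_seq for r in cat.records]
        dm = phylo_lite.distance_matrix(labels, peptides)
        tree = phylo_lite.nj_tree(dm)
        if config.outgroup_label and config.outgroup_label in labels:
            tree = phylo_lite.root_on_outgroup(tree, config.outgroup_label)
        result.newick = phylo_lite.write_newick(tree)
        if config.out_dir:
            p = os.path.join(config.out_dir, "alleles.nwk")
            with open(p, "w") as fh:
                fh.write(result.newick + "\n")
            result.table_paths["tree"] = p
    return result
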