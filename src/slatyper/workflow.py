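"""End-to-end orchestration: reads -> clusters -> calls -> haplotypes, with
publication-shaped TSV/JSON reports and structured stage logging."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .genotyping import NovelSequence, SampleGenotype, genotype_run
from .haplotypes import (HaplotypeInference, infer_haplotypes, prevalence)
from .library import AlleleLibrary, load_library
from .reads import PipelineStats, SampleClusterResult, read_fastq_pairs, \
    run_read_pipeline

logger = logging.getLogger(__name__)


def load_barcodes(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "barcode"} <= set(df.columns):
        raise ValueError(f"{path}: barcode TSV needs 'sample' and 'barcode' "
                         "columns")
    return dict(zip(df["sample"], df["barcode"]))


@dataclass
class RunReport:
    config: RunConfig
    stats: PipelineStats
    clusters: dict[str, SampleClusterResult]
    genotypes: dict[str, SampleGenotype]
    novels: list[NovelSequence]
    haplotypes: HaplotypeInference


def run_pipeline(config: RunConfig, *, write: bool = True) -> RunReport:
    """Execute every stage on the configured inputs.

    Missing or corrupt inputs fail fast; typing-failed samples are reported,
    not fatal.  With ``write=True`` per-stage artifacts land in
    ``config.out_dir``.
    """
    for p in (config.library_fasta, config.barcodes_tsv, config.fastq1,
              config.fastq2):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    library = load_library(config.library_fasta)
    barcodes = load_barcodes(config.barcodes_tsv)
    primers = config.primer_pair()
    logger.info("library: %d alleles; %d samples; primers %s",
                len(library), len(barcodes), primers.name)

    pairs = read_fastq_pairs(config.fastq1, config.fastq2)
    clusters, stats = run_read_pipeline(
        pairs, barcodes, primers,
        expected_len=config.insert_len(), q_min=config.q_min,
        min_overlap=config.min_overlap, min_match=config.min_match,
        min_reads=config.min_reads, max_clusters=config.max_clusters,
        length_tol=config.length_tol,
        dominant_fraction=config.dominant_fraction)
    logger.info("demultiplex: %d in, %d assigned, rejected %s",
                stats.n_input, stats.n_assigned, dict(stats.rejected))

    genotypes, novels = genotype_run(clusters, library, primers,
                                     config.min_identity)
    n_failed = sum(g.typing_failed for g in genotypes.values())
    logger.info("typing: %d samples, %d typing-failed, %d novel sequences",
                len(genotypes), n_failed, len(novels))

    allele_sets = {s: g.alleles_by_locus() for s, g in genotypes.items()
                   if not g.typing_failed}
    inference = infer_haplotypes(allele_sets, config.population,
                                 max_dup_per_locus=config.max_dup_per_locus)
    logger.info("haplotypes: pool of %d over %d typed animals",
                len(inference.pool), inference.n_typed)

    report = RunReport(config, stats, clusters, genotypes, novels, inference)
    if write:
        write_reports(report, Path(config.out_dir))
    return report


def genotype_table(report: RunReport) -> pd.DataFrame:
    rows = []
    for sample in sorted(report.genotypes):
        g = report.genotypes[sample]
        for call in g.calls:
            rows.append({
                "sample": sample,
                "locus": call.locus,
                "call": call.label if call.status != "novel_candidate"
                        else f"novel({call.closest_match})",
                "status": call.status,
                "reads": call.read_count,
                "fraction": round(call.read_fraction, 4),
                "similarity": call.similarity_str,
                "homozygous_locus": call.locus in g.homozygous_loci,
                "duplicated_locus": call.locus in g.duplication_flags,
                "typing_failed": g.typing_failed,
            })
        if not g.calls:
            rows.append({"sample": sample, "locus": "", "call": "",
                         "status": "", "reads": 0, "fraction": 0.0,
                         "similarity": "", "homozygous_locus": False,
                         "duplicated_locus": False, "typing_failed": True})
    return pd.DataFrame(rows)


def novel_table(novels: list[NovelSequence]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": n.ns_id,
        "size_nt": len(n.sequence),
        "closest_match": n.closest_match,
        "similarity": n.similarity_str,
        "n_carriers": len(n.carriers),
        "carriers": ",".join(n.carriers),
        "confidence": "low" if n.low_confidence else "confident",
        "locus": n.locus,
    } for n in novels])


def haplotype_tables(inference: HaplotypeInference
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    pool_rows = []
    for hap in inference.pool:
        d = hap.as_dict()
        pool_rows.append({
            "haplotype": hap.id,
            "SLA-1": ",".join(d.get("SLA-1", ())),
            "SLA-3": ",".join(d.get("SLA-3", ())),
            "SLA-2": ",".join(d.get("SLA-2", ())),
            "unassigned": ",".join(d.get("unassigned", ())),
        })
    asg_rows = [{
        "animal": a.animal,
        "status": a.status,
        "haplotypes": "/".join(a.haplotypes),
        "residual": ";".join(f"{l}:{n}" for l, n in a.residual),
        "note": a.note,
    } for a in inference.assignments.values()]
    prev_rows = [{
        "population": inference.population,
        "haplotype": p.haplotype,
        "carriers": p.carriers,
        "carrier_pct": round(p.carrier_pct, 1),
        "chromosome_freq": round(p.chromosome_freq, 4),
    } for p in prevalence(inference)] if inference.n_typed else []
    return (pd.DataFrame(pool_rows), pd.DataFrame(asg_rows),
            pd.DataFrame(prev_rows))


def cluster_table(clusters: dict[str, SampleClusterResult]) -> pd.DataFrame:
    rows = []
    for sample in sorted(clusters):
        res = clusters[sample]
        for c in res.clusters:
            rows.append({"sample": sample, "rank": c.rank, "size": c.size,
                         "length": c.length, "flags": ""})
        for reason, removed in sorted(res.removed.items()):
            for c in removed:
                rows.append({"sample": sample, "rank": c.rank, "size": c.size,
                             "length": c.length, "flags": reason})
    return pd.DataFrame(rows)


def write_reports(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    genotype_table(report).to_csv(out_dir / "genotypes.tsv", sep="\t",
                                  index=False)
    novel_table(report.novels).to_csv(out_dir / "novel_registry.tsv",
                                      sep="\t", index=False)
    cluster_table(report.clusters).to_csv(out_dir / "clusters.tsv", sep="\t",
                                          index=False)
    pool_df, asg_df, prev_df = haplotype_tables(report.haplotypes)
    pool_df.to_csv(out_dir / "haplotype_pool.tsv", sep="\t", index=False)
    asg_df.to_csv(out_dir / "haplotype_assignments.tsv", sep="\t", index=False)
    prev_df.to_csv(out_dir / "haplotype_prevalence.tsv", sep="\t", index=False)
    stats = report.stats.as_dict()
    stats["parameters"] = {
        k: v for k, v in vars(report.config).items()
        if not k.startswith("_")}
    with open(out_dir / "pipeline_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    report.config.to_yaml(out_dir / "run_config.yaml")
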