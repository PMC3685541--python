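"""End-to-end drivers: classify a cohort from files, design reporter
constructs for one gene, with a flat YAML config."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .classify import (
    ClassificationResult,
    ClassifyConfig,
    classify_gene,
    results_to_frame,
    summarize_cohort,
    aggregate_summary,
)
from .evidence import read_support_records
from .genemodel import load_genome, parse_gene_models
from .reporter import DEFAULT_REPORTER, design_constructs, homology_arms

log = logging.getLogger("isoscope")


@dataclass
class RunConfig:
    annotation: str = "annotation.gff3"
    genome: str = "genome.fa"
    evidence: str = "evidence.tsv"
    out_dir: str = "out"
    strong_threshold: int = 2
    junction_tolerance: int = 0
    nmd_distance: int = 50
    arm_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("strong_threshold", "nmd_distance", "arm_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.junction_tolerance < 0:
            raise ValueError("junction_tolerance must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def classify_config(self) -> ClassifyConfig:
        return ClassifyConfig(
            strong_threshold=self.strong_threshold,
            junction_tolerance=self.junction_tolerance,
            nmd_distance=self.nmd_distance,
        )


def run_classify(config: RunConfig) -> list[ClassificationResult]:
    """Classify every gene in the configured annotation; write the per-gene
    table and the category summary (with mechanism-family aggregates)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = load_genome(config.genome)
    genes = parse_gene_models(Path(config.annotation).read_text(), genome)
    records = (
        read_support_records(config.evidence)
        if Path(config.evidence).exists()
        else []
    )
    by_chrom: dict[str, list] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    cc = config.classify_config()
    results = []
    for g in genes:
        res = classify_gene(g, by_chrom.get(g.chrom, []), genome, cc)
        for w in res.warnings:
            log.info("%s: %s", g.id, w)
        results.append(res)
    results_to_frame(results).to_csv(out / "classifications.tsv", sep="\t", index=False)
    counts = summarize_cohort(results)
    counts.to_csv(out / "summary.tsv", sep="\t")
    agg = aggregate_summary(counts.to_dict())
    pd.Series(agg, name="n_genes").rename_axis("aggregate").to_csv(
        out / "summary_aggregates.tsv", sep="\t"
    )
    log.info("classified %d genes", len(results))
    return results


def run_design(
    config: RunConfig, gene_id: str, reporter_payload: str = DEFAULT_REPORTER
):
    """Design the reporter panel for one gene; write the construct table and
    a FASTA of 50-nt homology arms for every edit."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = load_genome(config.genome)
    genes = parse_gene_models(Path(config.annotation).read_text(), genome)
    matches = [g for g in genes if g.id == gene_id]
    if not matches:
        raise KeyError(f"gene {gene_id!r} not found in {config.annotation}")
    gene = matches[0]
    design = design_constructs(gene, genome, reporter_payload)
    rows = []
    arms_fa = []
    for c in design.constructs:
        for e in c.edits:
            left, right = homology_arms(
                genome, e.chrom, e.position, config.arm_length, gene.strand
            )
            arms_fa.append((f"{gene_id}|{c.name}|{e.kind.value}|up", left))
            arms_fa.append((f"{gene_id}|{c.name}|{e.kind.value}|down", right))
        rows.append(
            {
                "gene_id": gene_id,
                "construct": c.name,
                "n_edits": len(c.edits),
                "edits": ";".join(
                    f"{e.kind.value}@{e.position}" for e in c.edits
                ),
                "expressing_transcripts": ",".join(
                    sorted(t for t, v in c.vector.items() if v)
                ),
                "silent_transcripts": ",".join(
                    sorted(t for t, v in c.vector.items() if not v)
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out / f"{gene_id}_constructs.tsv", sep="\t", index=False)
    with open(out / f"{gene_id}_homology_arms.fa", "w") as fh:
        for name, seq in arms_fa:
            fh.write(f">{name}\n{seq}\n")
    if design.inseparable:
        log.warning(
            "%s: inseparable transcript classes: %s",
            gene_id,
            ["/".join(sorted(c)) for c in design.inseparable],
        )
    return design
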