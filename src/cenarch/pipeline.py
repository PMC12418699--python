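"""End-to-end runner: simulate -> delimit -> detect -> date -> classify -> compare.

The pipeline is pure given (config, seed): every stage consumes the
previous stage's in-memory objects, and all artefacts (FASTA, bedGraph,
BED, GFF3, TSV, YAML parameter echo) are written under the output
directory so each figure-style table is traceable to its parameters.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import comparative, dating, detect, enrichment, io
from .classify import FamilyEntry, FamilyLibrary, best_hit_assign
from .config import PipelineConfig
from .simulate import simulate_chip, simulate_genome


@dataclasses.dataclass
class PipelineResult:
    genome: dict
    truth: object
    calls: list
    elements: list
    dated: list
    assignments: pd.DataFrame
    copy_table: pd.DataFrame
    superfamily_pct: dict
    outdir: Path


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Run every stage on a simulated genome; deterministic given the seed."""
    config.validate()
    outdir = Path(outdir or config.outdir or "pipeline_out")
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.simulation
    if config.seed:
        spec = dataclasses.replace(spec, seed=config.seed)
    config.to_yaml(outdir / "config.yaml")

    # 1. simulate genome + ground truth
    genome, truth = simulate_genome(spec)
    io.write_fasta(genome, outdir / "genome.fa")
    io.write_truth_gff3(truth, outdir / "truth_elements.gff3")
    io.write_bed([(truth.chrom, *truth.centromere, "centromere")], outdir / "truth_centromere.bed")

    # 2. coverage + delimitation
    chip, inp = simulate_chip(
        truth.chrom_length, truth.centromere, spec.enrichment_factor,
        spec.mean_depth, config.enrichment.bin_size, spec.seed + 1,
        chrom=truth.chrom,
    )
    io.write_bedgraph(chip, outdir / "chip.bedgraph")
    io.write_bedgraph(inp, outdir / "input.bedgraph")
    ratio = enrichment.compute_ratio_track(chip, inp, config.enrichment.epsilon)
    calls = enrichment.call_enriched_intervals(
        ratio, config.enrichment.threshold, config.enrichment.merge_gap,
        config.enrichment.min_len,
    )
    io.write_calls_bed(calls, outdir / "centromere_calls.bed")

    # 3. detection
    seq = genome[truth.chrom]
    elements = detect.detect_flltrs(seq, config.detector, chrom=truth.chrom)

    # 4. dating
    dated = dating.date_elements(elements, seq, config.substitution_rate)

    # 5. classification against the simulated family library
    library = FamilyLibrary(
        entries=[
            FamilyEntry(f.family_id, f.superfamily, f.full_sequence())
            for f in spec.families
        ],
        min_identity=config.min_identity,
    ) if spec.families else None
    rows = []
    for el, de in zip(elements, dated):
        if library is not None:
            fam, sf, ident = best_hit_assign(seq[el.start : el.end], library)
        else:
            fam, sf, ident = "other", "unknown", float("nan")
        de.family_id, de.superfamily = fam, sf
        rows.append(
            {
                "chrom": el.chrom, "start": el.start, "end": el.end,
                "family_id": fam, "superfamily": sf, "identity": ident,
                "ltr_similarity": el.ltr_similarity,
                "K": de.K, "age_ma": de.age_ma,
                "incipient": de.incipient, "valid": de.valid,
            }
        )
    assignments = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "family_id", "superfamily", "identity",
            "ltr_similarity", "K", "age_ma", "incipient", "valid",
        ],
    )
    io.write_elements_gff3(
        elements, outdir / "elements.gff3",
        extra={
            i: {"family_id": r["family_id"], "age_ma": r["age_ma"]}
            for i, r in enumerate(rows)
        },
    )
    io.write_tsv(assignments, outdir / "elements.tsv")

    # 6. comparative tables
    copy_table, sf_pct = comparative.crw_copy_table(assignments, calls)
    io.write_tsv(copy_table.reset_index(names="family_id"), outdir / "copy_table.tsv")
    io.write_tsv(
        pd.DataFrame(
            [{"superfamily": k, "percent": v} for k, v in sf_pct.items()]
        ),
        outdir / "superfamily_percent.tsv",
    )
    ages = [de.age_ma for de in dated if de.valid and de.age_ma is not None]
    if ages:
        summary = comparative.age_distribution(ages, group="all")
        io.write_tsv(
            pd.DataFrame(
                [
                    {
                        "group": summary.group, "n": summary.n,
                        "median_ma": summary.median_ma,
                        "q1_ma": summary.q1_ma, "q3_ma": summary.q3_ma,
                        "incipient": summary.incipient_count,
                    }
                ]
            ),
            outdir / "age_summary.tsv",
        )

    return PipelineResult(
        genome=genome, truth=truth, calls=calls, elements=elements,
        dated=dated, assignments=assignments, copy_table=copy_table,
        superfamily_pct=sf_pct, outdir=outdir,
    )
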