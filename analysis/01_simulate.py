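"""Simulate the study chromosome: planted elements, satellite, ChIP coverage.

Writes the genome FASTA, ground-truth element GFF3 / centromere BED, and
the ChIP/Input bedGraph tracks under results/sim/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SIM_DIR, study_config

from cenarch import io
from cenarch.simulate import simulate_chip, simulate_genome


def main() -> None:
    cfg = study_config()
    spec = cfg.simulation
    SIM_DIR.mkdir(parents=True, exist_ok=True)

    genome, truth = simulate_genome(spec)
    chip, inp = simulate_chip(
        truth.chrom_length, truth.centromere, spec.enrichment_factor,
        spec.mean_depth, spec.bin_size, spec.seed + 1, chrom=truth.chrom,
    )

    io.write_fasta(genome, SIM_DIR / "genome.fa")
    io.write_truth_gff3(truth, SIM_DIR / "truth_elements.gff3")
    bed_rows = [(truth.chrom, *truth.centromere, "centromere")]
    if truth.satellite_interval:
        bed_rows.append((truth.chrom, *truth.satellite_interval, "satellite"))
    io.write_bed(bed_rows, SIM_DIR / "truth_centromere.bed")
    io.write_bedgraph(chip, SIM_DIR / "chip.bedgraph")
    io.write_bedgraph(inp, SIM_DIR / "input.bedgraph")
    cfg.to_yaml(SIM_DIR / "config.yaml")

    n = len(truth.elements)
    by_region = {}
    for el in truth.elements:
        by_region[el.region] = by_region.get(el.region, 0) + 1
    print(f"simulated {truth.chrom}: {truth.chrom_length:,} nt")
    print(f"planted {n} full-length elements: {by_region}")
    print(f"true centromere: {truth.centromere[0]:,}-{truth.centromere[1]:,}")
    if truth.satellite_interval:
        s, e = truth.satellite_interval
        print(f"satellite array: {s:,}-{e:,} ({truth.satellite_unit_len}-nt units)")
    print(f"outputs in {SIM_DIR}")


if __name__ == "__main__":
    main()
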