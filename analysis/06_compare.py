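"""Comparative statistics: regions, age contrasts, copy tables, satellite.

Partitions the chromosome into ancestral/derived classes, contrasts
insertion-age distributions between regions (Mann–Whitney U), tabulates
family copies per centromere with the superfamily roll-up, summarises the
satellite monomer identity structure, and reports the published
superfamily percentages for reference.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SIM_DIR, study_config

from cenarch import io
from cenarch.comparative import (
    age_distribution,
    crw_copy_table,
    monomerize_and_heatmap,
    partition_regions,
    region_age_summary,
    superfamily_percentages,
)
from cenarch.dating import date_elements
from cenarch.enrichment import CentromereCall
from cenarch.reference import SUPERFAMILY_COUNTS


def main() -> None:
    cfg = study_config()
    genome = io.read_fasta(SIM_DIR / "genome.fa")
    chrom, seq = next(iter(genome.items()))
    elements = io.read_elements_gff3(RESULTS / "elements.gff3")
    dated = date_elements(elements, seq, cfg.substitution_rate)
    assignments = io.read_tsv(RESULTS / "assignments.tsv")

    # ancestral = pericentromeric flanks (in all accessions), derived = centromere
    cbed = io.read_bed(SIM_DIR / "truth_centromere.bed")[0]
    cs, ce = cbed[1], cbed[2]
    flank = cfg.simulation.pericentromere_flank
    domain = (0, len(seq))
    ancestral = [[(max(0, cs - flank), cs), (ce, min(len(seq), ce + flank))]] * 3
    part = partition_regions(ancestral, [(cs, ce)], domain)
    summaries, tests = region_age_summary(dated, part)
    rows = [
        {
            "class": cls, "region_number": part.numbering[cls], "n": s.n,
            "median_ma": s.median_ma, "q1_ma": s.q1_ma, "q3_ma": s.q3_ma,
            "incipient": s.incipient_count,
        }
        for cls, s in summaries.items()
    ]
    io.write_tsv(pd.DataFrame(rows), RESULTS / "region_age_summary.tsv")
    io.write_tsv(tests, RESULTS / "region_age_tests.tsv")
    print("per-region insertion ages (Ma):")
    print(pd.DataFrame(rows).to_string(index=False))
    if not tests.empty:
        print("pairwise Mann–Whitney U:")
        print(tests.to_string(index=False))

    call = CentromereCall(chrom=chrom, start=cs, end=ce)
    table, pct = crw_copy_table(assignments, [call])
    io.write_tsv(table.reset_index(names="family_id"), RESULTS / "copy_table.tsv")
    print("\nfamily copies inside the centromere call:")
    print(table.to_string())
    print(f"simulated superfamily roll-up: {pct}")
    print(f"published roll-up (3111/141/344): {superfamily_percentages(SUPERFAMILY_COUNTS)}")

    ages = [d.age_ma for d in dated if d.valid and d.age_ma is not None]
    kde = age_distribution(ages, group="all")
    print(f"\nall-element age distribution: n={kde.n}, median {kde.median_ma:.2f} Ma, "
          f"{kde.incipient_count} incipient")

    # satellite monomer structure over the planted array
    import numpy as np

    sat = [r for r in io.read_bed(SIM_DIR / "truth_centromere.bed") if r[3] == "satellite"]
    unit_len = cfg.simulation.satellite[0] if cfg.simulation.satellite else None
    if sat and unit_len:
        _, ss, se, _ = sat[0]
        mh = monomerize_and_heatmap(seq[ss:se], unit_len)
        off = mh.identity[~np.eye(len(mh.monomers), dtype=bool)]
        print(f"satellite array: {len(mh.monomers)} monomers of {unit_len} nt, "
              f"mean off-diagonal identity {off.mean():.3f}")


if __name__ == "__main__":
    main()
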