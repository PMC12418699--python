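"""Date each detected element from its 5'/3' LTR divergence.

K2P-corrected divergence over the aligned LTR pair, age = K/(2r) with
r = 1.3e-8 /site/year.  Compares estimated to true ages and writes the
dating table.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SIM_DIR, study_config

from cenarch import io
from cenarch.dating import date_elements


def main() -> None:
    cfg = study_config()
    genome = io.read_fasta(SIM_DIR / "genome.fa")
    chrom, seq = next(iter(genome.items()))
    elements = io.read_elements_gff3(RESULTS / "elements.gff3")
    dated = date_elements(elements, seq, cfg.substitution_rate)

    truth = io.read_elements_gff3(SIM_DIR / "truth_elements.gff3")
    truth_age = {}
    for line in (SIM_DIR / "truth_elements.gff3").read_text().splitlines():
        if line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";"))
        truth_age[int(f[3]) - 1] = float(attrs["true_age_Ma"])

    rows = []
    for el, de in zip(elements, dated):
        rows.append(
            {
                "chrom": el.chrom, "start": el.start, "end": el.end,
                "P": de.counts.P if de.counts else None,
                "Q": de.counts.Q if de.counts else None,
                "K": de.K, "age_ma": de.age_ma, "incipient": de.incipient,
                "valid": de.valid, "true_age_ma": truth_age.get(el.start),
            }
        )
    df = pd.DataFrame(rows)
    io.write_tsv(df, RESULTS / "dating.tsv")

    ok = df.dropna(subset=["age_ma", "true_age_ma"])
    err = (ok["age_ma"] - ok["true_age_ma"]).abs()
    print(f"dated {len(df)} elements ({int(df['incipient'].sum())} incipient, "
          f"{int((~df['valid']).sum())} saturated)")
    print(f"median |estimated - true| age: {err.median():.3f} Ma "
          f"(true ages span {ok['true_age_ma'].min():.2f}-{ok['true_age_ma'].max():.2f} Ma)")
    r = np.corrcoef(ok["age_ma"], ok["true_age_ma"])[0, 1]
    print(f"estimated vs true age correlation r = {r:.3f}")
    print(f"wrote {RESULTS / 'dating.tsv'}")


if __name__ == "__main__":
    main()
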