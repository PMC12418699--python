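"""Published reference values for hexaploid wheat centromeres.

These are inputs to the summary operations: the 21 CENH3-delimited
centromere intervals of the Chinese Spring assembly (pseudomolecule
positions in Mb, with the printed total length), the per-subgenome
full-length LTR retrotransposon counts, and the superfamily breakdown
of those elements.
"""

from __future__ import annotations

# Per-chromosome CENH3-enriched intervals, pseudomolecule positions in Mb.
# (chromosome, start_mb, end_mb, printed_length_mb)
CS_CENTROMERE_INTERVALS_MB: list[tuple[str, float, float, float]] = [
    ("1A", 213.0, 219.2, 6.2),
    ("2A", 346.2, 352.1, 5.9),
    ("3A", 332.0, 338.2, 6.2),
    ("4A", 288.5, 295.0, 6.5),
    ("5A", 253.0, 260.0, 7.0),
    ("6A", 285.7, 293.5, 7.8),
    ("7A", 368.0, 373.6, 5.6),
    ("1B", 236.0, 243.3, 7.3),
    ("2B", 366.3, 373.0, 6.7),
    ("3B", 362.0, 365.2, 3.2),
    ("4B", 328.6, 334.7, 6.1),
    ("5B", 210.0, 215.0, 5.0),
    ("6B", 346.2, 351.8, 5.6),
    ("7B", 314.2, 320.3, 6.1),
    ("1D", 172.8, 180.0, 7.2),
    ("2D", 269.8, 276.5, 6.6),
    ("3D", 252.2, 258.0, 5.8),
    ("4D", 186.6, 191.6, 5.0),
    ("5D", 193.2, 199.3, 6.1),
    ("6D", 239.0, 244.8, 5.8),
    ("7D", 347.6, 353.0, 5.4),
]

#: chromosome -> subgenome (the trailing letter of the chromosome name)
CS_SUBGENOME_MAP: dict[str, str] = {
    row[0]: row[0][-1] * 2 for row in CS_CENTROMERE_INTERVALS_MB
}

#: full-length LTR-RT counts detected in functional centromeres, per subgenome
CENTROMERIC_FLLTR_COUNTS: dict[str, int] = {"AA": 1424, "BB": 1206, "DD": 965}

#: superfamily breakdown of the same elements
SUPERFAMILY_COUNTS: dict[str, int] = {"Gypsy": 3111, "Copia": 141, "unknown": 344}

#: average substitution rate used for molecular dating, /site/year
SUBSTITUTION_RATE: float = 1.3e-8

#: centromeric satellite monomer unit sizes, nt
SATELLITE_UNIT_SIZES: tuple[int, int] = (566, 550)

#: pericentromere flank widths per subgenome, nt
PERICENTROMERE_FLANK_NT: dict[str, int] = {
    "AA": 15_000_000,
    "BB": 15_000_000,
    "DD": 10_000_000,
}
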