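"""Readers and writers for the pipeline's file formats.

Conventions: internal coordinates are 0-based half-open everywhere; BED and
bedGraph share that convention on disk, GFF3 is 1-based inclusive and is
converted only at this boundary.  Sequence case is normalised to upper on
read.  Malformed lines raise with their line number.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detect import FlLTRElement
from .enrichment import CentromereCall, CoverageTrack

PathLike = Union[str, Path]


# ------------------------------------------------------------------- FASTA


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# --------------------------------------------------------------------- BED


def write_bed(
    intervals: Iterable[tuple], path: PathLike
) -> None:
    """Write (chrom, start, end[, name]) records; 0-based half-open."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            name = iv[3] if len(iv) > 3 else None
            if end <= start:
                raise ValueError(f"empty BED interval {chrom}:{start}-{end}")
            fields = [chrom, str(start), str(end)] + ([str(name)] if name else [])
            fh.write("\t".join(fields) + "\n")


def read_bed(path: PathLike) -> list[tuple]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise ValueError(f"{path}:{ln}: invalid interval [{start}, {end})")
            out.append((parts[0], start, end, *parts[3:4]))
    return out


# ---------------------------------------------------------------- bedGraph


def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    bs = track.bin_size
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            start = i * bs
            end = min(start + bs, track.chrom_length)
            fh.write(f"{track.chrom}\t{start}\t{end}\t{v:g}\n")


def read_bedgraph(path: PathLike) -> CoverageTrack:
    """Read a single-chromosome 4-column bedGraph into a binned track.

    Intervals must be sorted, non-overlapping and of one uniform bin size
    (the final interval may be shorter).
    """
    chrom = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: bedGraph needs exactly 4 columns")
            c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ValueError(f"{path}:{ln}: multiple chromosomes in one track")
            if e <= s:
                raise ValueError(f"{path}:{ln}: invalid interval [{s}, {e})")
            if rows and s < rows[-1][1]:
                raise ValueError(f"{path}:{ln}: overlapping or unsorted intervals")
            rows.append((s, e, v))
    if not rows:
        raise ValueError(f"{path}: empty bedGraph")
    bin_size = rows[0][1] - rows[0][0]
    for s, e, _ in rows[:-1]:
        if e - s != bin_size:
            raise ValueError(f"{path}: non-uniform bin size")
    values = np.array([v for _, _, v in rows])
    chrom_length = rows[-1][1]
    return CoverageTrack(chrom=chrom, bin_size=bin_size, values=values, chrom_length=chrom_length)


# -------------------------------------------------------------------- GFF3

_GFF_SOURCE = "cenarch"


def _fmt_attrs(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v is not None)


def _parse_attrs(field: str) -> dict:
    out = {}
    for item in field.split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def write_elements_gff3(
    elements: Sequence[FlLTRElement], path: PathLike, extra: Optional[dict] = None
) -> None:
    """One LTR_retrotransposon feature per element with LTR children.

    ``extra`` maps element index -> dict of additional attributes (e.g.
    family, age) merged into the parent feature.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, el in enumerate(elements):
            eid = f"flltr{i:05d}"
            attrs = {
                "ID": eid,
                "ltr_similarity": f"{el.ltr_similarity:.4f}",
                "tsd": el.tsd or "none",
                "motif": "TGCA" if el.motif_ok else "none",
            }
            if el.quality_flags:
                attrs["flags"] = ",".join(sorted(el.quality_flags))
            if extra and i in extra:
                attrs.update(extra[i])
            fh.write(
                "\t".join(
                    [
                        el.chrom, _GFF_SOURCE, "LTR_retrotransposon",
                        str(el.start + 1), str(el.end), ".", el.strand, ".",
                        _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )
            for part, (s, e) in (("five_prime", el.ltr5), ("three_prime", el.ltr3)):
                fh.write(
                    "\t".join(
                        [
                            el.chrom, _GFF_SOURCE, "long_terminal_repeat",
                            str(s + 1), str(e), ".", el.strand, ".",
                            _fmt_attrs({"ID": f"{eid}_{part}", "Parent": eid}),
                        ]
                    )
                    + "\n"
                )


def read_elements_gff3(path: PathLike) -> list[FlLTRElement]:
    parents: dict[str, dict] = {}
    ltrs: dict[str, dict[str, tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: GFF3 needs 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attr_field = parts
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
            attrs = _parse_attrs(attr_field)
            if ftype == "LTR_retrotransposon":
                eid = attrs["ID"]
                order.append(eid)
                parents[eid] = {
                    "chrom": chrom, "start": s, "end": e, "strand": strand,
                    "attrs": attrs,
                }
            elif ftype == "long_terminal_repeat":
                pid = attrs["Parent"]
                side = "ltr5" if attrs["ID"].endswith("five_prime") else "ltr3"
                ltrs.setdefault(pid, {})[side] = (s, e)
    out = []
    for eid in order:
        p = parents[eid]
        pair = ltrs.get(eid, {})
        a = p["attrs"]
        tsd = a.get("tsd", "none")
        flags = set(a["flags"].split(",")) if "flags" in a else set()
        out.append(
            FlLTRElement(
                chrom=p["chrom"],
                ltr5=pair.get("ltr5", (p["start"], p["start"] + 1)),
                ltr3=pair.get("ltr3", (p["end"] - 1, p["end"])),
                strand=p["strand"],
                ltr_similarity=float(a.get("ltr_similarity", "0")),
                tsd=None if tsd == "none" else tsd,
                motif_ok=a.get("motif", "none") != "none",
                quality_flags=flags,
            )
        )
    return out


def write_truth_gff3(truth, path: PathLike) -> None:
    """Ground-truth planted elements with family/age/tsd attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, el in enumerate(truth.elements):
            attrs = {
                "ID": f"planted{i:05d}",
                "family_id": el.family_id,
                "true_age_Ma": f"{el.true_age_ma:.4f}",
                "tsd": el.tsd,
                "ltr_len": str(el.ltr_len),
                "truncated": str(el.truncated).lower(),
                "region": el.region or None,
            }
            fh.write(
                "\t".join(
                    [
                        el.chrom, _GFF_SOURCE, "LTR_retrotransposon",
                        str(el.insert_pos + 1), str(el.end), ".", "+", ".",
                        _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )


def write_calls_bed(calls: Sequence[CentromereCall], path: PathLike) -> None:
    write_bed(
        [(c.chrom, c.start, c.end, "primary" if c.primary else "secondary") for c in calls],
        path,
    )


# ------------------------------------------------------------- Newick, TSV


def write_newick(tree, path: PathLike) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_newick(path: PathLike):
    from Bio import Phylo

    return Phylo.read(str(path), "newick")


def write_tsv(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
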