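"""File-format helpers.

All coordinates are stored 0-based half-open in memory; GFF3 is read
and written 1-based inclusive, BED 0-based half-open. FASTA goes
through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for field in attr.strip().split(";"):
        if not field:
            continue
        key, _, value = field.partition("=")
        out[key.strip()] = value.strip()
    return out


def format_gff3_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into a frame with 0-based half-open ``start``/``end``.

    Attribute key-value pairs are expanded into extra columns.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str, "source": str, "type": str, "strand": str},
    )
    df["start"] = df["start"].astype(int) - 1  # 1-based inclusive -> 0-based half-open
    df["end"] = df["end"].astype(int)
    attrs = df["attributes"].map(parse_gff3_attributes)
    attr_df = pd.DataFrame(list(attrs), index=df.index)
    return pd.concat([df.drop(columns=["attributes"]), attr_df], axis=1)


def write_gff3(
    rows: Iterable[dict], path: str | Path, source: str = "mircnv"
) -> None:
    """Write GFF3 from dicts with 0-based half-open coordinates.

    Each row needs ``seqid, type, start, end`` and may carry ``strand``,
    ``score`` and an ``attributes`` dict.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            attrs = format_gff3_attributes(row.get("attributes", {}))
            fh.write(
                "\t".join([
                    str(row["seqid"]),
                    row.get("source", source),
                    str(row["type"]),
                    str(int(row["start"]) + 1),  # back to 1-based inclusive
                    str(int(row["end"])),
                    str(row.get("score", ".")),
                    row.get("strand", "."),
                    row.get("phase", "."),
                    attrs or ".",
                ]) + "\n"
            )


def read_bed3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed3(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_depth_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a BedGraph-like per-base depth table (chrom, start, end, depth)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "depth"], dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_depth_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    kwargs.setdefault("index", False)
    df.to_csv(path, sep="\t", **kwargs)
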