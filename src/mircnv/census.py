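"""Precursor homology census.

Counts occurrences of a query sequence (e.g. a miRNA stem-loop
precursor) in an assembly at full query coverage and an identity
floor, the way a blastn search filtered to 100% coverage / >=97%
identity would. The scan is seed-and-extend: every true hit at >=97%
identity over a ~180 bp query must, by pigeonhole, contain an exact
match of length ceil(len/ (errors+1)) >= 12, so exact 12-mer seeds
locate candidate windows and banded gapped alignment (edlib) scores
them. Identity follows the blastn convention: matching columns over
total alignment columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .mask import reverse_complement

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class CensusHit:
    chrom: str
    start: int   # 0-based half-open genomic span of the alignment
    end: int
    strand: str
    identity: float
    alignment_length: int
    query_coverage: float = 1.0

    def to_row(self, query_id: str, query_len: int) -> dict:
        """blast outfmt-6-like record (1-based inclusive coordinates)."""
        mismatch_gap = self.alignment_length - round(self.identity * self.alignment_length)
        return {
            "qseqid": query_id, "sseqid": self.chrom,
            "pident": round(100 * self.identity, 2),
            "length": self.alignment_length,
            "qstart": 1, "qend": query_len,
            "sstart": self.start + 1 if self.strand == "+" else self.end,
            "send": self.end if self.strand == "+" else self.start + 1,
            "strand": self.strand,
        }


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matching columns, total columns) from an edlib extended CIGAR."""
    matches = 0
    columns = 0
    for count, op in _CIGAR_RE.findall(cigar):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def _align_query(query: str, target: str) -> tuple[int, int, float, int] | None:
    """Best infix alignment of the full query inside ``target``.

    Returns (start, end, identity, alignment_columns) in target
    coordinates, or None when edlib finds no alignment.
    """
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    t_start, t_end = res["locations"][0]
    matches, columns = _cigar_stats(res["cigar"])
    return t_start, t_end + 1, matches / columns, columns


def scan_assembly(
    genome: dict[str, str],
    query: str,
    min_identity: float = 0.97,
    min_coverage: float = 1.0,
    seed_k: int = 12,
) -> list[CensusHit]:
    """Find all full-coverage occurrences of ``query`` at an identity floor.

    Both strands are scanned; hits are reported in forward-genome
    coordinates. Candidate windows sharing >50% of their span are
    deduplicated keeping the higher identity. ``min_coverage`` below
    1.0 is accepted but the aligner always consumes the full query, so
    reported coverage is 1.0.
    """
    query = query.upper()
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    if len(query) < seed_k:
        raise ValueError(f"query shorter than seed length {seed_k}")
    if set(query) <= {"N"}:
        raise ValueError("degenerate all-N query")

    qlen = len(query)
    max_err = int((1 - min_identity) * qlen) + 2  # alignment band slack
    hits: list[CensusHit] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        index = _kmer_index(seq, seed_k)
        for strand, oriented in (("+", query), ("-", reverse_complement(query))):
            candidates = _candidate_windows(oriented, index, seed_k, qlen, max_err, len(seq))
            for w_start, w_end in candidates:
                aln = _align_query(oriented, seq[w_start:w_end])
                if aln is None:
                    continue
                t_start, t_end, identity, columns = aln
                if identity >= min_identity:
                    hits.append(CensusHit(
                        chrom=chrom, start=w_start + t_start, end=w_start + t_end,
                        strand=strand, identity=identity, alignment_length=columns,
                    ))
    return _deduplicate(hits)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _candidate_windows(
    query: str, index: dict[str, list[int]], k: int, qlen: int,
    max_err: int, seq_len: int,
) -> list[tuple[int, int]]:
    """Merge seed diagonals into alignment windows around each candidate."""
    starts: list[int] = []
    for q_off in range(0, qlen - k + 1):
        for g_pos in index.get(query[q_off : q_off + k], ()):
            starts.append(g_pos - q_off)  # implied query start on the genome
    if not starts:
        return []
    starts.sort()
    windows: list[tuple[int, int]] = []
    cluster_lo = cluster_hi = starts[0]
    for s in starts[1:]:
        if s - cluster_hi <= max_err:
            cluster_hi = s
        else:
            windows.append((cluster_lo, cluster_hi))
            cluster_lo = cluster_hi = s
    windows.append((cluster_lo, cluster_hi))
    return [
        (max(0, lo - max_err), min(seq_len, hi + qlen + max_err))
        for lo, hi in windows
    ]


def _deduplicate(hits: list[CensusHit]) -> list[CensusHit]:
    """Keep the best hit among spans overlapping by more than half."""
    kept: list[CensusHit] = []
    for hit in sorted(hits, key=lambda h: (-h.identity, h.chrom, h.start)):
        redundant = False
        for other in kept:
            if hit.chrom != other.chrom:
                continue
            overlap = min(hit.end, other.end) - max(hit.start, other.start)
            if overlap <= 0:
                continue
            if overlap > 0.5 * min(hit.end - hit.start, other.end - other.start):
                redundant = True
                break
        if not redundant:
            kept.append(hit)
    kept.sort(key=lambda h: (h.chrom, h.start))
    return kept


def hits_to_tsv(hits: list[CensusHit], query_id: str, query_len: int, path) -> None:
    import pandas as pd

    rows = [h.to_row(query_id, query_len) for h in hits]
    pd.DataFrame(
        rows, columns=["qseqid", "sseqid", "pident", "length", "qstart",
                       "qend", "sstart", "send", "strand"],
    ).to_csv(path, sep="\t", index=False)
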