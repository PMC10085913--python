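"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive and structurally different from the
implementation it checks: per-position window scans for the
uniqueness mask, union-find over the all-pairs overlap graph for
region grouping, and a vectorized full dynamic-programming alignment
matrix for the homology census.
"""

from __future__ import annotations

import numpy as np

from mircnv.mask import canonical_kmer, reverse_complement


def mask_oracle(seqs: dict[str, str], k: int) -> dict[str, np.ndarray]:
    """Per-position check: masked iff some covering k-mer occurs >= 2 times."""
    from collections import Counter

    counts: Counter[str] = Counter()
    for seq in seqs.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" not in w:
                counts[canonical_kmer(w)] += 1
    out = {}
    for chrom, seq in seqs.items():
        seq = seq.upper()
        n = len(seq)
        bad = [
            "N" in seq[i : i + k] or counts[canonical_kmer(seq[i : i + k])] >= 2
            for i in range(max(0, n - k + 1))
        ]
        masked = np.zeros(n, dtype=bool)
        for p in range(n):
            lo, hi = max(0, p - k + 1), min(p + 1, len(bad))
            masked[p] = any(bad[i] for i in range(lo, hi))
        out[chrom] = masked
    return out


def overlap_components(intervals: list[tuple[str, int, int]]) -> int:
    """Number of connected components of the all-pairs >=1 bp overlap graph."""
    n = len(intervals)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def _edit_distance_ends(query: str, target: str) -> np.ndarray:
    """d[j] = edit distance of the best full-query alignment ending at j.

    Row-by-row DP over the whole target with free start/end gaps in
    the target (infix semantics), vectorized per query row; the
    horizontal relaxation min_{j'<=j} cand[j'] + (j - j') is a running
    minimum of cand[j'] - j'.
    """
    m = len(target)
    jj = np.arange(m + 1)
    prev = np.zeros(m + 1, dtype=np.int32)  # free start gap in target
    t = np.frombuffer(target.encode(), dtype="S1")
    for qc in query.encode():
        sub = prev[:-1] + (t != bytes([qc]))
        cand = np.empty(m + 1, dtype=np.int32)
        cand[0] = prev[0] + 1
        cand[1:] = np.minimum(sub, prev[1:] + 1)
        prev = jj + np.minimum.accumulate(cand - jj)
    return prev[1:]  # index j: alignment ends at target position j (1-based -> j)


def census_oracle(
    genome: dict[str, str], query: str, min_identity: float
) -> list[tuple[str, str, int, int]]:
    """All full-coverage hits by exhaustive DP; returns (chrom, strand, d, end)."""
    qlen = len(query)
    max_err = int(round((1 - min_identity) * qlen))
    hits = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for strand, q in (("+", query.upper()), ("-", reverse_complement(query.upper()))):
            ends = _edit_distance_ends(q, seq)
            good = np.flatnonzero(ends <= max_err)
            # cluster nearby end positions into one hit each
            cluster: list[int] = []
            for j in good:
                if cluster and j - cluster[-1] > qlen // 2:
                    best = min(cluster, key=lambda x: ends[x])
                    hits.append((chrom, strand, int(ends[best]), int(best) + 1))
                    cluster = []
                cluster.append(int(j))
            if cluster:
                best = min(cluster, key=lambda x: ends[x])
                hits.append((chrom, strand, int(ends[best]), int(best) + 1))
    return hits
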