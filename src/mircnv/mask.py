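"""Genome uniqueness mask.

Read-depth genotyping only trusts positions that short reads can map
to uniquely. The mask marks every position covered by a k-mer window
(default k=40, step 1) that occurs two or more times genome-wide.
Counting is strand-blind: a window and its reverse complement are the
same k-mer, and a palindromic window counts once per position.
Windows containing N are masked unconditionally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class UniquenessMask:
    """Boolean per-chromosome vectors; True = masked (nonunique or N)."""

    masks: dict[str, np.ndarray]
    k: int
    step: int = 1

    def masked_fraction(self) -> float:
        total = sum(len(m) for m in self.masks.values())
        masked = sum(int(m.sum()) for m in self.masks.values())
        return masked / total if total else 0.0

    def callable_positions(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of unmasked positions within [start, end)."""
        m = self.masks[chrom]
        window = ~m[start:end]
        return start + np.nonzero(window)[0]

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.masks[chrom]


def build_uniqueness_mask(
    seqs: dict[str, str], k: int = 40, step: int = 1
) -> UniquenessMask:
    """Mask positions covered by any repeated (or N-containing) k-mer.

    Two passes: count canonical k-mers over every window of every
    chromosome, then mark the footprint of each window whose canonical
    k-mer count is >= 2. Sequences shorter than k contribute no windows
    and stay unmasked.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if not seqs or all(len(s) == 0 for s in seqs.values()):
        raise ValueError("empty genome")

    counts: Counter[str] = Counter()
    for seq in seqs.values():
        seq = seq.upper()
        for i in range(0, len(seq) - k + 1, step):
            window = seq[i : i + k]
            if "N" in window:
                continue
            counts[canonical_kmer(window)] += 1

    masks: dict[str, np.ndarray] = {}
    for chrom, seq in seqs.items():
        seq = seq.upper()
        n = len(seq)
        # difference array so each bad window marks its footprint in O(1)
        diff = np.zeros(n + 1, dtype=np.int32)
        for i in range(0, n - k + 1, step):
            window = seq[i : i + k]
            bad = "N" in window or counts[canonical_kmer(window)] >= 2
            if bad:
                diff[i] += 1
                diff[min(i + k, n)] -= 1
        masks[chrom] = np.cumsum(diff[:-1]) > 0
    return UniquenessMask(masks=masks, k=k, step=step)
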